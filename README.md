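# glycotyper

Glyco-based tumor subtyping from intact-glycopeptide mass spectrometry, at
desk scale.

Protein glycosylation is heavily remodeled in high-grade serous ovarian
carcinoma (HGSC), and the glycan a protein carries at a given asparagine is
information that neither mRNA nor global protein abundance contains.
`glycotyper` implements the full analysis chain that turns iTRAQ-labeled
MS/MS spectra into site-specific glycopeptide identifications and then into
tumor biology: glyco-based tumor subtypes, glycan-type signatures, survival
stratification, and multi-layer (mRNA / protein / glycosite / intact
glycopeptide / glycoenzyme) correlation structure. Because the original
tumor cohorts are not redistributable, the package ships a first-class
synthetic-data generator that emulates their statistical structure with
known ground truth, so every stage is testable end to end.

## What the package computes

**Identification.** An MS/MS spectrum is considered a glycopeptide
candidate if the HexNAc oxonium ion (m/z 204.0966) appears among its ten
most intense peaks after the iTRAQ reporter region is removed. For each
such spectrum the mass gap between the precursor neutral mass M and each
peptide mass m(p) in a glycosite-peptide database is matched against a
glycan composition database (10 ppm):

    |M − (m(p) + m(g))| ≤ 10 ppm · M,   m(g) = n_Hex·162.0528 + n_HexNAc·203.0794 + n_Fuc·146.0579 + n_NeuAc·291.0954

Candidates are scored against the spectrum by the Morpheus score
S = n_matched + (matched intensity)/(total intensity) over peptide b/y
ions, glycopeptide Y ions, oxonium ions, and +1/+2 isotope peaks (20 ppm).
Candidates with more than six matched fragment ions compete; best hits are
ranked by S and filtered at 1% target–decoy FDR (reversed-sequence decoys)
keeping identifications that explain >10% of the spectrum intensity.

**Quantification.** Per-PSM log2 reporter ratios against the pooled
reference channel (114), per-glycopeptide abundance as the median over
PSMs, per-sample normalization on the median of globally quantified
glycoproteins, then per-feature Z-scores.

**Subtyping.** Consensus clustering: 80% of samples subsampled without
replacement 500 times, each subsample partitioned by PAM (k-medoids,
Euclidean distance on Z-scores), co-clustering proportions cut by
average-linkage hierarchical clustering — k = 3 for tumors, k = 5 for
glycopeptide groups. Cluster-subtype association is scored by fold
enrichment overlap·N/(n_a·n_b) with an upper-tail hypergeometric p-value.

**Survival.** Per-sample group signature scores (mean Z over a
glycopeptide group), top-50 vs bottom-50 stratification, Kaplan–Meier
curves and the two-group log-rank test, and a Cox proportional-hazards
model on age plus cluster indicators (Efron ties; via lifelines).

**Correlations.** Spearman throughout: per-sample glycosite↔protein
concordance; per-gene layer correlations with Benjamini–Hochberg
adjustment; and a 22-glycoenzyme × glycopeptide correlation grid with
bi-clustering and glycan-flag group comparisons (Welch t-tests).

## Worked example

```python
from glycotyper.simulate import (CohortSimConfig, SpectraSimConfig,
                                 generate_cohort, generate_spectra)
from glycotyper.ident import search_spectra
from glycotyper.quant import complete_subset, zscore
from glycotyper.cluster import consensus_cluster, group_signature_score
from glycotyper.survival import select_extremes, logrank_test
from sklearn.metrics import adjusted_rand_score

sim = generate_spectra(SpectraSimConfig(n_glyco_spectra=200,
                                        n_nonglyco_spectra=200, seed=1))
accepted, best = search_spectra(sim.spectra, sim.peptides, sim.glycans)
print(f"accepted {len(accepted)} of {len(best)} best hits at 1% FDR")

ds = generate_cohort(CohortSimConfig(seed=1))
z = zscore(complete_subset(ds.igp))
clusters = consensus_cluster(z, k=3, n_reps=500, seed=1)
ari = adjusted_rand_score(ds.truth["sample_clusters"], clusters.labels)
print(f"consensus cluster sizes: {clusters.labels.value_counts().sort_index().to_dict()}")
print(f"adjusted Rand index vs planted clusters: {ari:.3f}")

groups = ds.truth["igp_groups"]
score = group_signature_score(z, list(groups.index[groups == 1]))
high, low = select_extremes(score, 50)
sv = ds.survival
chi2, p = logrank_test(sv.loc[high, "time_months"], sv.loc[high, "event"],
                       sv.loc[low, "time_months"], sv.loc[low, "event"])
print(f"group-1 signature extreme-strata log-rank: chi2 = {chi2:.2f}, p = {p:.2e}")
```

Output:

```
accepted 200 of 200 best hits at 1% FDR
consensus cluster sizes: {1: 43, 2: 48, 3: 28}
adjusted Rand index vs planted clusters: 0.976
group-1 signature extreme-strata log-rank: chi2 = 8.96, p = 2.76e-03
```

All 200 planted glycopeptide spectra are identified and no decoy survives
the 1% FDR filter; the three planted tumor clusters (27/49/43 samples) are
recovered almost exactly; and the samples scoring highest on the
fucosylated-glycopeptide (group 1) signature have significantly worse
overall survival — the planted hazard ratio of 2 per score SD is clearly
visible in 50-vs-50 extreme strata.

## Command line

```sh
glycotyper simulate-spectra --seed 1 --out sim/
glycotyper identify --spectra sim/spectra.jsonl --peptides sim/peptides.tsv --fdr 0.01 --out psms.tsv
glycotyper simulate-cohort --seed 1 --out cohort/
glycotyper cluster --matrix cohort/igp_matrix.tsv --k 3 --reps 500 --seed 1 --out clusters/
glycotyper survive --matrix cohort/igp_matrix.tsv --groups cohort/truth_igp_groups.tsv \
    --survival cohort/survival.tsv --group 1 --out surv/
glycotyper run-all --seed 1 --out run/
```

`run-all` executes every stage and writes TSV artifacts plus a
machine-readable `summary.json`; reruns with the same seed are
byte-identical.

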