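# Methods

This note documents the models and procedures implemented in `glycotyper`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing its outputs.

## Mass arithmetic

Monoisotopic masses follow the Unimod atomic-mass convention
(H 1.007825035, C 12, 13C 13.00335483, N 14.003074, 15N 15.00010897,
O 15.99491463, S 31.9720707 Da). This table — rather than the newest
CODATA values — is used deliberately: the conventional printed values of
the fixed-modification deltas (carbamidomethyl +57.021464, oxidation
+15.9949, iTRAQ 4-plex +144.102063, deamidation +0.984016 Da) round
correctly at six decimals only under it; the difference to CODATA is below
1e-6 Da and irrelevant at the 10–20 ppm tolerances used anywhere else.

Peptide masses carry the iTRAQ experiment's fixed modifications: the
4-plex label on the N-terminus and every Lys, carbamidomethyl on Cys, and
Met as the oxidized form. Deamidation (+0.984016 on Asn) is the PNGase-F
scar that marks a glycosite in deglycosylated (SPEG) data; for intact
glycopeptides the glycan itself occupies the Asn, so deamidation is never
applied in the intact search.

Glycans are compositions, not structures: counts of Hex, HexNAc, Fuc and
NeuAc (NeuGc is not modeled; the data are human). The five-way type
classification is:

* **high mannose** — HexNAc = 2, 5 ≤ Hex ≤ 9, no Fuc/NeuAc (the Man5–Man9 series);
* **fucosylated only** — Fuc ≥ 1, NeuAc = 0 (excluding the above);
* **sialylated only** — NeuAc ≥ 1, Fuc = 0;
* **fuco-sialylated** — both present;
* **other complex/hybrid** — everything else.

The packaged toy glycan database (42 compositions) spans all five labels;
real analyses would substitute a larger composition list via
`io.load_glycan_db(path)`.

## Identification engine

The oxonium filter tests whether any of the ten most intense peaks (after
removing the reporter region) lies within 20 ppm of the HexNAc oxonium
ion. Two conventions deserve note. First, the filter constant defaults to
the conventional m/z 204.0966 although the elemental mass of the
C8H14NO6+ ion is 204.0867; the constant is configurable, and the spectra
simulator plants the same constant the filter uses, so the two always
agree. Second, "removing reporter ions" is implemented as a fixed cutoff
at m/z 120 (iTRAQ 4-plex reporters lie at 114–117): a fixed low-mass
window is reproducible and instrument-independent, and the same window
defines the denominator of the matched-intensity fraction.

Candidate generation matches the precursor neutral mass against peptide
mass + glycan residue mass at 10 ppm. Fragment prediction enumerates
peptide b/y ions, glycopeptide Y ions along monotone glycan trimming
(capped at 64 sub-compositions), a standard oxonium set (Hex, HexNAc,
NeuAc, NeuAc−H2O, Hex+HexNAc), charges 1–2, and +1/+2 isotope peaks
spaced by the neutron mass over the charge. Scoring is the Morpheus
score: matched-fragment count plus matched-intensity fraction, with
greedy nearest-ppm unique matching (each peak and fragment used at most
once). Candidates need more than six matched fragment ions — counted over
all fragment classes, not backbone ions only — to qualify; ties in score
break by higher intensity fraction, then fewer glycan residues
(parsimony), then lexicographic identifiers, so outputs are deterministic.

FDR control is target–decoy: reversed peptide sequences with the
glycosite mirrored, competing in the same search. A reversed tryptic
peptide has the same mass as its target (so it enters the same candidate
lists) and the same Y-ion series, but different backbone fragments, which
is what the score separates. q-values are the running minimum of
(#decoys/#targets) down the ranked best-hit list; accepted
identifications need q < 0.01 and a matched-intensity fraction strictly
above 0.10.

## Quantification

Reporter ratios are log2(channel/reference) with channel 114 as the
pooled reference. Glycopeptide abundance is the median over PSMs
(midpoint convention for even counts). Sample normalization subtracts the
per-sample median of the globally quantified glycoproteins, making that
subset's median exactly zero; the operation is idempotent. Z-scores and
QC coefficients of variation use the sample standard deviation (n−1) —
the population/sample choice is not dictated by any printed number, so
the common statistical default is used and stated here. Downstream
clustering uses the "complete subset": features quantified in every
sample.

## Consensus clustering

PAM is implemented directly (greedy build, best-swap iterations on a
precomputed Euclidean distance matrix, strict-improvement termination);
consensus clustering subsamples 80% of items without replacement 500
times, re-runs PAM per subsample, and averages co-clustering indicators
over co-sampling counts. Final labels cut the (1 − consensus) matrix with
average linkage — the linkage is a documented, configurable choice, since
consensus matrices do not dictate one. Per-repetition randomness uses
counter-derived streams (`default_rng([seed, rep])`), so results are
reproducible and independent of execution order. k = 3 (tumors) and
k = 5 (glycopeptide groups) are fixed, not selected.

Cluster-subtype association defaults to fold enrichment
overlap·N/(n_a·n_b) — the observed overlap over its expectation under
independence, which is the scale on which scores like 2.9 arise; a
bounded overlap²/(n_a·n_b) variant is available as `formula="literal"`.
Significance is the upper-tail hypergeometric P(X ≥ overlap).

## Survival analysis

Signature scores are per-sample means of a group's Z-scores. Extreme
strata take the 50 highest and 50 lowest scoring samples (ties broken by
sample id, deterministically). Kaplan–Meier, the two-group log-rank test
and the Cox model are delegated to lifelines; the Cox model uses the
Efron approximation for ties and enters tumor clusters as indicator
covariates against cluster 1. Curves can be reported unrestricted or
truncated at 60 months for five-year summaries; the log-rank test always
uses unrestricted follow-up. The test suite cross-checks the product-limit
arithmetic, the O−E/hypergeometric-variance statistic, and a grid-search
maximization of the partial likelihood independently of lifelines.

## Correlation analyses

All correlations are Spearman (average ranks on ties); p-values use the
t approximation with n−2 degrees of freedom and are Benjamini–Hochberg
adjusted within each analysis. Sample-wise concordance correlates paired
(glycosite peptide, parent protein) abundances within each sample;
gene-wise correlations run across samples per linked feature pair. The
enzyme analysis correlates a 22-gene glycoenzyme panel (glucosidases,
mannosidases, OST subunits, fucosyltransferases/fucosidases,
sialyltransferases, branching enzymes) against every intact glycopeptide
and bi-clusters the grid by average linkage on (1 − correlation) of the
row/column profiles. "Upregulated" glyco-genes are counted per sample as
panel genes with protein Z > 1.5 — a definition this package fixes
explicitly (and exposes as a parameter) since counting requires one.
Welch's unequal-variance t-test is used wherever two groups of samples or
correlations are compared.

## The synthetic-data generator

The generator defines the study conditions for every statistical test in
the package.

**Spectra.** Glyco spectra are assembled from the theoretical fragments
of a sampled (peptide, glycan) pair: each singly charged monoisotopic
fragment appears with probability 0.7, intensities are lognormal
(log-mean 9, log-SD 1), every peak carries uniform ±5 ppm mass jitter
(half the fragment tolerance), the oxonium marker is planted at the
filter constant with high intensity, reporters appear at 114–117, and 30
uniform noise peaks are added (steered out of the oxonium window so
filter decisions are attributable). Non-glyco spectra carry peptide
fragments and noise but no oxonium ion. Defaults are 500 + 500 spectra
over a 50-peptide database and the packaged glycan list.

**Cohort.** 119 tumors in three clusters of 27/49/43; 328 intact
glycopeptides in five groups of 26/79/85/43/95 whose glycan types follow
the fucose-only (group 1), sialylated (2), fucose+sialic (3),
high-mannose (4) and high-mannose-enriched mixture (5) recipes. A latent
per-gene signal L drives the layers: protein = L; mRNA = 0.4·L + noise;
glycosite (SPEG) = 0.8·L + noise (200 features), with extra disturbance
noise (SD 0.5) in cluster-3 samples so glycosite–protein concordance is
visibly lower there. Intact glycopeptides combine a protein loading (0.8
for complex types, 0.4 for high mannose — making complex
glycopeptide↔protein correlation higher by construction), signed
glycoenzyme effects (weight 0.35: FUT11 +/FUCA1,2 − on fucosylated,
MOGS/GANAB/PRKCSH +/MAN1A1 − on high mannose, ST3GAL1/ST6GALNAC1 + on
sialylated), a group-by-cluster mean-shift pattern (Δ = 2.5, placing
groups 3, 4, 1 high in clusters 1, 2, 3), and residual noise (SD 0.5).
Δ = 2.5 represents clearly separated molecular subtypes: planted clusters
are then recoverable essentially without error, which is the regime in
which recovery tests are informative. Enzyme abundances additionally
shift by ±0.5 in the cluster executing their program, which links low
concordance to the fucosylation program and gives cluster-specific
upregulated-gene counts. Survival times are exponential with log-hazard
0.69 per SD of the group-1 signature score plus 0.03 per year of age over
60, censored by an independent uniform(6, 120)-month administrative time;
HRD flags are Bernoulli with frequencies 0.53/0.53/0.67 by cluster, and
proteome subtype labels co-vary with clusters (Stroma/Differentiated with
the sialylation cluster, Immunoreactive/Proliferative with the
high-mannose cluster, Mesenchymal with the fucosylation cluster).

**What passing tests show — and what they do not.** The generator
produces Gaussian layers with exactly linear cross-layer structure, iid
residuals, no missing values by default, no batch effects, exponential
hazards, and spectra with well-behaved noise. Tests passing on it
demonstrate that the implementations are correct and that the pipeline
recovers structure of the planted kind at realistic dimensions; they do
not demonstrate robustness to heavy-tailed abundances, missingness
patterns, chimeric spectra, isotope-impurity effects, or any particular
real cohort's effect sizes.

## Numerical conventions and edge cases

Deterministic tie-breaks everywhere (documented per operation); empty
spectra are non-glyco rather than errors; a zero reference reporter
yields missing ratios with a warning; constant features are dropped from
Z-scoring with a warning; Spearman with fewer than three complete pairs
is missing with a warning; a log-rank test with no events returns p = 1
with a warning; Cox fits reject constant covariates and insufficient
events up front. Matrix TSVs round-trip missing values as empty cells and
values to full float precision. All simulation randomness flows from a
single master seed via counter-derived child streams.

## Problem sizes

Default test and acceptance runs use the generator's native dimensions
(119 samples × 328 glycopeptides, 500 consensus repetitions, 500 + 500
spectra) and simulation batteries of 10–200 seeds chosen so the whole
suite completes in a couple of minutes on one core while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

Compositions only (no glycan topology or linkage); N-glycans only; no
open modification search, retention-time modeling, or chimeric-spectrum
deconvolution; no isotope-impurity correction of reporter ions; no batch
correction beyond median normalization; mzML support is read-only and
covers the centroided ProteoWizard-style subset of the format; k is fixed
by design, not selected from the data.
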