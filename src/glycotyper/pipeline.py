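"""End-to-end pipeline: simulate → identify → quantify → cluster → survive → correlate.

``run_pipeline`` wires the stages together on synthetic inputs, writes
every stage's artifacts as TSV/JSON under the output directory, echoes
parameters and input/output counts to a log, and aggregates headline
outputs into a machine-readable ``summary.json``. All randomness derives
from the single master seed, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glycotyper import cluster as cl
from glycotyper import correlations as corr
from glycotyper import io as gio
from glycotyper import quant
from glycotyper import survival as surv
from glycotyper.chem import GlycanComposition
from glycotyper.ident import search_spectra
from glycotyper.simulate import (
    CohortSimConfig,
    SpectraSimConfig,
    generate_cohort,
    generate_spectra,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_SIGNATURE_GROUPS = (1, 3, 4)


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic run. Unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "glycotyper_run"
    # identification
    n_glyco_spectra: int = 500
    n_nonglyco_spectra: int = 500
    fdr_threshold: float = 0.01
    min_intensity_fraction: float = 0.10
    precursor_tol_ppm: float = 10.0
    frag_tol_ppm: float = 20.0
    # clustering
    k_samples: int = 3
    k_igp_groups: int = 5
    n_reps: int = 500
    subsample_fraction: float = 0.8
    # survival
    n_per_tail: int = 50
    # correlations
    upregulated_z_threshold: float = 1.5
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cohort = d.pop("cohort", None)
        cfg = cls(**d)
        if cohort is not None:
            cohort_known = {f.name for f in dataclasses.fields(CohortSimConfig)}
            bad = set(cohort) - cohort_known
            if bad:
                raise ValueError(f"unknown cohort keys: {sorted(bad)}")
            cfg.cohort = CohortSimConfig(**cohort)
        return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("glycotyper")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": cfg.seed, "parameters": {
        "fdr_threshold": cfg.fdr_threshold,
        "n_reps": cfg.n_reps,
        "subsample_fraction": cfg.subsample_fraction,
        "k_samples": cfg.k_samples,
        "k_igp_groups": cfg.k_igp_groups,
        "n_per_tail": cfg.n_per_tail,
        "upregulated_z_threshold": cfg.upregulated_z_threshold,
    }}
    try:
        # ------------------------------------------------------------ identify
        logger.info("stage identify: simulating %d+%d spectra (seed %d)",
                    cfg.n_glyco_spectra, cfg.n_nonglyco_spectra, cfg.seed)
        sim = generate_spectra(SpectraSimConfig(
            n_glyco_spectra=cfg.n_glyco_spectra,
            n_nonglyco_spectra=cfg.n_nonglyco_spectra,
            seed=cfg.seed,
        ))
        gio.write_spectra_jsonl(sim.spectra, out / "spectra.jsonl")
        gio.write_peptide_db(sim.peptides, out / "peptides.tsv")
        gio.write_glycan_db(sim.glycans, out / "glycans.tsv")
        sim.truth.to_csv(out / "spectra_truth.tsv", sep="\t", index=False)
        accepted, best = search_spectra(
            sim.spectra, sim.peptides, sim.glycans,
            precursor_tol_ppm=cfg.precursor_tol_ppm,
            frag_tol_ppm=cfg.frag_tol_ppm,
            fdr_threshold=cfg.fdr_threshold,
            min_intensity_fraction=cfg.min_intensity_fraction,
        )
        gio.write_psm_table(accepted, out / "psms_accepted.tsv")
        gio.write_psm_table(best, out / "psms_best_hits.tsv")
        truth = sim.truth.set_index("spectrum_id")
        n_correct = sum(
            1 for p in accepted
            if truth.loc[p.spectrum_id, "sequence"] == p.peptide.sequence
            and tuple(truth.loc[p.spectrum_id, ["hex", "hexnac", "fuc", "neuac"]])
            == p.glycan.as_tuple()
        )
        recall = n_correct / cfg.n_glyco_spectra
        fdp = 1.0 - n_correct / len(accepted) if accepted else 0.0
        summary["identification"] = {
            "n_spectra": len(sim.spectra),
            "n_accepted": len(accepted),
            "recall": round(recall, 4),
            "false_assignment_rate": round(fdp, 4),
        }
        logger.info("identify: %d accepted, recall %.3f, FDP %.4f",
                    len(accepted), recall, fdp)

        # ------------------------------------------------------------ quantify
        reporters_by_id = {s.spectrum_id: s.reporter_intensities for s in sim.spectra}
        psm_rows = []
        for p in accepted:
            ratios = quant.reporter_log2_ratios(reporters_by_id[p.spectrum_id])
            feature = f"{p.peptide.protein_id}|{p.peptide.sequence}|{p.glycan}"
            psm_rows.append({"feature_id": feature, **ratios})
        psm_table = pd.DataFrame(psm_rows)
        igp_spectra_matrix = quant.aggregate_psms(psm_table)
        gio.write_matrix(igp_spectra_matrix, out / "igp_spectra_matrix.tsv")
        summary["quantification"] = {
            "n_quantified_glycopeptides": int(igp_spectra_matrix.shape[0]),
        }

        # ------------------------------------------------------------- cohort
        logger.info("stage cohort: generating synthetic cohort")
        cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        ds = generate_cohort(cohort_cfg)
        for name, df in (("mrna", ds.mrna), ("protein", ds.protein),
                         ("speg", ds.speg), ("igp", ds.igp), ("enzymes", ds.enzymes)):
            gio.write_matrix(df, out / f"{name}_matrix.tsv")
        ds.links.to_csv(out / "igp_links.tsv", sep="\t")
        ds.annotations.to_csv(out / "annotations.tsv", sep="\t")
        ds.survival.to_csv(out / "survival.tsv", sep="\t")

        complete = quant.complete_subset(ds.igp)
        z = quant.zscore(complete)
        gio.write_matrix(z.round(6), out / "igp_zscores.tsv")

        # ------------------------------------------------------------ cluster
        logger.info("stage cluster: consensus PAM, %d reps", cfg.n_reps)
        cs = cl.consensus_cluster(z, k=cfg.k_samples, n_reps=cfg.n_reps,
                                  subsample_fraction=cfg.subsample_fraction,
                                  seed=cfg.seed, items="columns")
        cf = cl.consensus_cluster(z, k=cfg.k_igp_groups, n_reps=cfg.n_reps,
                                  subsample_fraction=cfg.subsample_fraction,
                                  seed=cfg.seed + 1, items="rows")
        cs.labels.to_csv(out / "sample_clusters.tsv", sep="\t")
        cf.labels.to_csv(out / "igp_groups.tsv", sep="\t")
        cs.consensus.round(4).to_csv(out / "sample_consensus.tsv", sep="\t")
        scores, pvals = cl.enrichment_table(
            cs.labels, ds.annotations["proteome_subtype"]
        )
        scores.round(4).to_csv(out / "enrichment_scores.tsv", sep="\t")
        pvals.apply(lambda c: c.map("{:.3e}".format)).to_csv(
            out / "enrichment_pvalues.tsv", sep="\t")
        groups = {g: list(cf.labels.index[cf.labels == g]) for g in sorted(cf.labels.unique())}
        profile = cl.group_glycan_profile(
            groups, ds.links["glycan_type"].to_dict()
        )
        profile.round(2).to_csv(out / "group_glycan_profile.tsv", sep="\t")
        summary["clustering"] = {
            "sample_cluster_sizes": cs.labels.value_counts().sort_index().to_dict(),
            "igp_group_sizes": cf.labels.value_counts().sort_index().to_dict(),
            "enrichment_scores": scores.round(4).to_dict(),
        }

        # ----------------------------------------------------------- survival
        logger.info("stage survival: extreme strata log-rank + Cox")
        survival_summary = {}
        truth_groups = ds.truth["igp_groups"]
        for g in _SIGNATURE_GROUPS:
            members = list(truth_groups.index[truth_groups == g])
            score = cl.group_signature_score(z, [m for m in members if m in z.index])
            high, low = surv.select_extremes(score, cfg.n_per_tail)
            sv = ds.survival
            chi2, p = surv.logrank_test(
                sv.loc[high, "time_months"], sv.loc[high, "event"],
                sv.loc[low, "time_months"], sv.loc[low, "event"],
            )
            km_high = surv.km_curve(sv.loc[high, "time_months"], sv.loc[high, "event"])
            km_low = surv.km_curve(sv.loc[low, "time_months"], sv.loc[low, "event"])
            km_high.round(6).to_csv(out / f"km_group{g}_high.tsv", sep="\t", index=False)
            km_low.round(6).to_csv(out / f"km_group{g}_low.tsv", sep="\t", index=False)
            survival_summary[f"group{g}_logrank_p"] = round(p, 6)
            survival_summary[f"group{g}_logrank_chi2"] = round(chi2, 4)
        cox_data = pd.concat(
            [ds.survival[["time_months", "event"]],
             ds.annotations[["age"]].astype(float),
             surv.cluster_indicators(cs.labels)], axis=1)
        cox = surv.cox_fit(cox_data)
        cox.round(6).to_csv(out / "cox_age_clusters.tsv", sep="\t")
        survival_summary["cox_age_p"] = round(float(cox.loc["age", "p"]), 6)
        summary["survival"] = survival_summary

        # ------------------------------------------------------- correlations
        logger.info("stage correlations: layer ladder + enzyme matrix")
        speg_links = dict(zip(ds.speg_links.index, ds.speg_links["protein_id"]))
        igp_links = dict(zip(ds.links.index, ds.links["protein_id"]))
        mrna_links = dict(zip(ds.links["gene_id"], ds.links["protein_id"]))
        concord = corr.sample_wise_concordance(ds.speg, ds.protein, speg_links)
        concord.round(6).to_csv(out / "sample_concordance.tsv", sep="\t")
        mp = corr.gene_wise_layer_correlation(ds.mrna, ds.protein, mrna_links)
        sp = corr.gene_wise_layer_correlation(ds.speg, ds.protein, speg_links)
        ip = corr.gene_wise_layer_correlation(ds.igp, ds.protein, igp_links)
        for name, df in (("mrna_protein", mp), ("speg_protein", sp), ("igp_protein", ip)):
            df.round(6).to_csv(out / f"corr_{name}.tsv", sep="\t")
        gt = ds.links["glycan_type"]
        grid, row_order, col_order = corr.enzyme_igp_matrix(ds.enzymes, ds.igp)
        grid.round(4).loc[row_order, col_order].to_csv(
            out / "enzyme_igp_correlations.tsv", sep="\t")
        flag_tests = {}
        flags = {
            "FUT11": gt.index[ds.links["fuc"] >= 1],
            "FUCA1": gt.index[ds.links["fuc"] >= 1],
            "MAN1A1": gt.index[gt == "high_mannose"],
            "ST3GAL1": gt.index[ds.links["neuac"] >= 1],
        }
        for gene, members in flags.items():
            flag = pd.Series(gt.index.isin(members), index=gt.index)
            t, p, med = corr.flag_correlation_compare(grid.loc[gene], flag)
            flag_tests[gene] = {"t": round(t, 4), "p": round(p, 6), **{k: round(v, 4) for k, v in med.items()}}
        # upregulated glyco genes among concordance extremes
        hi, lo = surv.select_extremes(concord, cfg.n_per_tail)
        panel_z = quant.zscore(ds.enzymes)
        counts, t_up, p_up = corr.count_upregulated(
            panel_z, hi, lo, cfg.upregulated_z_threshold)
        summary["correlations"] = {
            "median_sample_concordance": round(float(concord.median()), 4),
            "median_mrna_protein_rho": round(float(mp["rho"].median()), 4),
            "median_speg_protein_rho": round(float(sp["rho"].median()), 4),
            "median_igp_protein_rho_complex": round(
                float(ip["rho"][gt != "high_mannose"].median()), 4),
            "median_igp_protein_rho_high_mannose": round(
                float(ip["rho"][gt == "high_mannose"].median()), 4),
            "flag_tests": flag_tests,
            "upregulated_mean_high_concordance": round(float(counts[hi].mean()), 4),
            "upregulated_mean_low_concordance": round(float(counts[lo].mean()), 4),
            "upregulated_t_p": round(p_up, 6),
        }

        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        logger.info("pipeline complete; summary written to %s", out / "summary.json")
        return summary
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
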