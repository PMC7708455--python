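"""Synthetic spectra and multi-layer cohorts with planted ground truth.

Two generators emulate the inputs of the glycoproteomic analysis at desk
scale, with every latent quantity returned so downstream modules can be
scored without external data.

``generate_spectra`` builds annotated glycopeptide MS/MS spectra: each
glyco spectrum is assembled from the theoretical fragments of a sampled
(peptide, glycan) pair, subsampled at a configurable rate, with the
HexNAc oxonium peak planted among the most intense peaks, iTRAQ reporter
peaks at channels 114–117, uniform noise peaks, lognormal intensities and
ppm mass jitter. Non-glyco spectra carry peptide fragments and noise but
no oxonium ion.

``generate_cohort`` builds a 119-sample cohort with three planted tumor
clusters (27/49/43 samples) and five intact-glycopeptide groups
(26/79/85/43/95 features) whose glycan types follow the fucose-only /
fucose+sialic / high-mannose motif: a latent per-gene signal propagates to
mRNA and protein layers with a configured correlation ladder, glycosite
(SPEG) rows track their protein, and IGP rows combine the protein signal,
signed glycoenzyme effects, and cluster-specific mean shifts. Survival
times are exponential with the hazard tied to the fucose-group (group 1)
signature score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from glycotyper.chem import GlycanComposition, GlycositePeptide, classify_glycan
from glycotyper.ident import HEXNAC_OXONIUM_MZ, PROTON_MASS, Spectrum, theoretical_fragments
from glycotyper.io import load_enzyme_panel, load_glycan_db

__all__ = [
    "SpectraSimConfig",
    "CohortSimConfig",
    "SpectraSimResult",
    "CohortDataset",
    "generate_peptide_db",
    "generate_spectra",
    "generate_cohort",
]

_AA_POOL = "ACDEFGHILQVWY"  # sequon and terminus added separately


# ---------------------------------------------------------------------------
# Spectra


@dataclass
class SpectraSimConfig:
    """Conditions for the spectra generator.

    ``fragment_sampling_rate`` is the probability that a theoretical
    fragment ion appears as a peak; ``mass_jitter_ppm`` stays at or below
    half the 20 ppm fragment-matching tolerance so planted peaks remain
    matchable. ``oxonium_mz`` is planted exactly where the identification
    filter looks (the conventional 204.0966).
    """

    n_glyco_spectra: int = 500
    n_nonglyco_spectra: int = 500
    n_peptides: int = 50
    fragment_sampling_rate: float = 0.7
    noise_peaks: int = 30
    intensity_log_mean: float = 9.0
    intensity_log_sd: float = 1.0
    mass_jitter_ppm: float = 5.0
    oxonium_mz: float = HEXNAC_OXONIUM_MZ
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_sampling_rate <= 1.0:
            raise ValueError("fragment_sampling_rate must be in [0, 1]")
        if self.mass_jitter_ppm > 10.0:
            raise ValueError("mass jitter must stay within half the 20 ppm tolerance")


@dataclass
class SpectraSimResult:
    spectra: list[Spectrum]
    truth: pd.DataFrame  # one row per spectrum with the planted assignment
    peptides: list[GlycositePeptide]
    glycans: list[GlycanComposition]


def generate_peptide_db(
    n: int, rng: np.random.Generator, min_len: int = 8, max_len: int = 14
) -> list[GlycositePeptide]:
    """Random tryptic-like glycosite peptides: NxS/T sequon, K/R C-terminus."""
    peptides: list[GlycositePeptide] = []
    seen: set[str] = set()
    while len(peptides) < n:
        length = int(rng.integers(min_len, max_len + 1))
        body = rng.choice(list(_AA_POOL), size=length - 1)
        site = int(rng.integers(0, length - 3))
        body[site] = "N"
        body[site + 2] = "S" if rng.random() < 0.5 else "T"
        if body[site + 1] == "P":
            body[site + 1] = "A"
        seq = "".join(body) + ("K" if rng.random() < 0.5 else "R")
        if seq in seen or seq[::-1] in seen or seq == seq[::-1]:
            continue
        seen.add(seq)
        peptides.append(
            GlycositePeptide(
                sequence=seq,
                glycosite_index=site,
                protein_id=f"PROT{len(peptides):04d}",
            )
        )
    return peptides


def _draw_peaks(
    mz: np.ndarray, rng: np.random.Generator, cfg: SpectraSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    intensity = rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd, size=mz.size)
    jitter = rng.uniform(-cfg.mass_jitter_ppm, cfg.mass_jitter_ppm, size=mz.size) * 1e-6
    return mz * (1.0 + jitter), intensity


def _noise_peaks(
    n: int, lo: float, hi: float, rng: np.random.Generator, cfg: SpectraSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    mz = rng.uniform(lo, hi, size=n)
    # keep synthetic noise out of the oxonium window so the filter's
    # decisions are attributable to planted structure
    shift = (np.abs(mz - cfg.oxonium_mz) < 0.15)
    mz[shift] += 0.5
    intensity = rng.lognormal(cfg.intensity_log_mean - 1.0, cfg.intensity_log_sd, size=n)
    return mz, intensity


def _merge(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    keep = np.ones(mz.size, dtype=bool)
    keep[1:] = np.diff(mz) > 1e-6
    return mz[keep], intensity[keep]


def generate_spectra(cfg: SpectraSimConfig) -> SpectraSimResult:
    """Annotated glyco and non-glyco spectra, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    peptides = generate_peptide_db(cfg.n_peptides, rng)
    glycans = load_glycan_db()
    if not peptides or not glycans:
        raise ValueError("peptide and glycan databases must be non-empty")

    spectra: list[Spectrum] = []
    rows = []
    for i in range(cfg.n_glyco_spectra):
        pep = peptides[int(rng.integers(len(peptides)))]
        gly = glycans[int(rng.integers(len(glycans)))]
        z = int(rng.choice([2, 3]))
        neutral = pep.backbone_mass + gly.residue_mass
        prec_jitter = rng.uniform(-cfg.mass_jitter_ppm, cfg.mass_jitter_ppm) * 1e-6
        precursor_mz = (neutral * (1 + prec_jitter) + z * PROTON_MASS) / z

        frags = theoretical_fragments(pep, gly, max_charge=1, n_isotopes=0)
        frags = frags[frags >= 120.0]
        keep = rng.random(frags.size) < cfg.fragment_sampling_rate
        frag_mz, frag_int = _draw_peaks(frags[keep], rng, cfg)
        # plant the oxonium marker among the most intense peaks
        oxo_mz = np.array([cfg.oxonium_mz])
        oxo_int = np.array([np.exp(cfg.intensity_log_mean + 2.5 * cfg.intensity_log_sd)])
        noise_mz, noise_int = _noise_peaks(
            cfg.noise_peaks, 150.0, neutral / 2 + 300.0, rng, cfg
        )
        mz, intensity = _merge(
            np.concatenate([frag_mz, oxo_mz, noise_mz]),
            np.concatenate([frag_int, oxo_int, noise_int]),
        )
        reporters = {
            c: float(rng.lognormal(cfg.intensity_log_mean, 0.5))
            for c in ("114", "115", "116", "117")
        }
        sid = f"glyco_{i:05d}"
        spectra.append(
            Spectrum(sid, precursor_mz, z, mz, intensity, reporters)
        )
        rows.append(
            (sid, True, pep.protein_id, pep.sequence, pep.glycosite_index,
             gly.hex, gly.hexnac, gly.fuc, gly.neuac)
        )

    for i in range(cfg.n_nonglyco_spectra):
        pep = peptides[int(rng.integers(len(peptides)))]
        z = 2
        precursor_mz = (pep.backbone_mass + z * PROTON_MASS) / z
        frags = theoretical_fragments(pep, GlycanComposition(), max_charge=1, n_isotopes=0)
        frags = frags[frags >= 250.0]  # drop the oxonium set entirely
        keep = rng.random(frags.size) < cfg.fragment_sampling_rate
        frag_mz, frag_int = _draw_peaks(frags[keep], rng, cfg)
        noise_mz, noise_int = _noise_peaks(
            cfg.noise_peaks, 150.0, pep.backbone_mass / 2 + 300.0, rng, cfg
        )
        mz, intensity = _merge(
            np.concatenate([frag_mz, noise_mz]), np.concatenate([frag_int, noise_int])
        )
        reporters = {
            c: float(rng.lognormal(cfg.intensity_log_mean, 0.5))
            for c in ("114", "115", "116", "117")
        }
        sid = f"nonglyco_{i:05d}"
        spectra.append(Spectrum(sid, precursor_mz, z, mz, intensity, reporters))
        rows.append((sid, False, pep.protein_id, pep.sequence, pep.glycosite_index,
                     0, 0, 0, 0))

    truth = pd.DataFrame(
        rows,
        columns=["spectrum_id", "is_glyco", "protein_id", "sequence",
                 "glycosite_index", "hex", "hexnac", "fuc", "neuac"],
    )
    return SpectraSimResult(spectra, truth, peptides, glycans)


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class CohortSimConfig:
    """Conditions for the multi-layer cohort generator.

    Cluster and group sizes default to the reference cohort's dimensions
    (119 tumors in clusters of 27/49/43; 328 intact glycopeptides in groups
    of 26/79/85/43/95). The correlation ladder fixes the mRNA→protein and
    SPEG→protein targets at 0.4 and 0.8; intact glycopeptides load on their
    protein with 0.8 (complex glycans) or 0.4 (high mannose), so
    glycopeptide–protein concordance is higher for complex types. Group
    expression patterns place groups 3, 4 and 1 high in clusters 1, 2 and 3
    respectively. Survival hazard is exponential with log-HR
    ``survival_log_hr`` per SD of the group-1 (fucose) signature score.
    """

    cluster_sizes: tuple[int, ...] = (27, 49, 43)
    igp_group_sizes: tuple[int, ...] = (26, 79, 85, 43, 95)
    n_speg: int = 200
    mrna_protein_corr: float = 0.4
    speg_protein_corr: float = 0.8
    igp_protein_loading_complex: float = 0.8
    igp_protein_loading_highman: float = 0.4
    enzyme_effect_weight: float = 0.35
    enzyme_cluster_shift: float = 0.5
    cluster_shift: float = 2.5
    residual_sd: float = 0.5
    speg_disturbance_sd: float = 0.5
    survival_baseline_hazard: float = 0.0193  # ln 2 / 36 months
    survival_log_hr: float = 0.69  # hazard ratio 2 per SD of group-1 score
    age_log_hr: float = 0.03
    censor_low: float = 6.0
    censor_high: float = 120.0
    hrd_frequency: tuple[float, ...] = (0.53, 0.53, 0.67)  # clusters 1..3; fucose cluster high
    seed: int = 0

    # group -> glycan-type recipe; group 5 is a high-mannose-enriched mixture
    group_glycan_types: dict[int, str] = field(
        default_factory=lambda: {
            1: "fucosylated_only",
            2: "sialylated_only",
            3: "fuco_sialylated",
            4: "high_mannose",
            5: "high_mannose_mixed",
        }
    )

    @property
    def n_samples(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def n_igp(self) -> int:
        return int(sum(self.igp_group_sizes))

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.cluster_sizes + self.igp_group_sizes):
            raise ValueError("cluster and group sizes must be positive")
        if self.survival_baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if len(self.hrd_frequency) != len(self.cluster_sizes):
            raise ValueError("hrd_frequency must give one frequency per cluster")


#: Per-group expression pattern over the three tumor clusters, in units of
#: ``cluster_shift``. Groups 3, 4, 1 are the high groups of clusters 1, 2, 3.
_GROUP_PATTERNS: dict[int, tuple[float, float, float]] = {
    1: (0.0, 0.0, 1.0),
    2: (0.5, 0.0, 0.5),
    3: (1.0, 0.0, 0.0),
    4: (0.0, 1.0, 0.0),
    5: (0.0, 0.0, -1.0),
}

#: Which cluster's samples carry the coordinated enzyme shifts of each
#: glycan program (sialylation in cluster 1, high mannose in cluster 2,
#: fucosylation in cluster 3).
_ENZYME_PROGRAM_CLUSTER = {"sialylated": 1, "high_mannose": 2, "fucosylated": 3}

_PROTEOME_SUBTYPES = ["Differentiated", "Immunoreactive", "Mesenchymal", "Proliferative", "Stroma"]
_CLUSTER_SUBTYPE_WEIGHTS = {
    1: {"Stroma": 0.35, "Differentiated": 0.35},
    2: {"Immunoreactive": 0.35, "Proliferative": 0.35},
    3: {"Mesenchymal": 0.60},
}


@dataclass
class CohortDataset:
    """A generated cohort: aligned omic layers, annotations, ground truth."""

    mrna: pd.DataFrame
    protein: pd.DataFrame
    speg: pd.DataFrame
    igp: pd.DataFrame
    enzymes: pd.DataFrame
    links: pd.DataFrame
    speg_links: pd.DataFrame
    annotations: pd.DataFrame
    survival: pd.DataFrame
    truth: dict


def _glycan_pools(glycans: Sequence[GlycanComposition]) -> dict[str, list[GlycanComposition]]:
    pools: dict[str, list[GlycanComposition]] = {t: [] for t in (
        "high_mannose", "fucosylated_only", "sialylated_only",
        "fuco_sialylated", "other_complex_hybrid")}
    for g in glycans:
        pools[classify_glycan(g)].append(g)
    return pools


def _enzyme_flag_match(target_type: str, glycan: GlycanComposition) -> bool:
    if target_type == "fucosylated":
        return glycan.fuc >= 1
    if target_type == "sialylated":
        return glycan.neuac >= 1
    if target_type == "high_mannose":
        return classify_glycan(glycan) == "high_mannose"
    return False


def generate_cohort(cfg: CohortSimConfig) -> CohortDataset:
    """Generate the multi-layer cohort; byte-deterministic per config+seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:03d}" for i in range(n)]
    cluster_of = np.repeat(
        np.arange(1, len(cfg.cluster_sizes) + 1), cfg.cluster_sizes
    )
    # shuffle so cluster membership is not confounded with sample order
    perm = rng.permutation(n)
    cluster_of = cluster_of[perm]

    group_of = np.repeat(np.arange(1, 6), cfg.igp_group_sizes)
    n_igp = cfg.n_igp
    igp_ids = [f"IGP{i:04d}" for i in range(n_igp)]
    gene_ids = [f"GENE{i:04d}" for i in range(n_igp)]
    protein_ids = [f"PROT{i:04d}" for i in range(n_igp)]

    glycan_pools = _glycan_pools(load_glycan_db())
    glycan_of: list[GlycanComposition] = []
    for g in group_of:
        recipe = cfg.group_glycan_types[int(g)]
        if recipe == "high_mannose_mixed":
            pool_name = "high_mannose" if rng.random() < 0.6 else "other_complex_hybrid"
        else:
            pool_name = recipe
        pool = glycan_pools[pool_name]
        glycan_of.append(pool[int(rng.integers(len(pool)))])

    # latent per-gene signal and the mRNA / protein / SPEG layers
    latent = rng.standard_normal((n_igp, n))
    protein = latent.copy()
    rho_m = cfg.mrna_protein_corr
    mrna = rho_m * latent + np.sqrt(1 - rho_m**2) * rng.standard_normal((n_igp, n))

    speg_idx = np.arange(min(cfg.n_speg, n_igp))
    rho_s = cfg.speg_protein_corr
    speg = rho_s * latent[speg_idx] + np.sqrt(1 - rho_s**2) * rng.standard_normal(
        (speg_idx.size, n)
    )
    # glycan-driven disturbance lowers SPEG<->protein concordance in the
    # fucose-program cluster (cluster 3)
    disturbed = cluster_of == _ENZYME_PROGRAM_CLUSTER["fucosylated"]
    speg[:, disturbed] += cfg.speg_disturbance_sd * rng.standard_normal(
        (speg_idx.size, int(disturbed.sum()))
    )

    # glycoenzyme panel (protein level) with coordinated per-cluster shifts
    panel = load_enzyme_panel()
    enzymes = rng.standard_normal((len(panel), n))
    for e, (gene, row) in enumerate(panel.iterrows()):
        sign = int(row["default_sign"])
        program = str(row["target_type"])
        if sign and program in _ENZYME_PROGRAM_CLUSTER:
            in_cluster = cluster_of == _ENZYME_PROGRAM_CLUSTER[program]
            enzymes[e, in_cluster] += sign * cfg.enzyme_cluster_shift

    # intact glycopeptides: protein loading + signed enzyme effects +
    # cluster-specific group pattern + residual noise
    igp = np.empty((n_igp, n))
    effect_signs = panel["default_sign"].to_numpy(dtype=float)
    for f in range(n_igp):
        gly = glycan_of[f]
        gtype = classify_glycan(gly)
        rho_g = (
            cfg.igp_protein_loading_highman
            if gtype == "high_mannose"
            else cfg.igp_protein_loading_complex
        )
        affected = np.array(
            [
                _enzyme_flag_match(str(t), gly) and s != 0
                for t, s in zip(panel["target_type"], effect_signs)
            ]
        )
        enzyme_term = (effect_signs[affected] @ enzymes[affected]) if affected.any() else 0.0
        pattern = np.array(_GROUP_PATTERNS[int(group_of[f])])[cluster_of - 1]
        igp[f] = (
            rho_g * latent[f]
            + cfg.enzyme_effect_weight * enzyme_term
            + cfg.cluster_shift * pattern
            + cfg.residual_sd * rng.standard_normal(n)
        )

    # clinical annotations
    age = np.clip(rng.normal(60.0, 10.0, size=n), 30.0, 90.0)
    hrd = np.array(
        [rng.random() < cfg.hrd_frequency[c - 1] for c in cluster_of], dtype=int
    )
    subtypes = []
    for c in cluster_of:
        weights = np.full(len(_PROTEOME_SUBTYPES), 1.0)
        favored = _CLUSTER_SUBTYPE_WEIGHTS[int(c)]
        total_favor = sum(favored.values())
        rest = (1.0 - total_favor) / (len(_PROTEOME_SUBTYPES) - len(favored))
        probs = np.array(
            [favored.get(s, rest) for s in _PROTEOME_SUBTYPES]
        )
        subtypes.append(_PROTEOME_SUBTYPES[int(rng.choice(len(probs), p=probs / probs.sum()))])

    # survival tied to the group-1 (fucose) signature score
    igp_df = pd.DataFrame(igp, index=igp_ids, columns=sample_ids)
    group1 = [igp_ids[i] for i in range(n_igp) if group_of[i] == 1]
    z = igp_df.sub(igp_df.mean(axis=1), axis=0).div(igp_df.std(axis=1, ddof=1), axis=0)
    score = z.loc[group1].mean(axis=0)
    score_std = (score - score.mean()) / score.std(ddof=1)
    rate = cfg.survival_baseline_hazard * np.exp(
        cfg.survival_log_hr * score_std.to_numpy()
        + cfg.age_log_hr * (age - 60.0)
    )
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(cfg.censor_low, cfg.censor_high, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    links = pd.DataFrame(
        {
            "feature_id": igp_ids,
            "protein_id": protein_ids,
            "gene_id": gene_ids,
            "hex": [g.hex for g in glycan_of],
            "hexnac": [g.hexnac for g in glycan_of],
            "fuc": [g.fuc for g in glycan_of],
            "neuac": [g.neuac for g in glycan_of],
            "glycan_type": [classify_glycan(g) for g in glycan_of],
            "group": group_of,
        }
    ).set_index("feature_id")

    speg_ids = [f"SPEG{i:04d}" for i in speg_idx]
    speg_links = pd.DataFrame(
        {
            "feature_id": speg_ids,
            "protein_id": [protein_ids[i] for i in speg_idx],
            "gene_id": [gene_ids[i] for i in speg_idx],
        }
    ).set_index("feature_id")

    annotations = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "proteome_subtype": subtypes,
            "hrd": hrd,
            "age": np.round(age, 1),
        }
    ).set_index("sample_id")

    survival = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time_months": np.round(time, 3),
            "event": event,
        }
    ).set_index("sample_id")

    truth = {
        "sample_clusters": pd.Series(cluster_of, index=sample_ids, name="cluster"),
        "igp_groups": pd.Series(group_of, index=igp_ids, name="group"),
        "group1_score": score,
        "config": cfg,
    }

    return CohortDataset(
        mrna=pd.DataFrame(mrna, index=gene_ids, columns=sample_ids),
        protein=pd.DataFrame(protein, index=protein_ids, columns=sample_ids),
        speg=pd.DataFrame(speg, index=speg_ids, columns=sample_ids),
        igp=igp_df,
        enzymes=pd.DataFrame(enzymes, index=list(panel.index), columns=sample_ids),
        links=links,
        speg_links=speg_links,
        annotations=annotations,
        survival=survival,
        truth=truth,
    )
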