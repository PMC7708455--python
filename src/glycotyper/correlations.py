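"""Multi-layer correlation analyses.

Three families of Spearman analyses connect the omic layers:

* sample-wise concordance — for each tumor, the correlation across paired
  (glycosite peptide, parent glycoprotein) abundances; low concordance
  marks samples whose glycosylation is perturbed beyond substrate supply;
* gene-wise layer correlation — per feature, the correlation across
  samples between two layers (mRNA vs protein, glycosite vs protein,
  intact glycopeptide vs protein), with Benjamini–Hochberg adjustment and
  glycan-type stratified medians;
* enzyme–glycopeptide matrix — the glycoenzyme panel (protein level)
  against every intact glycopeptide, bi-clustered, with per-enzyme
  comparisons of correlations between glycan-flag groups.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr, ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman",
    "sample_wise_concordance",
    "gene_wise_layer_correlation",
    "enzyme_igp_matrix",
    "flag_correlation_compare",
    "count_upregulated",
]


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties), NaN-pair aware.

    Fewer than 3 complete pairs yields NaN with a warning rather than an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 complete pairs; Spearman rho is NaN", stacklevel=2)
        return float("nan")
    rho = spearmanr(x[ok], y[ok]).statistic
    return float(rho)


def sample_wise_concordance(
    layer_a: pd.DataFrame,
    layer_b: pd.DataFrame,
    links: Mapping[str, str],
) -> pd.Series:
    """Per-sample Spearman correlation across linked feature pairs.

    ``links`` maps features of ``layer_a`` (e.g. glycosite peptides) to
    features of ``layer_b`` (e.g. their parent glycoproteins). Samples
    missing from either layer are skipped with a warning.
    """
    pairs = [(f, p) for f, p in links.items() if f in layer_a.index and p in layer_b.index]
    if not pairs:
        raise ValueError("no linked feature pairs present in both layers")
    a_idx = [f for f, _ in pairs]
    b_idx = [p for _, p in pairs]
    shared = [s for s in layer_a.columns if s in layer_b.columns]
    skipped = set(layer_a.columns).symmetric_difference(layer_b.columns)
    if skipped:
        warnings.warn(f"skipping {len(skipped)} sample(s) absent from one layer", stacklevel=2)
    out = {}
    A = layer_a.loc[a_idx, shared].to_numpy()
    B = layer_b.loc[b_idx, shared].to_numpy()
    for j, s in enumerate(shared):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[s] = spearman(A[:, j], B[:, j])
    return pd.Series(out, name="rho")


def gene_wise_layer_correlation(
    layer_a: pd.DataFrame,
    layer_b: pd.DataFrame,
    links: Mapping[str, str],
) -> pd.DataFrame:
    """Per-feature Spearman across samples between two layers, BH-adjusted.

    Returns a DataFrame indexed by layer-A feature with columns ``rho``,
    ``p`` (two-sided t approximation, n-2 df) and ``q`` (Benjamini–
    Hochberg). Features without a counterpart or with <3 shared samples
    are dropped.
    """
    shared = [s for s in layer_a.columns if s in layer_b.columns]
    rows = []
    for f, p in links.items():
        if f not in layer_a.index or p not in layer_b.index:
            continue
        x = layer_a.loc[f, shared].to_numpy(dtype=float)
        y = layer_b.loc[p, shared].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3:
            continue
        res = spearmanr(x[ok], y[ok])
        rows.append((f, p, float(res.statistic), float(res.pvalue), n))
    if not rows:
        raise ValueError("no feature pair with at least 3 shared samples")
    out = pd.DataFrame(rows, columns=["feature_id", "partner_id", "rho", "p", "n"])
    out = out.set_index("feature_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def enzyme_igp_matrix(
    enzymes: pd.DataFrame, igp: pd.DataFrame
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Enzyme x glycopeptide Spearman grid with bi-cluster orderings.

    Returns the rho grid (enzymes as rows) plus average-linkage leaf
    orderings of rows and columns on (1 - rho) distance.
    """
    shared = [s for s in enzymes.columns if s in igp.columns]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    E = np.apply_along_axis(rankdata, 1, enzymes[shared].to_numpy(dtype=float))
    G = np.apply_along_axis(rankdata, 1, igp[shared].to_numpy(dtype=float))

    def _std(R: np.ndarray) -> np.ndarray:
        R = R - R.mean(axis=1, keepdims=True)
        norm = np.sqrt((R**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = 1.0
        return R / norm

    rho = _std(E) @ _std(G).T
    grid = pd.DataFrame(rho, index=enzymes.index, columns=igp.index)

    def _order(M: np.ndarray, ids: Sequence[str]) -> list[str]:
        if M.shape[0] < 3:
            return list(ids)
        corr = np.nan_to_num(np.corrcoef(M), nan=0.0)  # constant profiles -> distance 1
        np.fill_diagonal(corr, 1.0)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        leaves = leaves_list(average(squareform(d, checks=False)))
        return [ids[i] for i in leaves]

    row_order = _order(grid.to_numpy(), list(grid.index))
    col_order = _order(grid.to_numpy().T, list(grid.columns))
    return grid, row_order, col_order


def flag_correlation_compare(
    rho: pd.Series, flag: pd.Series
) -> tuple[float, float, dict[str, float]]:
    """Welch t-test of correlation values between flagged and unflagged IGPs.

    Returns (t, p, {"flagged": median, "unflagged": median}).
    """
    shared = rho.index.intersection(flag.index)
    r = rho[shared].astype(float)
    f = flag[shared].astype(bool)
    a = r[f]
    b = r[~f]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both flag groups need at least 2 values")
    medians = {"flagged": float(a.median()), "unflagged": float(b.median())}
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        warnings.warn("degenerate variance in both groups", stacklevel=2)
        if a.mean() == b.mean():
            return 0.0, 1.0, medians
        return float("inf"), 0.0, medians
    t, p = ttest_ind(a, b, equal_var=False)
    return float(t), float(p), medians


def count_upregulated(
    panel_z: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
    threshold: float = 1.5,
) -> tuple[pd.Series, float, float]:
    """Per-sample count of panel genes with Z above threshold, plus t-test.

    ``panel_z`` is a Z-scored protein matrix restricted to the glyco-gene
    panel. Returns the per-sample counts over the union of both sets and
    the Welch t statistic / p-value comparing set A against set B.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both sample sets must be non-empty")
    counts = (panel_z > threshold).sum(axis=0)
    a = counts[set_a].astype(float)
    b = counts[set_b].astype(float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    else:
        t, p = ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    return counts[set_a + set_b], t, p
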