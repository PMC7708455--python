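"""Consensus PAM clustering and cluster/subtype association statistics.

Tumor samples are partitioned into k=3 clusters and intact-glycopeptide
features into k=5 groups by consensus clustering: the item pool is
repeatedly subsampled (80%, without replacement, 500 times), each subsample
is partitioned with PAM (k-medoids, build+swap, Euclidean distance on
Z-scores), and the co-clustering proportion matrix is cut with
average-linkage hierarchical clustering to produce final labels.

Cluster-to-subtype association is summarized by a fold-enrichment score
with an upper-tail hypergeometric p-value, glycan-type percentage profiles
per feature group, and per-sample group signature scores (mean Z of the
group's features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, ttest_ind
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import pairwise_distances

__all__ = [
    "pam",
    "ConsensusClustering",
    "ClusterResult",
    "consensus_cluster",
    "enrichment_score",
    "overlap_pvalue",
    "group_glycan_profile",
    "group_signature_score",
    "annotation_frequency_compare",
]


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        # gain of adding candidate j: sum of reductions over all points
        gains = np.maximum(current[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def pam(D: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Partitioning around medoids (build + swap) on a distance matrix.

    Deterministic: the build step is greedy and swaps are applied
    first-improvement-free (best swap per sweep). Returns integer labels
    0..k-1 in order of medoid index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of items n={n}")
    medoids = _pam_build(D, k)
    for _ in range(max_iter):
        best_delta = 1e-10  # require strict improvement to guarantee termination
        best_swap = None
        dist_to_medoids = D[:, medoids]  # (n, k)
        cost = dist_to_medoids.min(axis=1).sum()
        for mi in range(len(medoids)):
            others = [m for j, m in enumerate(medoids) if j != mi]
            d_without = D[:, others].min(axis=1) if others else np.full(n, np.inf)
            # cost if medoid mi is replaced by each candidate x (vectorized)
            cand_cost = np.minimum(d_without[:, None], D).sum(axis=0)
            cand_cost[medoids] = np.inf
            x = int(np.argmin(cand_cost))
            delta = cost - cand_cost[x]
            if delta > best_delta:
                best_delta = delta
                best_swap = (mi, x)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids_sorted = sorted(medoids)
    return np.argmin(D[:, medoids_sorted], axis=1)


@dataclass
class ClusterResult:
    """Consensus clustering output for one item set."""

    item_ids: list[str]
    labels: pd.Series  # item -> cluster index in 1..k
    consensus: pd.DataFrame  # item x item co-clustering proportions
    k: int
    n_reps: int
    subsample_fraction: float
    seed: int


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """Consensus PAM clustering, scikit-learn style.

    Parameters
    ----------
    k : number of clusters.
    n_reps : number of subsampling repetitions (default 500).
    subsample_fraction : fraction of items drawn without replacement per
        repetition (default 0.8).
    seed : master seed; each repetition uses the counter-derived stream
        ``default_rng([seed, rep])`` so runs are reproducible and
        parallel-safe.

    Attributes (after ``fit``)
    --------------------------
    labels_ : ndarray of cluster indices 1..k.
    consensus_ : (n, n) co-clustering proportion matrix (diagonal 1).
    """

    def __init__(
        self,
        k: int = 3,
        n_reps: int = 500,
        subsample_fraction: float = 0.8,
        seed: int = 0,
        metric: str = "euclidean",
    ) -> None:
        self.k = k
        self.n_reps = n_reps
        self.subsample_fraction = subsample_fraction
        self.seed = seed
        self.metric = metric

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2D items x dimensions array")
        n = X.shape[0]
        if self.k >= n:
            raise ValueError(f"k={self.k} must be < number of items {n}")
        D = pairwise_distances(X, metric=self.metric)
        m = int(np.ceil(self.subsample_fraction * n))
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for rep in range(self.n_reps):
            rng = np.random.default_rng([self.seed, rep])
            idx = np.sort(rng.choice(n, size=m, replace=False))
            labels = pam(D[np.ix_(idx, idx)], self.k)
            same = labels[:, None] == labels[None, :]
            co_sample[np.ix_(idx, idx)] += 1
            co_cluster[np.ix_(idx, idx)] += same
        never = (co_sample + np.eye(n) == 0).all(axis=1)
        if never.any():
            raise ValueError(
                f"{int(never.sum())} item(s) never co-sampled; increase n_reps"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0

        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        Z = average(squareform(dist, checks=False))
        raw = fcluster(Z, t=self.k, criterion="maxclust")
        # relabel 1..k by first appearance for determinism
        remap: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i, r in enumerate(raw):
            if r not in remap:
                remap[r] = len(remap) + 1
            labels[i] = remap[r]
        self.labels_ = labels
        self.consensus_ = consensus
        self.n_features_in_ = X.shape[1]
        return self


def consensus_cluster(
    matrix: pd.DataFrame,
    k: int,
    n_reps: int = 500,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    items: str = "columns",
) -> ClusterResult:
    """Consensus-cluster the samples (columns) or features (rows) of a matrix.

    ``matrix`` is a Z-scored, complete-subset abundance matrix (features x
    samples). ``items="columns"`` clusters samples (the k=3 tumor
    clustering); ``items="rows"`` clusters features (the k=5 glycopeptide
    grouping).
    """
    if items == "columns":
        X = matrix.T.to_numpy()
        ids = list(matrix.columns)
    elif items == "rows":
        X = matrix.to_numpy()
        ids = list(matrix.index)
    else:
        raise ValueError("items must be 'columns' or 'rows'")
    est = ConsensusClustering(
        k=k, n_reps=n_reps, subsample_fraction=subsample_fraction, seed=seed
    ).fit(X)
    return ClusterResult(
        item_ids=ids,
        labels=pd.Series(est.labels_, index=ids, name="cluster"),
        consensus=pd.DataFrame(est.consensus_, index=ids, columns=ids),
        k=k,
        n_reps=n_reps,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def enrichment_score(
    overlap: int, n_a: int, n_b: int, n_total: int, formula: str = "fold"
) -> float:
    """Association score between two sample categories.

    ``fold`` (default) is the fold enrichment ``overlap * N / (n_a * n_b)``
    — the observed overlap over its expectation under independence.
    ``literal`` is ``overlap**2 / (n_a * n_b)``, an alternative bounded-by-1
    normalization.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("category sizes must be positive")
    if not 0 <= overlap <= min(n_a, n_b) <= n_total:
        raise ValueError("inconsistent contingency counts")
    if formula == "fold":
        return overlap * n_total / (n_a * n_b)
    if formula == "literal":
        return overlap**2 / (n_a * n_b)
    raise ValueError(f"unknown formula {formula!r}")


def overlap_pvalue(overlap: int, n_a: int, n_b: int, n_total: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap).

    X counts category-A samples in a draw of ``n_b`` from ``n_total`` with
    ``n_a`` successes.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("category sizes must be positive")
    if not 0 <= overlap <= min(n_a, n_b) <= n_total:
        raise ValueError("inconsistent contingency counts")
    return float(hypergeom.sf(overlap - 1, n_total, n_a, n_b))


def enrichment_table(
    labels_a: pd.Series, labels_b: pd.Series, formula: str = "fold"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and p-value grids for every (cluster, subtype) pair.

    Both series are indexed by sample id; only shared samples are used.
    """
    shared = labels_a.index.intersection(labels_b.index)
    a = labels_a[shared]
    b = labels_b[shared]
    n_total = len(shared)
    cats_a = sorted(a.unique(), key=str)
    cats_b = sorted(b.unique(), key=str)
    scores = pd.DataFrame(index=cats_a, columns=cats_b, dtype=float)
    pvals = pd.DataFrame(index=cats_a, columns=cats_b, dtype=float)
    for ca in cats_a:
        for cb in cats_b:
            overlap = int(((a == ca) & (b == cb)).sum())
            n_a = int((a == ca).sum())
            n_b = int((b == cb).sum())
            scores.loc[ca, cb] = enrichment_score(overlap, n_a, n_b, n_total, formula)
            pvals.loc[ca, cb] = overlap_pvalue(overlap, n_a, n_b, n_total)
    return scores, pvals


def group_glycan_profile(
    groups: Mapping[int, Sequence[str]], glycan_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Glycan-type percentage composition of each feature group.

    Rows are groups, columns glycan-type labels; each row sums to 100.
    """
    from glycotyper.chem import GLYCAN_TYPES

    rows = {}
    for group, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {group} is empty")
        missing = [m for m in members if m not in glycan_labels]
        if missing:
            raise ValueError(f"unlabeled members in group {group}: {missing[:5]}")
        counts = pd.Series([glycan_labels[m] for m in members]).value_counts()
        rows[group] = 100.0 * counts.reindex(GLYCAN_TYPES, fill_value=0) / len(members)
    return pd.DataFrame(rows).T


def group_signature_score(
    z_matrix: pd.DataFrame, group_members: Sequence[str]
) -> pd.Series:
    """Per-sample signature score: mean Z over the group's features."""
    members = list(group_members)
    if not members:
        raise ValueError("group is empty")
    missing = [m for m in members if m not in z_matrix.index]
    if missing:
        raise ValueError(f"features absent from matrix: {missing}")
    return z_matrix.loc[members].mean(axis=0)


def annotation_frequency_compare(
    cluster_labels: pd.Series,
    flag: pd.Series,
    group_a: Sequence[int],
    group_b: Sequence[int],
) -> tuple[pd.Series, float, float]:
    """Per-cluster flag frequency plus a Welch t-test between cluster sets.

    The test compares the per-sample flag values (0/1) of samples in
    ``group_a`` clusters against those in ``group_b`` clusters.
    """
    shared = cluster_labels.index.intersection(flag.index)
    cl = cluster_labels[shared]
    fl = flag[shared].astype(float)
    freq = fl.groupby(cl).mean()
    a = fl[cl.isin(group_a)]
    b = fl[cl.isin(group_b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each compared group needs at least 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        warnings.warn("degenerate variance in both groups", stacklevel=2)
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = ttest_ind(a, b, equal_var=False)
    return freq, float(t), float(p)
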