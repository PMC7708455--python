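"""iTRAQ reporter quantification, normalization, Z-scoring, and QC CVs.

Abundance matrices are plain pandas DataFrames with features as rows and
samples as columns, holding log2 ratios to the pooled reference channel;
missing values are NaN. Quantification follows the standard iTRAQ scheme:
per-PSM log2 reporter ratios against the reference channel (114 by
convention), the per-glycopeptide abundance as the median over its PSMs,
then per-sample centering on the median of the globally quantified
glycoproteins.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "reporter_log2_ratios",
    "aggregate_psms",
    "complete_subset",
    "normalize_to_global",
    "zscore",
    "qc_cv",
]

REFERENCE_CHANNEL = "114"


def reporter_log2_ratios(
    reporters: Mapping[str, float],
    reference_channel: str = REFERENCE_CHANNEL,
) -> dict[str, float]:
    """log2(channel / reference) for every non-reference channel.

    A non-positive (or absent) reference intensity yields NaN ratios with a
    warning rather than an error; non-positive sample channels yield NaN for
    that channel only.
    """
    ref = reporters.get(reference_channel, 0.0)
    channels = [c for c in reporters if c != reference_channel]
    if ref is None or not np.isfinite(ref) or ref <= 0:
        warnings.warn(
            f"non-positive reference channel {reference_channel}; ratios set to NaN",
            stacklevel=2,
        )
        return {c: float("nan") for c in channels}
    out = {}
    for c in channels:
        v = reporters[c]
        out[c] = float(np.log2(v / ref)) if v and v > 0 else float("nan")
    return out


def aggregate_psms(psm_table: pd.DataFrame, feature_col: str = "feature_id") -> pd.DataFrame:
    """Per-glycopeptide abundance as the median log2 ratio over its PSMs.

    ``psm_table`` has one row per PSM with a ``feature_col`` identifier and
    one column per sample/channel. Medians use the midpoint convention for
    even counts and ignore NaN.
    """
    value_cols = [c for c in psm_table.columns if c != feature_col]
    grouped = psm_table.groupby(feature_col, sort=True)[value_cols].median()
    grouped.index.name = "feature_id"
    return grouped


def complete_subset(matrix: pd.DataFrame) -> pd.DataFrame:
    """Features quantified in every sample (no missing values), logged."""
    out = matrix.dropna(axis=0, how="any")
    logger.info(
        "complete subset: %d of %d features quantified in all %d samples",
        out.shape[0], matrix.shape[0], matrix.shape[1],
    )
    return out


def normalize_to_global(
    matrix: pd.DataFrame, global_medians: pd.Series
) -> pd.DataFrame:
    """Subtract the per-sample median of the global glycoprotein set.

    After normalization the per-sample median of the set that defined
    ``global_medians`` is zero. A sample missing from ``global_medians``
    is an error.
    """
    missing = [s for s in matrix.columns if s not in global_medians.index]
    if missing:
        raise ValueError(f"no global median for samples: {missing}")
    return matrix.sub(global_medians[matrix.columns], axis=1)


def zscore(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-feature standardization: (x - mean) / SD over non-missing entries.

    Sample SD (ddof=1) by default. Features with zero SD are dropped with a
    warning.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    degenerate = (sd == 0) | sd.isna()
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} constant feature(s) from Z-scoring",
            stacklevel=2,
        )
    kept = matrix.loc[~degenerate]
    return kept.sub(mean[~degenerate], axis=0).div(sd[~degenerate], axis=0)


def qc_cv(
    replicates: pd.DataFrame, ddof: int = 1
) -> tuple[pd.Series, dict[str, float]]:
    """Per-feature coefficient of variation (%) across QC replicates.

    ``replicates`` holds linear-scale intensities, one row per feature and
    one column per replicate (>= 2 required). Features with non-positive
    mean are skipped. Returns the CV series and a summary dict with the
    median and inter-quartile range over features.
    """
    if replicates.shape[1] < 2:
        raise ValueError("qc_cv requires at least 2 replicates")
    mean = replicates.mean(axis=1)
    sd = replicates.std(axis=1, ddof=ddof)
    valid = mean > 0
    if (~valid).any():
        logger.warning("qc_cv: skipping %d feature(s) with non-positive mean", int((~valid).sum()))
    cv = (sd[valid] / mean[valid]) * 100.0
    q1, q3 = np.nanpercentile(cv.to_numpy(), [25, 75]) if len(cv) else (np.nan, np.nan)
    summary = {"median_cv_pct": float(np.nanmedian(cv.to_numpy())) if len(cv) else float("nan"),
               "iqr_cv_pct": float(q3 - q1) if len(cv) else float("nan")}
    return cv, summary
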