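"""Survival machinery: extreme-score strata, Kaplan–Meier, log-rank, Cox.

The signature-based survival analysis takes a per-sample score (mean Z of
an intact-glycopeptide group), selects the 50 highest- and 50 lowest-score
samples, compares their overall survival with the Kaplan–Meier estimator
and the two-group log-rank test, and adjusts for age and tumor cluster with
a Cox proportional-hazards model (Efron handling of ties). Estimation is
delegated to lifelines, the same library the field uses for these fits.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "select_extremes",
    "km_curve",
    "logrank_test",
    "cox_fit",
]


def select_extremes(
    scores: pd.Series, n_per_tail: int = 50
) -> tuple[list[str], list[str]]:
    """Disjoint top-n and bottom-n sample sets by score.

    Ties are broken by sample id so the split is deterministic; an
    all-equal score vector still yields a valid (id-ordered) split with a
    warning.
    """
    if 2 * n_per_tail > len(scores):
        raise ValueError(
            f"2 x {n_per_tail} extremes exceed cohort size {len(scores)}"
        )
    if scores.nunique() == 1:
        warnings.warn("all scores equal; extreme split is id-ordered", stacklevel=2)
    order = scores.reset_index()
    order.columns = ["sample_id", "score"]
    order = order.sort_values(["score", "sample_id"], ascending=[False, True])
    high = sorted(order["sample_id"].iloc[:n_per_tail].tolist())
    low = sorted(order["sample_id"].iloc[-n_per_tail:].tolist())
    return high, low


def km_curve(
    times: Sequence[float], events: Sequence[int], max_months: float | None = None
) -> pd.DataFrame:
    """Product-limit survival curve as a (time, survival) step table.

    Right-continuous, S(0)=1, non-increasing. ``max_months`` optionally
    truncates the curve (e.g. at 60 months for 5-year summaries).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_curve requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    out = pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )
    if max_months is not None:
        out = out[out["time"] <= max_months].reset_index(drop=True)
    return out


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    With no observed events in either group the test is undefined and
    (0.0, 1.0) is returned with a warning.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() == 0 and eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) of all remaining columns.

    Returns a per-covariate table with columns ``coef``, ``ci_lower``,
    ``ci_upper`` (95% Wald), and ``p``. Constant covariates and
    insufficient events are rejected up front; lifelines convergence
    errors propagate with their diagnostics.
    """
    covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    if not covariates:
        raise ValueError("no covariate columns")
    for c in covariates:
        if data[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant across samples")
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    summary = cph.summary
    return pd.DataFrame(
        {
            "coef": summary["coef"],
            "ci_lower": summary["coef lower 95%"],
            "ci_upper": summary["coef upper 95%"],
            "p": summary["p"],
        }
    )


def cluster_indicators(labels: pd.Series, reference: int | str = 1) -> pd.DataFrame:
    """Indicator covariates for cluster membership against a reference cluster."""
    cats = sorted(labels.unique(), key=str)
    if reference not in cats:
        raise ValueError(f"reference cluster {reference!r} not among {cats}")
    out = {}
    for c in cats:
        if c == reference:
            continue
        out[f"cluster_{c}"] = (labels == c).astype(float)
    return pd.DataFrame(out, index=labels.index)
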