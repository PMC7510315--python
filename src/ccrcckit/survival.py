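"""Kaplan-Meier estimation, median survival and multi-group log-rank tests.

Survival stratification of the classified cohorts: product-limit curves per
group, median survival (first time the curve reaches 0.5), the standard
multi-group log-rank chi-square with ``groups - 1`` degrees of freedom, and
the combined class x immune-phenotype stratification (up to 9 groups for a
3 x 3 design).  Estimation and testing are delegated to lifelines; ties at
an event time use the usual simultaneous-risk-set convention and no
continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "km_curve",
    "median_survival",
    "logrank_test",
    "combine_groups",
    "plot_km",
]


@dataclass
class SurvivalCurve:
    """Step function of the product-limit estimator for one group."""

    times: np.ndarray  # distinct observed times (events and censorings)
    survival: np.ndarray  # S(t) just after each time; starts from S(0)=1
    at_risk: np.ndarray  # risk-set size just before each time

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if ((s < -1e-12) | (s > 1 + 1e-12)).any() or (np.diff(s) > 1e-12).any():
            raise ValueError("survival probabilities must be non-increasing in [0, 1]")


def _check_data(data: pd.DataFrame) -> pd.DataFrame:
    if not {"time_days", "event"}.issubset(data.columns):
        raise ValueError("survival data needs 'time_days' and 'event' columns")
    if (data["time_days"] < 0).any():
        raise ValueError("negative follow-up time")
    if not data["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return data


def km_curve(data: pd.DataFrame) -> SurvivalCurve:
    """Product-limit curve for one group of (time_days, event) rows."""
    data = _check_data(data)
    if len(data) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time_days"], data["event"])
    times = kmf.survival_function_.index.to_numpy()[1:]
    surv = kmf.survival_function_["KM_estimate"].to_numpy()[1:]
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk)


def median_survival(curve: SurvivalCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None when never reached."""
    below = np.flatnonzero(curve.survival <= 0.5 + 1e-12)
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank_test(data: pd.DataFrame, group_col: str = "group") -> LogRankResult:
    """Multi-group log-rank test (chi-square, df = groups - 1)."""
    data = _check_data(data)
    groups = data[group_col]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups")
    if int(data["event"].sum()) == 0:
        raise ValueError("log-rank test refused: no events observed")
    res = multivariate_logrank_test(data["time_days"], groups, data["event"])
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=int(groups.nunique() - 1),
        p=float(res.p_value),
    )


def combine_groups(class_labels: pd.Series, immune_labels: pd.Series) -> pd.Series:
    """Cartesian-product label per sample, e.g. ``"2|active"``.

    Only occupied cells appear; a 3-class x 3-phenotype design yields at most
    9 groups.
    """
    class_labels, immune_labels = pd.Series(class_labels), pd.Series(immune_labels)
    if set(class_labels.index) != set(immune_labels.index):
        raise ValueError("labelings cover different samples")
    immune_labels = immune_labels.loc[class_labels.index]
    return pd.Series(
        [f"{c}|{i}" for c, i in zip(class_labels, immune_labels)],
        index=class_labels.index,
        name="combined_group",
    )


def plot_km(data: pd.DataFrame, group_col: str = "group", path: str | None = None):
    """Minimal KM plot per group; returns the matplotlib axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _check_data(data)
    fig, ax = plt.subplots()
    for g, sub in data.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], sub["event"], label=str(g))
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return ax
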