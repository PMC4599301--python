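"""Kaplan–Meier estimation and log-rank comparison by EZH2 IHC expression.

Patients are dichotomized on the raw percentage of tumor cells stained
for EZH2 (< 70% = EZH2-low, >= 70% = EZH2-high; the cutoff follows prior
DLBCL work) and overall / progression-free survival is compared between
the groups with the product-limit estimator and the log-rank test,
typically within cell-of-origin subtypes. Ties between events and
censorings at the same time are resolved events-first (the standard
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .exceptions import ValidationError
from .stats import TestResult


class Ezh2Group(str, Enum):
    LOW = "EZH2_low"
    HIGH = "EZH2_high"


DEFAULT_EXPRESSION_CUTOFF = 70.0  # percent of tumor cells stained


def dichotomize_ezh2(
    percent_stained: Optional[float], cutoff: float = DEFAULT_EXPRESSION_CUTOFF
) -> Optional[Ezh2Group]:
    """EZH2-low iff percent stained < cutoff; None (excluded) when missing."""
    if percent_stained is None or (
        isinstance(percent_stained, float) and np.isnan(percent_stained)
    ):
        warnings.warn("missing percent stained; patient excluded from survival")
        return None
    if not 0 <= percent_stained <= 100:
        raise ValidationError(
            f"percent stained must be in 0..100, got {percent_stained!r}"
        )
    return Ezh2Group.LOW if percent_stained < cutoff else Ezh2Group.HIGH


@dataclass
class KMCurve:
    """Product-limit estimate with its at-risk table."""

    table: pd.DataFrame  # time, survival, n_at_risk, n_events

    def survival_at(self, t: float) -> float:
        """S(t): value at the last event time <= t (right-continuous step)."""
        tab = self.table[self.table.time <= t]
        return 1.0 if tab.empty else float(tab.survival.iloc[-1])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan–Meier product-limit estimator honoring right-censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("need at least one record")
    if np.any(times < 0):
        raise ValidationError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "time": ev.index.values,
            "survival": surv.reindex(ev.index).values,
            "n_at_risk": ev["at_risk"].values,
            "n_events": ev["observed"].values,
        }
    )
    return KMCurve(table=table.reset_index(drop=True))


def log_rank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (chi-square, df 1, two-sided)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea = np.asarray(events_a, bool)
    eb = np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return TestResult(p_value=1.0, statistic=0.0, df=1, method="log_rank (no events)")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(
        p_value=float(res.p_value),
        statistic=float(res.test_statistic),
        df=1,
        method="log_rank",
    )


def compare_survival(
    cohort: pd.DataFrame,
    endpoint: str = "os",
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
) -> dict:
    """KM curves and log-rank test for EZH2-low vs EZH2-high.

    ``cohort`` needs ``ezh2_percent_stained``, ``{endpoint}_time`` and
    ``{endpoint}_event`` columns; rows with missing fields are dropped
    with a warning. Returns {"low": KMCurve, "high": KMCurve,
    "test": TestResult, "n": {...}}.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for c in (tcol, ecol, "ezh2_percent_stained"):
        if c not in cohort.columns:
            raise ValidationError(f"missing column {c!r}")
    sub = cohort.dropna(subset=[tcol, ecol, "ezh2_percent_stained"])
    if len(sub) < len(cohort):
        warnings.warn(
            f"{len(cohort) - len(sub)} patients dropped from survival "
            "(missing time/event/percent)"
        )
    groups = sub.ezh2_percent_stained.map(lambda p: dichotomize_ezh2(p, cutoff))
    low = sub[groups == Ezh2Group.LOW]
    high = sub[groups == Ezh2Group.HIGH]
    if low.empty or high.empty:
        raise ValidationError("one EZH2 expression group is empty")
    return {
        "low": km_estimate(low[tcol], low[ecol].astype(bool)),
        "high": km_estimate(high[tcol], high[ecol].astype(bool)),
        "test": log_rank(low[tcol], low[ecol].astype(bool),
                         high[tcol], high[ecol].astype(bool)),
        "n": {"low": len(low), "high": len(high)},
    }


def plot_km(result: dict, path, endpoint: str = "OS") -> None:
    """Save the low/high KM curves from `compare_survival` as a figure.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for key, label, color in (("low", "EZH2-low (<70%)", "tab:blue"),
                              ("high", "EZH2-high (≥70%)", "tab:orange")):
        t = result[key].table
        ax.step([0, *t.time], [1.0, *t.survival], where="post",
                label=f"{label}, n={result['n'][key]}", color=color)
    p = result["test"].p_value
    ax.set_xlabel("years")
    ax.set_ylabel(f"{endpoint} probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"log-rank p = {p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
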