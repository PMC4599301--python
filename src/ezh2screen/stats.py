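"""Cohort-level statistics for the mutant-vs-WT comparison tables.

Thin, convention-pinning wrappers around scipy.stats plus the builder
for the characteristics-by-mutation-status summary table. Conventions
that matter and are fixed here:

* Fisher exact is two-sided by the minimum-likelihood rule (sum the
  hypergeometric probabilities of all tables with the observed margins
  that are no more probable than the observed one).
* Chi-square carries no continuity correction.
* The rank-sum test uses the normal approximation with tie correction
  and continuity correction — IHC scores live on a coarse grid and are
  heavily tied.
* p-values print with 2 significant figures, scientific below 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, ValidationError


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    statistic: Optional[float] = None
    df: Optional[int] = None


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValidationError("contingency cells must be non-negative integers")
    return t


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test (minimum-likelihood convention)."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return TestResult(p_value=1.0, method="fisher_exact (degenerate margins)")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(p_value=float(p), statistic=float(odds), method="fisher_exact")


def chi_square(table) -> TestResult:
    """Pearson chi-square without continuity correction, upper-tail p."""
    t = _as_table(table)
    if t.shape[0] != 2:
        raise ValidationError("expected a 2-row table")
    expected = sps.contingency.expected_freq(t)
    if np.any(expected <= 0):
        raise ValidationError(
            "a zero expected cell makes chi-square invalid; use the exact test"
        )
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(p_value=float(p), statistic=float(chi2), df=int(df), method="chi_square")


def fisher_exact_2x3(table) -> TestResult:
    """Exact test on a 2x3 table (Freeman–Halton extension).

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed (same
    minimum-likelihood convention as the 2x2 case).
    """
    t = _as_table(table).astype(int)
    if t.shape != (2, 3):
        raise ValidationError(f"expected a 2x3 table, got shape {t.shape}")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()

    def log_p(a, b, c):  # first row (a,b,c); second row fixed by margins
        tab = np.array([[a, b, c], [col[0] - a, col[1] - b, col[2] - c]])
        if np.any(tab < 0):
            return None
        from scipy.special import gammaln

        lp = (
            gammaln(row + 1).sum()
            + gammaln(col + 1).sum()
            - gammaln(n + 1)
            - gammaln(tab + 1).sum()
        )
        return lp

    obs = log_p(*t[0])
    total = 0.0
    for a in range(min(row[0], col[0]) + 1):
        for b in range(min(row[0] - a, col[1]) + 1):
            c = row[0] - a - b
            lp = log_p(a, b, c)
            if lp is not None and lp <= obs + 1e-7:
                total += np.exp(lp)
    return TestResult(p_value=min(float(total), 1.0), method="freeman_halton")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided rank-sum test, normal approximation with tie/continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult(p_value=1.0, statistic=0.0, method="wilcoxon_rank_sum (constant)")
    u, p = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(p_value=float(p), statistic=float(u), method="wilcoxon_rank_sum")


def pearson_cor(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def format_p(p: float) -> str:
    """2 significant figures; scientific notation below 1e-3."""
    if p < 1e-3:
        return f"{p:.2E}"
    return f"{float(f'{p:.2g}'):g}"


def _median_range(v: pd.Series) -> str:
    v = v.dropna()
    if v.empty:
        return "NA"
    lo, hi, med = v.min(), v.max(), v.median()

    def fmt(x):
        return f"{x:g}" if round(x, 2) == round(x, 0) else f"{x:.2f}".rstrip("0").rstrip(".")

    if lo == hi:
        return fmt(med)
    return f"{fmt(med)} ({fmt(lo)}–{fmt(hi)})"


def build_summary_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Characteristics-by-EZH2-status summary table.

    ``cohort`` is a scored patient table: one row per patient with
    ``ezh2_sanger`` ("WT"/"Y641"), ``usable``, the per-antibody scores,
    ``me3me2_score``, ``t1418``, ``age``, ``ipi_band`` ("0-2"/"3-5") and
    ``coo``. Count rows carry a Fisher exact p, score rows a rank-sum p.
    """
    wt = cohort[cohort.ezh2_sanger == "WT"]
    mut = cohort[cohort.ezh2_sanger == "Y641"]
    rows = []

    def add(label, total, wt_v, mut_v, p):
        rows.append(
            {"characteristic": label, "total": total, "wt": wt_v,
             "mutant": mut_v, "p_value": p}
        )

    if wt.empty or mut.empty:
        add("Patients, n", len(cohort), len(wt), len(mut), "not computable")
        return pd.DataFrame(rows)

    add("Patients, n", len(cohort), len(wt), len(mut), "")

    u_wt, u_mut = int(wt.usable.sum()), int(mut.usable.sum())
    p = fisher_exact_2x2(
        [[u_wt, len(wt) - u_wt], [u_mut, len(mut) - u_mut]]
    ).p_value
    add("me3/me2 score usable, n", u_wt + u_mut, u_wt, u_mut, format_p(p))

    score_rows = [
        ("EZH2 IHC score, median (range)", "ezh2_score"),
        ("H3K27me1 IHC score, median (range)", "me1_score"),
        ("H3K27me2 IHC score, median (range)", "me2_score"),
        ("H3K27me3 IHC score, median (range)", "me3_score"),
        ("me3/me2 score, median (range)", "me3me2_score"),
    ]
    uw, um = wt[wt.usable], mut[mut.usable]
    for label, col in score_rows:
        if col not in cohort.columns:
            continue
        a, b = uw[col].dropna(), um[col].dropna()
        p = wilcoxon_rank_sum(a, b).p_value if len(a) and len(b) else None
        add(
            label,
            _median_range(pd.concat([a, b])),
            _median_range(a),
            _median_range(b),
            format_p(p) if p is not None else "not computable",
        )

    if "t1418" in cohort.columns:
        t_wt = int(wt.t1418.fillna(False).sum())
        t_mut = int(mut.t1418.fillna(False).sum())
        p = fisher_exact_2x2(
            [[t_wt, len(wt) - t_wt], [t_mut, len(mut) - t_mut]]
        ).p_value
        add("t(14;18), n", t_wt + t_mut, t_wt, t_mut, format_p(p))

    if "age" in cohort.columns:
        p = wilcoxon_rank_sum(wt.age.dropna(), mut.age.dropna()).p_value
        add("Age (years), median (range)", _median_range(cohort.age),
            _median_range(wt.age), _median_range(mut.age), format_p(p))

    if "ipi_band" in cohort.columns:
        lo_wt = int((wt.ipi_band == "0-2").sum())
        lo_mut = int((mut.ipi_band == "0-2").sum())
        hi_wt, hi_mut = len(wt) - lo_wt, len(mut) - lo_mut
        p = fisher_exact_2x2([[lo_wt, hi_wt], [lo_mut, hi_mut]]).p_value
        add("IPI: 0-2/3-5, n", f"{lo_wt + lo_mut}/{hi_wt + hi_mut}",
            f"{lo_wt}/{hi_wt}", f"{lo_mut}/{hi_mut}", format_p(p))

    if "coo" in cohort.columns:
        g_wt = int((wt.coo == "GCB").sum())
        g_mut = int((mut.coo == "GCB").sum())
        a_wt = int((wt.coo == "ABC").sum())
        a_mut = int((mut.coo == "ABC").sum())
        p = fisher_exact_2x2([[g_wt, a_wt], [g_mut, a_mut]]).p_value
        add("GCB / ABC, n", f"{g_wt + g_mut}/{a_wt + a_mut}",
            f"{g_wt}/{a_wt}", f"{g_mut}/{a_mut}", format_p(p))

    return pd.DataFrame(rows)
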