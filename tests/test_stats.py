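"""Cohort statistics: exact tests, rank-sum, correlation, summary table."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ezh2screen import (
    DegenerateDataError,
    ValidationError,
    build_summary_table,
    chi_square,
    fisher_exact_2x2,
    fisher_exact_2x3,
    pearson_cor,
    wilcoxon_rank_sum,
)


def _fisher_enumeration_oracle(table):
    """Two-sided minimum-likelihood Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,printed,sig_figs",
        [
            ([[8, 70], [9, 5]], 3.5e-05, 2),  # t(14;18) by mutation status
            ([[36, 39], [12, 1]], 0.005, 1),  # GCB/ABC by mutation status
            ([[32, 46], [8, 6]], 0.38, 2),  # IPI band by mutation status
            ([[70, 8], [12, 2]], 0.65, 2),  # IHC-usable by mutation status
        ],
    )
    def test_reported_cohort_tables_at_printed_precision(self, table, printed, sig_figs):
        p = fisher_exact_2x2(table).p_value
        assert float(f"{p:.{sig_figs}g}") == pytest.approx(printed)

    def test_equal_proportions_give_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0

    def test_degenerate_margin(self):
        r = fisher_exact_2x2([[0, 0], [3, 4]])
        assert r.p_value == 1.0 and "degenerate" in r.method

    def test_matches_enumeration_oracle(self, rng):
        tables = [[[8, 70], [9, 5]], [[3, 1], [2, 7]], [[10, 0], [0, 10]]]
        tables += [
            np.reshape(rng.integers(0, 40, 4), (2, 2)).tolist() for _ in range(20)
        ]
        for t in tables:
            if min(np.sum(t, 0).min(), np.sum(t, 1).min()) == 0:
                continue
            assert fisher_exact_2x2(t).p_value == pytest.approx(
                _fisher_enumeration_oracle(t), rel=1e-9
            )

    def test_invariance_under_transposition_and_swaps(self):
        t = np.array([[8, 70], [9, 5]])
        p = fisher_exact_2x2(t).p_value
        for variant in (t.T, t[::-1], t[:, ::-1], t[::-1, ::-1]):
            assert fisher_exact_2x2(variant).p_value == pytest.approx(p)


class TestChiSquare:
    def test_profile_distribution_is_order_1e_minus_5(self):
        r = chi_square([[7, 4, 1], [5, 28, 37]])
        assert r.df == 2
        assert 1e-5 <= r.p_value < 1e-4

    def test_no_association(self):
        r = chi_square([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_computed_diagonal_table(self):
        r = chi_square([[20, 0], [0, 20]])
        assert r.statistic == pytest.approx(40.0) and r.df == 1

    def test_zero_expected_cell_directs_to_exact_test(self):
        with pytest.raises(ValidationError, match="exact"):
            chi_square([[0, 5], [0, 7]])

    def test_exact_2x3_on_profile_table(self):
        # frozen against R's fisher.test on the same 2x3 table
        t = [[7, 4, 1], [5, 28, 37]]
        p_exact = fisher_exact_2x3(t).p_value
        assert p_exact == pytest.approx(3.824403e-05, rel=1e-5)
        # both the exact and the chi-square p sit at the 1e-5 order
        p_chi = chi_square(t).p_value
        assert 1e-5 <= p_chi < 1e-4 and 1e-5 <= p_exact < 1e-4


class TestWilcoxonRankSum:
    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_constant_equal_samples(self):
        assert wilcoxon_rank_sum([2, 2], [2, 2]).p_value == 1.0

    def test_complete_separation_attains_the_minimum(self):
        p_sep = wilcoxon_rank_sum([1, 2, 3], [101, 102, 103]).p_value
        p_mix = wilcoxon_rank_sum([1, 102, 3], [101, 2, 103]).p_value
        assert p_sep < p_mix
        assert p_sep < 0.15  # n=3,3 cannot go below ~0.08 two-sided

    def test_tied_heavy_fixture_agrees_with_permutation_oracle(self, rng):
        # IHC-like coarse scores, 12 vs 70 with massive ties
        x = rng.choice([0, 9, 18, 27, 30], size=12, p=[0.1, 0.1, 0.2, 0.4, 0.2])
        y = rng.choice([0, 9, 18, 27, 30], size=70, p=[0.1, 0.2, 0.3, 0.3, 0.1])
        p = wilcoxon_rank_sum(x, y).p_value

        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:12].sum()
        r2 = np.random.default_rng(0)
        perms = r2.permuted(np.tile(ranks, (100_000, 1)), axis=1)
        null = perms[:, :12].sum(axis=1)
        mc = np.mean(np.abs(null - null.mean()) >= abs(obs - null.mean()) - 1e-9)
        assert p == pytest.approx(mc, rel=0.10)


class TestPearson:
    def test_perfect_linear(self):
        r, _ = pearson_cor([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        r, _ = pearson_cor([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_ten_point_fixture_matches_covariance_ratio(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, p = pearson_cor(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(manual)
        assert 0 < p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_cor([1, 1, 1], [1, 2, 3])


def _mini_cohort(n_wt=78, n_mut=14, usable_wt=70, usable_mut=12,
                 ipi_low=(32, 8)):
    rows = []
    rng = np.random.default_rng(3)
    for i in range(n_wt + n_mut):
        mut = i >= n_wt
        group_i = i - n_wt if mut else i
        usable = group_i < (usable_mut if mut else usable_wt)
        low = group_i < (ipi_low[1] if mut else ipi_low[0])
        me2, me3 = (9, 27) if mut else (27, 18)
        rows.append(
            {
                "patient_id": f"P{i}",
                "ezh2_sanger": "Y641" if mut else "WT",
                "usable": usable,
                "ezh2_score": 18, "me1_score": 30,
                "me2_score": me2 if usable else None,
                "me3_score": me3 if usable else None,
                "me3me2_score": (
                    round(np.log2((me3 + 1) / (me2 + 1)), 4) if usable else None
                ),
                "t1418": bool(rng.random() < (0.6 if mut else 0.1)),
                "age": int(rng.integers(20, 88)),
                "ipi_band": "0-2" if low else "3-5",
                "coo": "GCB" if (mut or rng.random() < 0.5) else "ABC",
            }
        )
    return pd.DataFrame(rows)


class TestBuildTable2:
    def test_row_structure_matches_reporting_layout(self, default_bundle):
        from ezh2screen import score_patient_table

        scored = score_patient_table(default_bundle.patients)
        cohort = default_bundle.patients.merge(scored, on="patient_id")
        t = build_summary_table(cohort)
        expected = [
            "Patients, n", "me3/me2 score usable, n",
            "EZH2 IHC score, median (range)",
            "H3K27me1 IHC score, median (range)",
            "H3K27me2 IHC score, median (range)",
            "H3K27me3 IHC score, median (range)",
            "me3/me2 score, median (range)", "t(14;18), n",
            "Age (years), median (range)", "IPI: 0-2/3-5, n", "GCB / ABC, n",
        ]
        assert list(t.characteristic) == expected

    def test_usable_row_reproduces_printed_p(self):
        t = build_summary_table(_mini_cohort())
        row = t[t.characteristic == "me3/me2 score usable, n"].iloc[0]
        assert row.p_value == "0.65"
        assert (row.wt, row.mutant) == (70, 12)

    def test_ipi_row_reproduces_printed_p(self):
        t = build_summary_table(_mini_cohort())
        row = t[t.characteristic == "IPI: 0-2/3-5, n"].iloc[0]
        assert row.p_value == "0.38"

    def test_empty_group_marked_not_computable(self):
        df = _mini_cohort(n_wt=5, n_mut=0, usable_wt=5, usable_mut=0)
        t = build_summary_table(df)
        assert t.iloc[0].p_value == "not computable"
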