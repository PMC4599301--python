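"""IHC scoring: core/patient scores, me3/me2 score, profiles, kappa."""

import math

import numpy as np
import pytest

from ezh2screen import (
    CoreStain,
    DegenerateDataError,
    Profile,
    ValidationError,
    accuracy_sweep,
    classify_profile,
    core_score,
    me3me2_score,
    patient_score,
    percent_to_decile,
    weighted_kappa,
)


@pytest.mark.parametrize(
    "intensity,proportion,expected",
    [(3, 10, 30), (0, 0, 0), (3, 9, 27), (1, 1, 1), (2, 5, 10)],
)
def test_core_score_product(intensity, proportion, expected):
    assert core_score(intensity, proportion) == expected


@pytest.mark.parametrize("intensity,proportion", [(4, 5), (-1, 3), (2, 11), (1, -2)])
def test_core_score_rejects_out_of_range(intensity, proportion):
    with pytest.raises(ValidationError):
        core_score(intensity, proportion)


@pytest.mark.parametrize("intensity,proportion", [(0, 5), (2, 0)])
def test_negative_core_normalizes_both_fields_to_zero(intensity, proportion):
    # a 0 in either field encodes a fully negative core
    assert core_score(intensity, proportion) == 0


def _cores(scores, ab="me3"):
    decomp = {0: (0, 0), 9: (3, 3), 27: (3, 9), 30: (3, 10)}
    return [CoreStain(ab, *decomp[s]) for s in scores]


@pytest.mark.parametrize(
    "scores,expected", [([27, 9, 0], 27), ([9], 9), ([0, 0, 0], 0)]
)
def test_patient_score_is_max_over_cores(scores, expected):
    assert patient_score(_cores(scores)) == expected


def test_patient_score_empty_marks_antibody_missing():
    assert patient_score([]) is None


def test_patient_score_rejects_mixed_antibodies_and_excess_cores():
    with pytest.raises(ValidationError):
        patient_score([CoreStain("me3", 3, 9), CoreStain("me2", 3, 9)])
    with pytest.raises(ValidationError):
        patient_score(_cores([9, 9, 9, 9]))


def test_me3me2_score_examples():
    assert round(me3me2_score(27, 0), 1) == 4.8
    assert me3me2_score(27, 9) == pytest.approx(math.log2(28 / 10))
    for x in (0, 9, 27, 30):
        assert me3me2_score(x, x) == 0.0
    with pytest.raises(ValidationError):
        me3me2_score(31, 0)


def test_me3me2_grid_bounds_antisymmetry_monotonicity():
    bound = math.log2(31)
    grid = range(31)
    vals = {(a, b): me3me2_score(a, b) for a in grid for b in grid}
    for (a, b), v in vals.items():
        assert -bound <= v <= bound
        assert v == pytest.approx(-vals[(b, a)], abs=1e-12)
    for b in grid:  # strictly increasing in me3
        col = [vals[(a, b)] for a in grid]
        assert all(x < y for x, y in zip(col, col[1:]))
    for a in grid:  # strictly decreasing in me2
        row = [vals[(a, b)] for b in grid]
        assert all(x > y for x, y in zip(row, row[1:]))


@pytest.mark.parametrize(
    "score,profile,merged",
    [
        (0.56, Profile.MUTANT_LIKE, Profile.MUTANT_LIKE),
        (0.0, Profile.INTERMEDIATE, Profile.WT_LIKE),
        (-0.25, Profile.WT_LIKE, Profile.WT_LIKE),
    ],
)
def test_classify_profile(score, profile, merged):
    call = classify_profile(score)
    assert call.profile is profile and call.merged is merged


def test_classify_profile_partitions_and_merge_rule():
    for s in np.linspace(-5, 5, 201):
        call = classify_profile(float(s))
        assert call.merged is (
            Profile.MUTANT_LIKE if s > 0 else Profile.WT_LIKE
        )
        assert (call.profile is Profile.MUTANT_LIKE) == (s > 0)
        assert (call.profile is Profile.INTERMEDIATE) == (s == 0)
    with pytest.raises(ValidationError):
        classify_profile(math.nan)


def test_percent_to_decile_binning():
    assert percent_to_decile(0) == 0
    assert percent_to_decile(1) == 1
    assert percent_to_decile(10) == 1
    assert percent_to_decile(10.5) == 2
    assert percent_to_decile(100) == 10
    with pytest.raises(ValidationError):
        percent_to_decile(101)


class TestAccuracySweep:
    def test_perfect_separation(self):
        t, acc, _ = accuracy_sweep([-1, -1, 1, 1], ["WT", "WT", "mutant", "mutant"])
        assert acc == 1.0 and t == 0.0

    def test_published_profile_counts_give_88_percent_at_zero(self):
        # mutants: 7 positive, 4 intermediate, 1 negative; WT: 5/28/37
        scores = [1] * 7 + [0] * 4 + [-1] * 1 + [1] * 5 + [0] * 28 + [-1] * 37
        labels = ["mutant"] * 12 + ["WT"] * 70
        t, acc, table = accuracy_sweep(scores, labels)
        assert t == 0.0
        assert acc == pytest.approx(72 / 82)
        assert round(100 * acc) == 88
        at_zero = table[table.threshold == 0.0].iloc[0]
        assert at_zero.accuracy == pytest.approx(72 / 82)

    def test_constant_scores_fall_back_to_majority_class(self):
        _, acc, _ = accuracy_sweep([1.0] * 5, ["mutant"] * 2 + ["WT"] * 3)
        assert acc == pytest.approx(3 / 5)

    def test_single_class_is_rejected(self):
        with pytest.raises(DegenerateDataError):
            accuracy_sweep([1, 2], ["WT", "WT"])

    def test_matches_exhaustive_classification_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 21))
            scores = np.round(rng.normal(size=n), 2)
            labels = rng.choice(["mutant", "WT"], size=n)
            if len(set(labels)) < 2:
                continue
            is_mut = labels == "mutant"
            # every classification a threshold can induce
            best = 0.0
            for t in np.concatenate([[scores.min() - 1], np.unique(scores)]):
                acc = ((scores > t) == is_mut).mean()
                best = max(best, acc)
            _, acc, _ = accuracy_sweep(scores, labels)
            assert acc == pytest.approx(best)


class TestWeightedKappa:
    FIXTURE_A = [0, 0, 1, 2, 1, 0, 2, 2, 1, 0, 1, 2, 0, 1, 2, 0, 0, 1, 2, 1]
    FIXTURE_B = [0, 1, 1, 2, 0, 0, 2, 1, 1, 0, 2, 2, 0, 1, 1, 0, 1, 1, 2, 2]

    def test_perfect_agreement(self):
        r = weighted_kappa([0, 1, 2, 1], [0, 1, 2, 1])
        assert r.kappa == pytest.approx(1.0)

    def test_constant_rater_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            weighted_kappa([0, 1, 2, 1], [1, 1, 1, 1])

    def test_hand_computed_fixture(self):
        # frozen from a by-hand confusion-matrix evaluation with linear weights
        r = weighted_kappa(self.FIXTURE_A, self.FIXTURE_B)
        assert r.kappa == pytest.approx(0.5930232558139533)
        assert r.kappa_max >= r.kappa
        assert r.ratio_of_max == pytest.approx(r.kappa / r.kappa_max)

    def test_symmetry_and_kappa_max_dominance(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, size=25)
            b = rng.integers(0, 3, size=25)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            r1 = weighted_kappa(a, b)
            r2 = weighted_kappa(b, a)
            assert r1.kappa == pytest.approx(r2.kappa)
            assert r1.kappa <= r1.kappa_max <= 1.0 + 1e-12

    def test_quadratic_weights_differ(self):
        lin = weighted_kappa(self.FIXTURE_A, self.FIXTURE_B, weighting="linear")
        quad = weighted_kappa(self.FIXTURE_A, self.FIXTURE_B, weighting="quadratic")
        assert lin.kappa != pytest.approx(quad.kappa)
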