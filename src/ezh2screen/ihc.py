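"""Immunohistochemical H3K27-methylation scoring.

Implements the tissue-microarray scoring scheme used to detect EZH2
hyperactivity in DLBCL at the protein level: each core is scored as the
product of staining intensity (0-3) and the decile of tumor cells stained
(0-10), the patient-level score per antibody is the maximum over replicate
cores, and the trimethylation/dimethylation balance is summarized as

    me3/me2 score = log2((me3 + 1) / (me2 + 1))

Positive scores define the "mutant-like" methylation profile
(H3K27me3-high / H3K27me2-low, the expected consequence of an EZH2 Y641
gain-of-function mutation); negative scores the "WT-like" profile; zero
an intermediate profile that merges into the WT-like group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import DegenerateDataError, ValidationError

ANTIBODIES = ("ezh2", "me1", "me2", "me3")

#: Hard bounds of the per-antibody score (intensity 3 x proportion 10).
MAX_CORE_SCORE = 30


class Profile(str, Enum):
    MUTANT_LIKE = "mutant_like"
    INTERMEDIATE = "intermediate"
    WT_LIKE = "wt_like"


@dataclass(frozen=True)
class CoreStain:
    """One antibody on one TMA core.

    ``intensity`` 0-3 (0 negative, 1 weak ... 3 strong); ``proportion``
    decile 0-10 (0 = no positive tumor cells, k covers (10(k-1), 10k]%).
    A 0 in either field forces the other to 0 (both conventions encode a
    fully negative core and normalize to score 0).
    """

    antibody: str
    intensity: int
    proportion: int
    percent_stained: float | None = None

    def __post_init__(self):
        if self.antibody not in ANTIBODIES:
            raise ValidationError(f"unknown antibody {self.antibody!r}")
        if self.intensity not in (0, 1, 2, 3):
            raise ValidationError(
                f"intensity must be in 0..3, got {self.intensity!r}"
            )
        if self.proportion not in range(11):
            raise ValidationError(
                f"proportion must be in 0..10, got {self.proportion!r}"
            )
        if (self.intensity == 0) != (self.proportion == 0):
            # normalize: either field at 0 means a negative core
            object.__setattr__(self, "intensity", 0)
            object.__setattr__(self, "proportion", 0)

    @property
    def score(self) -> int:
        return self.intensity * self.proportion


def core_score(intensity: int, proportion: int) -> int:
    """Score one core: staining intensity x proportion decile, range 0-30."""
    return CoreStain("me3", intensity, proportion).score


def patient_score(cores: Sequence[CoreStain]) -> int | None:
    """Patient-level score for one antibody: max over 1-3 replicate cores.

    Returns None for an empty core list (all cores lost / non-tumoral);
    callers mark the antibody missing and the patient unusable.
    """
    if not cores:
        return None
    abs_ = {c.antibody for c in cores}
    if len(abs_) > 1:
        raise ValidationError(f"cores mix antibodies {sorted(abs_)}")
    if len(cores) > 3:
        raise ValidationError(f"at most 3 replicate cores, got {len(cores)}")
    return max(c.score for c in cores)


def me3me2_score(me3: int, me2: int) -> float:
    """log2((me3 + 1) / (me2 + 1)); antisymmetric in its arguments."""
    for name, v in (("me3", me3), ("me2", me2)):
        if not 0 <= v <= MAX_CORE_SCORE:
            raise ValidationError(f"{name} score must be in 0..30, got {v!r}")
    return math.log2((me3 + 1) / (me2 + 1))


class ProfileCall(NamedTuple):
    profile: Profile
    merged: Profile  # MUTANT_LIKE or WT_LIKE only


def classify_profile(score: float) -> ProfileCall:
    """Sign-based methylation profile; scores <= 0 merge into WT-like."""
    if not math.isfinite(score):
        raise ValidationError(f"me3/me2 score must be finite, got {score!r}")
    if score > 0:
        return ProfileCall(Profile.MUTANT_LIKE, Profile.MUTANT_LIKE)
    if score == 0:
        return ProfileCall(Profile.INTERMEDIATE, Profile.WT_LIKE)
    return ProfileCall(Profile.WT_LIKE, Profile.WT_LIKE)


def percent_to_decile(percent: float) -> int:
    """Map a raw percent stained (0-100) to the 0-10 decile scale.

    0% -> 0; otherwise decile k covers (10(k-1), 10k]%. The raw percent
    is kept alongside so downstream cutoffs (e.g. the 70% EZH2-expression
    dichotomy) never depend on this binning.
    """
    if not 0 <= percent <= 100:
        raise ValidationError(f"percent stained must be in 0..100, got {percent!r}")
    return int(math.ceil(percent / 10))


def accuracy_sweep(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[float, float, pd.DataFrame]:
    """Sweep classification thresholds for the me3/me2 score.

    ``labels`` are "mutant"/"WT" truth; ``score > t`` calls mutant.
    Candidate thresholds are the midpoints between adjacent sorted unique
    scores, one sentinel below the minimum and one above the maximum, and
    0 exactly (the operating point of the merged-profile rule). Ties on
    accuracy break toward the fewest false negatives, then the smallest t.

    Returns (best_threshold, max_accuracy, table) where ``table`` has one
    row per candidate with tp/fn/fp/tn and accuracy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if scores.shape[0] != labels.shape[0]:
        raise ValidationError("scores and labels differ in length")
    bad = set(labels) - {"mutant", "WT"}
    if bad:
        raise ValidationError(f"labels must be 'mutant'/'WT', got {sorted(bad)}")
    is_mut = labels == "mutant"
    if is_mut.all() or (~is_mut).all():
        raise DegenerateDataError(
            "accuracy is undefined as a discriminator with a single class"
        )

    uniq = np.unique(scores)
    cands = [uniq[0] - 1.0, uniq[-1] + 1.0, 0.0]
    cands.extend((uniq[:-1] + uniq[1:]) / 2.0)
    cands = sorted(set(cands))

    rows = []
    n = scores.shape[0]
    for t in cands:
        pred_mut = scores > t
        tp = int(np.sum(pred_mut & is_mut))
        fp = int(np.sum(pred_mut & ~is_mut))
        fn = int(np.sum(~pred_mut & is_mut))
        tn = int(np.sum(~pred_mut & ~is_mut))
        rows.append((t, tp, fp, fn, tn, (tp + tn) / n))
    table = pd.DataFrame(
        rows, columns=["threshold", "tp", "fp", "fn", "tn", "accuracy"]
    )
    best = table.sort_values(
        ["accuracy", "fn", "threshold"], ascending=[False, True, True]
    ).iloc[0]
    return float(best.threshold), float(best.accuracy), table


@dataclass(frozen=True)
class AgreementResult:
    """Weighted inter-rater agreement with its marginal-constrained ceiling."""

    kappa: float
    kappa_max: float

    @property
    def ratio_of_max(self) -> float:
        return self.kappa / self.kappa_max


def _disagreement_weights(k: int, weighting: str) -> np.ndarray:
    # agreement weights: 1 on the diagonal, decaying with ordinal distance
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    d = np.abs(i - j) / (k - 1)
    if weighting == "linear":
        return 1.0 - d
    if weighting == "quadratic":
        return 1.0 - d**2
    raise ValidationError(f"weighting must be linear/quadratic, got {weighting!r}")


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    weighting: str = "linear",
    categories: Sequence | None = None,
) -> AgreementResult:
    """Weighted Cohen kappa with its maximum attainable value (Kmax).

    Kmax holds the observed marginals of both raters fixed and asks how
    much weighted agreement a confusion matrix could carry at most — a
    transportation problem solved exactly by linear programming. The
    ratio kappa/Kmax separates genuine disagreement from disagreement
    forced by unequal marginal usage of the categories.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValidationError("rating vectors differ in length")
    if not a:
        raise ValidationError("empty rating vectors")
    if categories is None:
        categories = sorted(set(a) | set(b))
    cats = list(categories)
    k = len(cats)
    if k < 2:
        raise DegenerateDataError(
            "agreement is undefined with fewer than 2 categories in use"
        )
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((k, k))
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    p = conf / conf.sum()
    row, col = p.sum(axis=1), p.sum(axis=0)
    if np.max(row) == 1.0 or np.max(col) == 1.0:
        raise DegenerateDataError(
            "a rater used a single category; kappa is undefined"
        )

    w = _disagreement_weights(k, weighting)
    po = float(np.sum(w * p))
    pe = float(np.sum(w * np.outer(row, col)))
    kappa = (po - pe) / (1.0 - pe)

    # max_X sum(w*X) s.t. X>=0, row sums = row, col sums = col
    c = -w.ravel()
    a_eq = np.zeros((2 * k, k * k))
    for i in range(k):
        a_eq[i, i * k : (i + 1) * k] = 1.0  # row sums
        a_eq[k + i, i::k] = 1.0  # col sums
    b_eq = np.concatenate([row, col])
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - LP on a transportation polytope
        raise RuntimeError(f"kappa_max LP failed: {res.message}")
    po_max = float(-res.fun)
    kappa_max = (po_max - pe) / (1.0 - pe)
    # guard fp noise: po_max >= po always, so kappa_max >= kappa
    kappa_max = max(kappa_max, kappa)
    return AgreementResult(kappa=kappa, kappa_max=min(kappa_max, 1.0))


@dataclass
class PatientIHC:
    """Per-patient IHC summary across the four antibodies."""

    patient_id: str
    scores: dict  # antibody -> int score or None if missing
    me3me2: float | None = None
    profile: Profile | None = None
    merged_profile: Profile | None = None
    usable: bool = False

    @classmethod
    def from_cores(cls, patient_id: str, cores_by_antibody: dict) -> "PatientIHC":
        scores = {
            ab: patient_score(cores_by_antibody.get(ab, []))
            for ab in ANTIBODIES
        }
        rec = cls(patient_id=patient_id, scores=scores)
        # me2 and me3 are both required for the methylation profile
        if scores["me2"] is not None and scores["me3"] is not None:
            rec.me3me2 = me3me2_score(scores["me3"], scores["me2"])
            call = classify_profile(rec.me3me2)
            rec.profile, rec.merged_profile = call.profile, call.merged
            rec.usable = True
        return rec


def score_patient_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Score every patient in a cohort table.

    Expects per-core columns ``{antibody}_core{1..3}_intensity`` /
    ``..._proportion`` (antibodies ezh2, me1, me2, me3); missing cores are
    NA in both fields. Returns one row per patient with per-antibody
    scores, the me3/me2 score (4 decimals), profile calls and usability.
    """
    out = []
    for _, row in patients.iterrows():
        cores: dict[str, list[CoreStain]] = {ab: [] for ab in ANTIBODIES}
        for ab in ANTIBODIES:
            for k in (1, 2, 3):
                i = row.get(f"{ab}_core{k}_intensity")
                p = row.get(f"{ab}_core{k}_proportion")
                if pd.isna(i) or pd.isna(p):
                    continue
                cores[ab].append(CoreStain(ab, int(i), int(p)))
        rec = PatientIHC.from_cores(str(row["patient_id"]), cores)
        out.append(
            {
                "patient_id": rec.patient_id,
                "ezh2_score": rec.scores["ezh2"],
                "me1_score": rec.scores["me1"],
                "me2_score": rec.scores["me2"],
                "me3_score": rec.scores["me3"],
                "me3me2_score": (
                    round(rec.me3me2, 4) if rec.me3me2 is not None else None
                ),
                "profile": rec.profile.value if rec.profile else None,
                "merged_profile": (
                    rec.merged_profile.value if rec.merged_profile else None
                ),
                "usable": rec.usable,
            }
        )
    return pd.DataFrame(out)
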