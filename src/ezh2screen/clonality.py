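"""EZH2 mutation clonality from relative variant allele frequencies.

A clonal EZH2 mutation is carried by (nearly) every tumor cell, so its
VAF tracks the VAFs of the other somatic mutations in the same sample; a
subclonal mutation sits in a minority population and shows a depressed
VAF. For each EZH2-mutant patient we take

    log_ratio = log2( EZH2 VAF / mean(associated-mutation VAFs) )

and split the cohort's log ratios into two groups with exact 1-D 2-means
clustering (contiguous in sorted order, so the global optimum is found by
enumerating the n-1 split points — no random initialization). The cluster
with the lower center is the subclonal one. VAFs are used as reported,
uncorrected for copy number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .exceptions import ValidationError


class Clonality(str, Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"
    INDETERMINATE = "indeterminate"


def log_vaf_ratio(ezh2_vaf: float, associated_vafs: Sequence[float]) -> float:
    """log2 of the EZH2 VAF over the arithmetic mean of associated VAFs.

    Returns NaN (the indeterminate signal) when no associated mutation
    exists or any VAF is zero; such patients are excluded from clustering.
    """
    vafs = list(associated_vafs)
    if not vafs or ezh2_vaf <= 0 or any(v <= 0 for v in vafs):
        return math.nan
    if ezh2_vaf > 1 or any(v > 1 for v in vafs):
        raise ValidationError("VAFs must lie in (0, 1]")
    return math.log2(ezh2_vaf / (sum(vafs) / len(vafs)))


@dataclass(frozen=True)
class KMeans1DResult:
    labels: np.ndarray  # 0 = lower-center cluster, 1 = higher
    centers: np.ndarray  # ascending
    wcss: float
    degenerate: bool = False  # all values identical -> single cluster


def kmeans_1d(values: Sequence[float], k: int = 2) -> KMeans1DResult:
    """Exact 2-means in one dimension.

    Optimal 1-D clusters are contiguous in sorted order, so the global
    within-cluster-sum-of-squares optimum is found deterministically by
    scanning all n-1 contiguous splits.
    """
    if k != 2:
        raise ValidationError("only k = 2 is supported")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValidationError("need at least 2 one-dimensional values")
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")
    if np.ptp(x) == 0:
        return KMeans1DResult(
            labels=np.zeros(x.shape[0], dtype=int),
            centers=np.array([x[0]]),
            wcss=0.0,
            degenerate=True,
        )

    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.shape[0]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i, j):  # SSE of xs[i:j] around its mean
        s, q, m = csum[j] - csum[i], csq[j] - csq[i], j - i
        return q - s * s / m

    splits = np.array([sse(0, m) + sse(m, n) for m in range(1, n)])
    m = int(np.argmin(splits)) + 1
    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[m:] = 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    centers = np.array([xs[:m].mean(), xs[m:].mean()])
    return KMeans1DResult(labels=labels, centers=centers, wcss=float(splits[m - 1]))


@dataclass
class ClonalityCall:
    patient_id: str
    ezh2_vaf: float
    associated_vafs: list[float]
    mean_associated_vaf: Optional[float] = None
    log_ratio: float = math.nan
    cluster: Clonality = Clonality.INDETERMINATE

    def __post_init__(self):
        self.associated_vafs = list(self.associated_vafs)
        if self.associated_vafs:
            self.mean_associated_vaf = sum(self.associated_vafs) / len(
                self.associated_vafs
            )
        self.log_ratio = log_vaf_ratio(self.ezh2_vaf, self.associated_vafs)


def classify_clonality(
    cohort: Sequence[ClonalityCall], min_separation: float = 0.5
) -> list[ClonalityCall]:
    """Label each EZH2-mutant patient clonal or subclonal.

    Runs exact 1-D 2-means on the finite log ratios; the lower-center
    cluster is subclonal. Because 2-means always splits, a guard declares
    the whole cohort clonal when the centers are closer than
    ``min_separation`` (log2 units): a unimodal cohort has no subclone
    signal. Patients without a finite ratio stay indeterminate.
    """
    calls = list(cohort)
    finite = [c for c in calls if math.isfinite(c.log_ratio)]
    if len(finite) < 2:
        warnings.warn(
            "fewer than 2 patients with finite log ratios; all indeterminate"
        )
        for c in calls:
            c.cluster = Clonality.INDETERMINATE
        return calls

    res = kmeans_1d([c.log_ratio for c in finite], k=2)
    if res.degenerate or (res.centers[-1] - res.centers[0]) < min_separation:
        for c in finite:
            c.cluster = Clonality.CLONAL
        return calls
    for c, lab in zip(finite, res.labels):
        c.cluster = Clonality.SUBCLONAL if lab == 0 else Clonality.CLONAL
    return calls
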