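"""Targeted-panel variant filtering, quality triage and VAFs.

Variants come annotated (functional class, dbSNP/COSMIC membership, SIFT,
caller quality score, read counts); this module applies the somatic
filtering rules — keep only protein-affecting classes, discard known
polymorphisms absent from COSMIC, discard tolerated SIFT predictions —
and triages survivors into accept / gray-zone / reject bands of the
caller quality score, with Sanger/pyrosequencing confirmation promoting
or demoting gray-zone calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .exceptions import UndefinedVAFError, ValidationError

#: Functional classes retained by the somatic filter.
KEPT_CLASSES = frozenset(
    {
        "frameshift_deletion",
        "frameshift_insertion",
        "nonframeshift_deletion",
        "nonframeshift_substitution",
        "splicing",
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
    }
)

#: All recognized functional-class strings.
KNOWN_CLASSES = KEPT_CLASSES | {"synonymous_SNV", "other"}


class Triage(str, Enum):
    ACCEPT = "accept"
    REJECT = "reject"
    CONFIRM_REQUIRED = "confirm_required"


class Confirmation(str, Enum):
    SANGER_CONFIRMED = "sanger_confirmed"
    SANGER_REFUTED = "sanger_refuted"
    PYRO_CONFIRMED = "pyro_confirmed"
    UNTESTED = "untested"


def compute_vaf(alt_reads: int, total_reads: int) -> float:
    """Variant allele frequency: mutant reads / total reads, in [0, 1]."""
    if alt_reads < 0 or total_reads < 0:
        raise ValidationError("read counts must be non-negative")
    if alt_reads > total_reads:
        raise ValidationError(
            f"alt_reads ({alt_reads}) exceeds total_reads ({total_reads})"
        )
    if total_reads == 0:
        raise UndefinedVAFError("VAF undefined with zero total reads")
    return alt_reads / total_reads


@dataclass
class VariantRecord:
    patient_id: str
    gene: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    func_class: str
    in_dbsnp: bool
    in_cosmic: bool
    sift: Optional[float]
    tvc_score: float
    alt_reads: int
    total_reads: int
    confirmed: Confirmation = Confirmation.UNTESTED
    vaf: float = field(init=False)

    def __post_init__(self):
        if self.func_class not in KNOWN_CLASSES:
            raise ValidationError(
                f"unknown functional class {self.func_class!r}"
            )
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise ValidationError(f"SIFT must be in [0,1], got {self.sift!r}")
        if isinstance(self.confirmed, str):
            self.confirmed = Confirmation(self.confirmed)
        self.vaf = compute_vaf(self.alt_reads, self.total_reads)


@dataclass(frozen=True)
class QualityThresholds:
    """Caller-quality bands: reject below / accept at-or-above, gray between."""

    reject_below: float = 9.5
    accept_at_or_above: float = 22.0
    derived: bool = False
    warning: Optional[str] = None

    def __post_init__(self):
        if not self.reject_below < self.accept_at_or_above:
            raise ValidationError(
                "reject_below must be strictly below accept_at_or_above"
            )


DEFAULT_THRESHOLDS = QualityThresholds()

_RULES = ("func_class", "dbsnp_not_cosmic", "sift")


def _rule_outcomes(rec: VariantRecord) -> dict:
    """Pass/fail of each filter rule; all three must pass to keep."""
    return {
        "func_class": rec.func_class in KEPT_CLASSES,
        "dbsnp_not_cosmic": not (rec.in_dbsnp and not rec.in_cosmic),
        # missing SIFT passes: the rule only discards predictions > 0.05
        "sift": rec.sift is None or rec.sift <= 0.05,
    }


def filter_variants(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], list[dict]]:
    """Apply the somatic filter; return (kept, per-record audit).

    The audit lists, for every input record in order, the outcome of each
    rule and the final decision. Filtering is order-independent and
    idempotent (each record is judged in isolation).
    """
    kept, audit = [], []
    for rec in records:
        outcomes = _rule_outcomes(rec)
        keep = all(outcomes.values())
        audit.append(
            {
                "patient_id": rec.patient_id,
                "gene": rec.gene,
                "chrom": rec.chrom,
                "pos": rec.pos,
                **{f"pass_{r}": outcomes[r] for r in _RULES},
                "kept": keep,
            }
        )
        if keep:
            kept.append(rec)
    return kept, audit


def triage_by_quality(
    rec: VariantRecord, thresholds: QualityThresholds = DEFAULT_THRESHOLDS
) -> Triage:
    """Place a call in the accept / gray / reject quality bands.

    Gray-zone calls are promoted to accept by Sanger or pyrosequencing
    confirmation and demoted to reject by Sanger refutation; otherwise
    they require confirmation.
    """
    if rec.tvc_score < thresholds.reject_below:
        return Triage.REJECT
    if rec.tvc_score >= thresholds.accept_at_or_above:
        return Triage.ACCEPT
    if rec.confirmed in (Confirmation.SANGER_CONFIRMED, Confirmation.PYRO_CONFIRMED):
        return Triage.ACCEPT
    if rec.confirmed is Confirmation.SANGER_REFUTED:
        return Triage.REJECT
    return Triage.CONFIRM_REQUIRED


def derive_quality_thresholds(
    confirmed_scores: Iterable[float], refuted_scores: Iterable[float]
) -> QualityThresholds:
    """Derive quality bands from orthogonally validated calls.

    reject_below sits one decimal step above the worst refuted score;
    accept_at_or_above is the smallest confirmed score that no refuted
    score reaches. When the two sets interleave too much to honor
    reject_below < accept_at_or_above, the published defaults (9.5, 22)
    are returned with a warning flag.
    """
    confirmed = sorted(confirmed_scores)
    refuted = sorted(refuted_scores)
    if not confirmed or not refuted:
        raise ValidationError("both confirmed and refuted scores are required")
    reject_below = round(max(refuted) + 0.1, 1)
    candidates = [s for s in confirmed if all(r < s for r in refuted)]
    if not candidates or round(min(candidates), 1) <= reject_below:
        msg = (
            "confirmed and refuted quality scores do not separate; "
            "falling back to published defaults (9.5, 22)"
        )
        warnings.warn(msg)
        return QualityThresholds(derived=False, warning=msg)
    return QualityThresholds(
        reject_below=reject_below,
        accept_at_or_above=round(min(candidates), 1),
        derived=True,
    )
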