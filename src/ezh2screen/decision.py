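"""Treatment-decision support combining Sanger EZH2 status and IHC profile.

The screening algorithm: when Sanger sequencing of the EZH2 Y641 hotspot
and the IHC methylation profile agree, no further testing is needed —
concordant mutants are recommended for EZH2-inhibitor treatment and
concordant wild-types are not. Discordant cases are sent to targeted NGS,
which can explain the discordance: a subclonal or low-VAF EZH2 mutation
weakens the case for treating a Sanger-mutant patient with a WT-like
profile, while an activating mutation in an EZH2-upregulating gene can
argue for treating a Sanger-WT patient with a mutant-like profile.

Verdicts are advisory labels for study triage, not clinical guidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .clonality import Clonality
from .exceptions import ValidationError
from .ihc import Profile

DISCLAIMER = (
    "Advisory research output only; not a substitute for clinical judgment."
)

#: Genes whose activating mutations can phenocopy EZH2 hyperactivity.
DEFAULT_ACTIVATING_GENES = frozenset({"MYD88", "PIM1", "PRDM1", "MYC"})


class Verdict(str, Enum):
    RECOMMEND = "recommend"
    DENY = "deny"
    NGS_REQUIRED = "ngs_required"
    RECOMMEND_WITH_CAUTION = "recommend_with_caution"
    CONSIDER_DESPITE_WT = "consider_despite_wt"


class Rationale(str, Enum):
    CONCORDANT_MUTANT = "concordant_mutant"
    CONCORDANT_WT = "concordant_wt"
    SUBCLONAL_EZH2 = "subclonal_ezh2"
    LOW_EZH2_VAF = "low_ezh2_vaf"
    ASSOCIATED_ACTIVATING_MUTATION = "associated_activating_mutation"
    NO_EXPLANATORY_FINDING = "no_explanatory_finding"


@dataclass(frozen=True)
class NgsFindings:
    """What targeted NGS adds for a discordant patient."""

    ezh2_clonality: Optional[Clonality] = None
    ezh2_vaf: Optional[float] = None
    validated_genes: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "validated_genes", frozenset(self.validated_genes))


@dataclass(frozen=True)
class DecisionConfig:
    activating_genes: frozenset = DEFAULT_ACTIVATING_GENES
    low_vaf_cutoff: float = 0.10  # fraction; the observed subclonal VAFs were 6-8.4%

    def __post_init__(self):
        object.__setattr__(self, "activating_genes", frozenset(self.activating_genes))


@dataclass
class DecisionOutcome:
    patient_id: str
    verdict: Verdict
    rationale: list[Rationale] = field(default_factory=list)
    disclaimer: str = DISCLAIMER


def decide(
    patient_id: str,
    sanger: str,
    merged_profile: Profile | str,
    ngs: Optional[NgsFindings] = None,
    config: DecisionConfig = DecisionConfig(),
) -> DecisionOutcome:
    """Apply the Sanger x IHC decision grid, with NGS triage when discordant.

    * Y641 + mutant-like profile -> recommend (concordant).
    * WT + WT-like profile -> deny (concordant).
    * Discordant without NGS data -> ngs_required.
    * Y641 + WT-like + NGS: subclonal call or VAF below the cutoff ->
      recommend_with_caution with the explaining flags; a clonal,
      high-VAF mutation leaves nothing to explain the WT-like profile,
      so the verdict is recommend_with_caution flagged
      no_explanatory_finding (plain `recommend` is reserved for
      concordant mutants).
    * WT + mutant-like + NGS: a validated hit in the activating-gene
      watch list -> consider_despite_wt; no hit -> deny, flagged
      no_explanatory_finding.
    """
    if sanger not in ("WT", "Y641"):
        raise ValidationError(f"sanger must be WT or Y641, got {sanger!r}")
    merged = Profile(merged_profile)
    if merged not in (Profile.MUTANT_LIKE, Profile.WT_LIKE):
        raise ValidationError(
            f"merged profile must be mutant_like or wt_like, got {merged!r}"
        )
    mutant = sanger == "Y641"
    mutant_like = merged is Profile.MUTANT_LIKE

    if mutant and mutant_like:
        return DecisionOutcome(patient_id, Verdict.RECOMMEND,
                               [Rationale.CONCORDANT_MUTANT])
    if not mutant and not mutant_like:
        return DecisionOutcome(patient_id, Verdict.DENY,
                               [Rationale.CONCORDANT_WT])
    if ngs is None:
        return DecisionOutcome(patient_id, Verdict.NGS_REQUIRED, [])

    if mutant:  # Y641 with a WT-like profile
        flags = []
        if ngs.ezh2_clonality is Clonality.SUBCLONAL:
            flags.append(Rationale.SUBCLONAL_EZH2)
        if ngs.ezh2_vaf is not None and ngs.ezh2_vaf < config.low_vaf_cutoff:
            flags.append(Rationale.LOW_EZH2_VAF)
        if not flags:
            flags = [Rationale.NO_EXPLANATORY_FINDING]
        return DecisionOutcome(patient_id, Verdict.RECOMMEND_WITH_CAUTION, flags)

    # WT with a mutant-like profile
    hits = ngs.validated_genes & config.activating_genes
    if hits:
        return DecisionOutcome(patient_id, Verdict.CONSIDER_DESPITE_WT,
                               [Rationale.ASSOCIATED_ACTIVATING_MUTATION])
    return DecisionOutcome(patient_id, Verdict.DENY,
                           [Rationale.NO_EXPLANATORY_FINDING])


def decide_cohort(
    scored,  # DataFrame: patient_id, ezh2_sanger, merged_profile, usable
    clonality_calls: Optional[Sequence] = None,
    kept_variants: Optional[Sequence] = None,
    config: DecisionConfig = DecisionConfig(),
) -> list[DecisionOutcome]:
    """Vectorize `decide` over a scored cohort table.

    ``clonality_calls`` are ClonalityCall objects and ``kept_variants``
    filtered VariantRecords; both optional — patients without NGS data
    fall through the discordant branch to ngs_required. Unusable patients
    (no IHC profile) are skipped.
    """
    clon = {c.patient_id: c for c in clonality_calls or []}
    genes: dict[str, set] = {}
    for v in kept_variants or []:
        genes.setdefault(v.patient_id, set()).add(v.gene)

    out = []
    for _, row in scored.iterrows():
        if not row.get("usable", True) or row.get("merged_profile") is None:
            continue
        pid = str(row.patient_id)
        ngs = None
        if pid in clon or pid in genes:
            c = clon.get(pid)
            ngs = NgsFindings(
                ezh2_clonality=c.cluster if c else None,
                ezh2_vaf=c.ezh2_vaf if c else None,
                validated_genes=frozenset(genes.get(pid, set())),
            )
        out.append(
            decide(pid, row.ezh2_sanger, row.merged_profile, ngs, config)
        )
    return out
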