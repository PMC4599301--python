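"""Pipeline configuration: one YAML file with per-module sections."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .decision import DecisionConfig
from .exceptions import ValidationError
from .simulate import CohortConfig
from .variants import QualityThresholds


@dataclass
class PipelineConfig:
    patients: str | None = None  # path to the patient table (TSV/CSV)
    variants: str | None = None  # path to variant calls (VCF 4.2 or TSV)
    out_dir: str = "ezh2screen_out"
    seed: int = 0
    kappa_weighting: str = "linear"
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    clonality_min_separation: float = 0.5
    cap_vaf_at_half: bool = False  # optional CNV guard on associated VAFs
    expression_cutoff: float = 70.0  # percent stained for EZH2 low/high
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    simulate: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config root must be a mapping: {path}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                [f"unknown config key {k!r}" for k in sorted(unknown)]
            )
        kwargs = dict(raw)
        if "quality" in kwargs:
            kwargs["quality"] = QualityThresholds(**kwargs["quality"])
        if "decision" in kwargs:
            d = dict(kwargs["decision"])
            if "activating_genes" in d:
                d["activating_genes"] = frozenset(d["activating_genes"])
            kwargs["decision"] = DecisionConfig(**d)
        if "simulate" in kwargs:
            sim = dict(kwargs["simulate"])
            for k in ("clonal_vaf_bounds", "subclonal_vaf_bounds"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            kwargs["simulate"] = CohortConfig(**sim)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["decision"]["activating_genes"] = sorted(
            self.decision.activating_genes
        )
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
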