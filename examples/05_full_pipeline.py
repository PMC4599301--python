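"""Simulate a cohort and run the whole screening pipeline on it.

Generates a 92-patient synthetic cohort (IHC cores, Sanger status,
variant calls with planted decoys, survival), then runs scoring ->
filtering -> clonality -> summary statistics -> survival -> treatment
decisions, writing every stage's TSV plus a text report.
"""

import tempfile
from pathlib import Path

from ezh2screen import CohortConfig, PipelineConfig, generate_cohort
from ezh2screen.io import run_pipeline, write_cohort

work = Path(tempfile.mkdtemp(prefix="ezh2screen_demo_"))
bundle = generate_cohort(CohortConfig(seed=1))
paths = write_cohort(bundle, work / "sim")

cfg = PipelineConfig(patients=str(paths["patients"]),
                     variants=str(paths["variants_tsv"]),
                     out_dir=str(work / "out"), seed=1)
results = run_pipeline(cfg)

print(results["summary"].to_string(index=False))
verdicts = {}
for d in results["decisions"]:
    verdicts[d.verdict] = verdicts.get(d.verdict, 0) + 1
print("\ndecision verdicts:", {k.value: v for k, v in verdicts.items()})
from ezh2screen.decision import Rationale

n_direct = sum(
    Rationale.CONCORDANT_MUTANT in d.rationale
    or Rationale.CONCORDANT_WT in d.rationale
    for d in results["decisions"]
)
print(f"{n_direct} patients resolved by concordant Sanger+IHC alone; "
      "the rest need (or got) NGS triage")
print(f"\nall stage outputs under {work / 'out'}")
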