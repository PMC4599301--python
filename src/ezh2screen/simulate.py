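"""Seeded synthetic DLBCL cohorts for exercising the pipeline end to end.

No patient-level data is publicly deposited for this kind of study, so
every pipeline stage is validated against generated cohorts whose
statistical structure mirrors the real one: ~92 patients with ~15% EZH2
Y641 mutants, mutants almost all GCB and strongly enriched for t(14;18),
group-shifted H3K27me2/me3 IHC score distributions (medians 27/18 in WT
vs 18/27 in mutants), GCB patients carrying more validated panel
variants than ABC (means 5.2 vs 2.9), and mostly clonal EZH2 mutations
(subclonal in 3/15) with VAF distributions anchored to the reported
per-patient values (clonal ~38%, subclonal 6-8.4%).

Every latent label (true status, profile concordance, clonality, decoy
rule) is recorded in truth tables so recovery can be tested exactly.
Outputs are byte-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .clonality import ClonalityCall
from .exceptions import ValidationError
from .ihc import percent_to_decile
from .variants import KEPT_CLASSES

#: 34-gene lymphoma panel (EZH2 first, then by typical mutation frequency).
PANEL_GENES = (
    "EZH2", "KMT2D", "CREBBP", "BCL2", "TNFRSF14", "GNA13", "MYD88",
    "PIM1", "CD79B", "TP53", "CARD11", "TNFAIP3", "EP300", "PRDM1",
    "MYC", "BCL6", "B2M", "FOXO1", "MEF2B", "SOCS1", "SGK1", "STAT6",
    "STAT3", "NOTCH1", "NOTCH2", "CIITA", "IRF4", "ITPKB", "BTG1",
    "BTG2", "XPO1", "POU2F2", "TBL1XR1", "CD58",
)

#: hg19 coordinates of the EZH2 Y641 hotspot codon.
EZH2_Y641 = ("7", 148508727, "T", "A")

# patient-level (me2, me3) score pairs and weights; mutant pattern keeps
# me3 > me2 strictly (me3/me2 score > 0), WT pattern me3 <= me2.
# Weights were chosen so group medians land on 18/27 (mutant) and 27/18
# (WT) and the WT intermediate:negative split is roughly 0.4:0.6.
_MUTANT_PATTERN = (
    ((18, 27), 0.40), ((9, 27), 0.15), ((18, 30), 0.10), ((0, 27), 0.10),
    ((9, 18), 0.15), ((0, 9), 0.05), ((18, 21), 0.05),
)
_WT_PATTERN = (
    ((27, 18), 0.30), ((27, 27), 0.30), ((30, 18), 0.10), ((27, 9), 0.10),
    ((18, 18), 0.10), ((27, 0), 0.05), ((18, 9), 0.05),
)

# canonical (intensity, proportion) realizing each score on the grid
_SCORE_DECOMP = {0: (0, 0), 9: (3, 3), 18: (2, 9), 21: (3, 7),
                 27: (3, 9), 30: (3, 10)}


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the study conditions."""

    n_patients: int = 92
    mutant_fraction: float = 14 / 92
    gcb_fraction_wt: float = 36 / 75
    gcb_fraction_mutant: float = 12 / 13
    t1418_prob_wt: float = 8 / 78
    t1418_prob_mutant: float = 9 / 14
    discordant_profile_rate: float = 0.10
    ezh2_low_expression_rate: float = 0.36  # < 70% stained
    variant_mean_gcb: float = 5.2
    variant_mean_abc: float = 2.9
    decoy_rate: float = 0.30  # fraction of raw calls failing a filter rule
    clonal_vaf_mean: float = 0.35
    clonal_vaf_sd: float = 0.08
    clonal_vaf_bounds: tuple = (0.02, 0.6)
    subclonal_vaf_mean: float = 0.07
    subclonal_vaf_sd: float = 0.02
    subclonal_vaf_bounds: tuple = (0.01, 0.15)
    # clonal mutations within one patient share the tumor-purity-driven
    # VAF level; this is their dispersion around it (the reported clonal
    # EZH2/MYD88 pairs differ by 2.5-3.6 VAF points)
    within_patient_vaf_sd: float = 0.03
    subclonal_fraction: float = 3 / 15
    mean_depth: float = 215.0  # negative-binomial mean per site
    depth_dispersion: float = 8.0
    os_rate_low: float = 0.06  # yearly event rates by EZH2 expression group
    os_rate_high: float = 0.18
    pfs_rate_low: float = 0.09
    pfs_rate_high: float = 0.25
    censor_horizon: float = 10.0  # uniform censoring on (0.5, horizon) years
    seed: int = 0

    def __post_init__(self):
        bad = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.endswith(("fraction", "rate", "prob_wt", "prob_mutant")) and not (
                isinstance(v, (int, float)) and 0 <= v <= 1
            ):
                bad.append(f.name)
        for name in ("os_rate_low", "os_rate_high", "pfs_rate_low",
                     "pfs_rate_high", "mean_depth", "censor_horizon"):
            if getattr(self, name) <= 0:
                bad.append(name)
        if self.n_patients < 1:
            bad.append("n_patients")
        if bad:
            raise ValidationError([f"invalid config field {b}" for b in sorted(set(bad))])


@dataclass
class CohortBundle:
    patients: pd.DataFrame
    variants: pd.DataFrame
    truth_patients: pd.DataFrame
    truth_variants: pd.DataFrame


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (bounds well within 4 sd here)."""
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        ok = draw[(draw > lo) & (draw < hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return float(out[0]) if size is None else out


def _cores_from_score(rng, score):
    """Three replicate cores whose max realizes the patient-level score.

    Core 1 carries the intended (intensity, proportion); the replicates
    keep the intensity but lose staining proportion, emulating core-to-
    core heterogeneity without moving the max.
    """
    inten, prop = _SCORE_DECOMP[score]
    cores = [(inten, prop)]
    for _ in range(2):
        p = int(rng.integers(0, prop + 1)) if prop else 0
        cores.append((inten, p) if p else (0, 0))
    return cores


def _draw_pattern(rng, pattern):
    pairs, weights = zip(*pattern)
    i = rng.choice(len(pairs), p=np.asarray(weights))
    return pairs[i]


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate (patients, variants, patient truth, variant truth)."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    n_mut = int(round(n * cfg.mutant_fraction))
    status = np.array(["Y641"] * n_mut + ["WT"] * (n - n_mut))
    rng.shuffle(status)

    n_sub_target = int(round(n_mut * cfg.subclonal_fraction))
    mut_idx = np.flatnonzero(status == "Y641")
    subclonal_ids = set(rng.choice(mut_idx, size=n_sub_target, replace=False)) if n_mut else set()

    patients, truth_p, variant_rows, truth_v = [], [], [], []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        mutant = status[i] == "Y641"
        gcb_p = cfg.gcb_fraction_mutant if mutant else cfg.gcb_fraction_wt
        coo = "GCB" if rng.random() < gcb_p else "ABC"
        t1418 = rng.random() < (cfg.t1418_prob_mutant if mutant else cfg.t1418_prob_wt)
        concordant = rng.random() >= cfg.discordant_profile_rate
        pattern = _MUTANT_PATTERN if mutant == concordant else _WT_PATTERN
        me2, me3 = _draw_pattern(rng, pattern)

        row = {
            "patient_id": pid,
            "ezh2_sanger": str(status[i]),
            "coo": coo,
            "t1418": bool(t1418),
            "ipi_band": "0-2" if rng.random() < 42 / 96 else "3-5",
            "age": int(np.clip(round(rng.normal(64, 13)), 17, 87)),
            "treatment": str(rng.choice(
                ["R-CHOP", "R-ACVBP", "R-mCHOP", "R-IVA"],
                p=[0.55, 0.25, 0.18, 0.02],
            )),
        }

        # EZH2 expression drives the survival dichotomy at 70% stained
        low_expr = rng.random() < cfg.ezh2_low_expression_rate
        pct = rng.uniform(5, 70) if low_expr else rng.uniform(70, 100)
        row["ezh2_percent_stained"] = round(pct, 1)
        rate_os = cfg.os_rate_low if low_expr else cfg.os_rate_high
        rate_pfs = cfg.pfs_rate_low if low_expr else cfg.pfs_rate_high
        for ep, rate in (("os", rate_os), ("pfs", rate_pfs)):
            t_event = rng.exponential(1.0 / rate)
            t_cens = rng.uniform(0.5, cfg.censor_horizon)
            row[f"{ep}_time"] = round(min(t_event, t_cens), 3)
            row[f"{ep}_event"] = bool(t_event <= t_cens)

        ezh2_inten = int(rng.choice([1, 2, 3], p=[0.15, 0.50, 0.35]))
        core_scores = {
            "ezh2": _cores_from_score(
                rng, _nearest_grid_score(ezh2_inten, percent_to_decile(pct))
            ),
            "me1": [(3, 10), (3, 10), (3, 10)],
            "me2": _cores_from_score(rng, me2),
            "me3": _cores_from_score(rng, me3),
        }
        for ab, cores in core_scores.items():
            for k, (ci, cp) in enumerate(cores, start=1):
                row[f"{ab}_core{k}_intensity"] = ci
                row[f"{ab}_core{k}_proportion"] = cp

        clonality = ""
        if mutant:
            clonality = "subclonal" if i in subclonal_ids else "clonal"
        truth_p.append(
            {
                "patient_id": pid,
                "true_status": status[i],
                "profile_concordant": bool(concordant),
                "true_clonality": clonality,
                "ezh2_low_expression": bool(low_expr),
            }
        )
        patients.append(row)

        v_rows, t_rows = _generate_patient_variants(
            rng, cfg, pid, coo, mutant, clonality
        )
        variant_rows.extend(v_rows)
        truth_v.extend(t_rows)

    return CohortBundle(
        patients=pd.DataFrame(patients),
        variants=pd.DataFrame(
            variant_rows,
            columns=["patient_id", "gene", "chrom", "pos", "ref", "alt",
                     "func_class", "in_dbsnp", "in_cosmic", "sift",
                     "tvc_score", "alt_reads", "total_reads", "confirmed"],
        ),
        truth_patients=pd.DataFrame(truth_p),
        truth_variants=pd.DataFrame(
            truth_v,
            columns=["patient_id", "gene", "chrom", "pos", "is_decoy",
                     "decoy_rule", "true_vaf"],
        ),
    )


def _nearest_grid_score(intensity, proportion):
    s = intensity * proportion
    return min(_SCORE_DECOMP, key=lambda g: abs(g - s))


def _gene_locus(gene, offset):
    idx = PANEL_GENES.index(gene)
    chrom = str((idx % 22) + 1)
    return chrom, 1_000_000 + idx * 10_000 + offset


_BASES = "ACGT"


def _draw_clonal_level(rng, cfg):
    """Patient-level clonal VAF, set by tumor purity: ~mutation fraction/2."""
    return _trunc_normal(rng, cfg.clonal_vaf_mean, cfg.clonal_vaf_sd,
                         *cfg.clonal_vaf_bounds)


def _draw_vaf(rng, cfg, kind, level=None):
    """One variant's VAF.

    Clonal mutations scatter tightly around the patient's clonal level
    (all clonal variants ride the same tumor purity); subclonal EZH2
    VAFs come from their own depressed distribution.
    """
    if kind == "subclonal":
        return _trunc_normal(rng, cfg.subclonal_vaf_mean, cfg.subclonal_vaf_sd,
                             *cfg.subclonal_vaf_bounds)
    if level is None:
        level = _draw_clonal_level(rng, cfg)
    return _trunc_normal(rng, level, cfg.within_patient_vaf_sd,
                         *cfg.clonal_vaf_bounds)


def _reads_for_vaf(rng, cfg, vaf):
    p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth)
    depth = max(int(rng.negative_binomial(cfg.depth_dispersion, p)), 30)
    alt = int(rng.binomial(depth, vaf))
    return max(alt, 1), depth


def _generate_patient_variants(rng, cfg, pid, coo, mutant, clonality):
    """Raw (unfiltered) calls for one patient, plus per-variant truth.

    True calls arrive at a Poisson rate whose mean, after removing the
    Bernoulli(decoy_rate) filter-failing decoys, matches the subtype's
    validated-variant mean; the EZH2 Y641 call of a mutant patient is
    always a true call on top of that.
    """
    mean_valid = cfg.variant_mean_gcb if coo == "GCB" else cfg.variant_mean_abc
    if mutant:
        mean_valid = max(mean_valid - 1.0, 1.0)  # EZH2 itself is one validated call
    n_raw = int(rng.poisson(mean_valid / (1.0 - cfg.decoy_rate)))
    level = _draw_clonal_level(rng, cfg)  # shared by this tumor's clonal calls

    v_rows, t_rows = [], []
    if mutant:
        vaf = _draw_vaf(rng, cfg, clonality, level)
        alt, depth = _reads_for_vaf(rng, cfg, vaf)
        chrom, pos, ref, altb = EZH2_Y641
        v_rows.append(_true_call(rng, cfg, pid, "EZH2", chrom, pos, ref, altb,
                                 alt, depth))
        t_rows.append({"patient_id": pid, "gene": "EZH2", "chrom": chrom,
                       "pos": pos, "is_decoy": False, "decoy_rule": "",
                       "true_vaf": round(vaf, 4)})
        if n_raw == 0:  # a mutant needs >= 1 associated call for clonality
            n_raw = 1

    genes = rng.choice(PANEL_GENES[1:], size=n_raw, replace=True)
    for j, gene in enumerate(genes):
        chrom, pos = _gene_locus(gene, j)
        ref = _BASES[rng.integers(4)]
        altb = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
        is_decoy = bool(rng.random() < cfg.decoy_rate)
        vaf = _draw_vaf(rng, cfg, "clonal", level)
        alt, depth = _reads_for_vaf(rng, cfg, vaf)
        if is_decoy:
            rule = rng.choice(["func_class", "dbsnp_not_cosmic", "sift"])
            row = _decoy_call(rng, cfg, pid, gene, chrom, pos, ref, altb,
                              alt, depth, rule)
        else:
            rule = ""
            row = _true_call(rng, cfg, pid, gene, chrom, pos, ref, altb,
                             alt, depth)
        v_rows.append(row)
        t_rows.append({"patient_id": pid, "gene": gene, "chrom": chrom,
                       "pos": pos, "is_decoy": is_decoy, "decoy_rule": rule,
                       "true_vaf": round(vaf, 4)})
    return v_rows, t_rows


_TRUE_CLASSES = tuple(sorted(KEPT_CLASSES))
_TRUE_CLASS_P = None


def _true_class_probs():
    global _TRUE_CLASS_P
    if _TRUE_CLASS_P is None:
        w = {c: 0.04 for c in _TRUE_CLASSES}
        w["nonsynonymous_SNV"] = 0.60
        w["stopgain"] = 0.12
        w["frameshift_deletion"] = 0.08
        total = sum(w.values())
        _TRUE_CLASS_P = np.array([w[c] / total for c in _TRUE_CLASSES])
    return _TRUE_CLASS_P


def _quality_and_confirmation(rng, true_call):
    """TVC score from the true/false mixture, with gray-zone confirmation."""
    if true_call:
        score = round(max(float(rng.normal(50, 15)), 10.0), 1)
        if score < 22:
            conf = "sanger_confirmed" if rng.random() < 0.9 else "pyro_confirmed"
        else:
            conf = "untested"
    else:
        score = round(max(float(rng.normal(6, 2)), 0.1), 1)
        conf = "sanger_refuted" if 9.5 <= score < 22 else "untested"
    return score, conf


def _true_call(rng, cfg, pid, gene, chrom, pos, ref, altb, alt, depth):
    in_dbsnp = bool(rng.random() < 0.2)
    sift = None if rng.random() < 0.3 else round(float(rng.uniform(0, 0.05)), 3)
    score, conf = _quality_and_confirmation(rng, True)
    return {
        "patient_id": pid, "gene": gene, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": altb,
        "func_class": str(rng.choice(_TRUE_CLASSES, p=_true_class_probs())),
        "in_dbsnp": in_dbsnp, "in_cosmic": in_dbsnp,  # dbSNP hits rescued by COSMIC
        "sift": sift, "tvc_score": score,
        "alt_reads": alt, "total_reads": depth, "confirmed": conf,
    }


def _decoy_call(rng, cfg, pid, gene, chrom, pos, ref, altb, alt, depth, rule):
    func = str(rng.choice(_TRUE_CLASSES, p=_true_class_probs()))
    in_dbsnp, in_cosmic = bool(rng.random() < 0.2), False
    if in_dbsnp:
        in_cosmic = True
    sift = None if rng.random() < 0.3 else round(float(rng.uniform(0, 0.05)), 3)
    if rule == "func_class":
        func = "synonymous_SNV"
    elif rule == "dbsnp_not_cosmic":
        in_dbsnp, in_cosmic = True, False
    else:  # sift
        sift = round(float(rng.uniform(0.06, 1.0)), 3)
    score, conf = _quality_and_confirmation(rng, False)
    return {
        "patient_id": pid, "gene": gene, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": altb, "func_class": func,
        "in_dbsnp": in_dbsnp, "in_cosmic": in_cosmic, "sift": sift,
        "tvc_score": score, "alt_reads": alt, "total_reads": depth,
        "confirmed": conf,
    }


def generate_clonality_cohort(
    rng: np.random.Generator,
    n_clonal: int = 12,
    n_subclonal: int = 3,
    config: CohortConfig | None = None,
) -> list[ClonalityCall]:
    """EZH2-mutant VAF cohort for clonality-recovery studies.

    Each patient gets a clonal VAF level from the anchored distribution
    (truncated Normal(0.35, 0.08)); clonal mutations — associated ones
    always, EZH2 in clonal patients — scatter tightly around it, since
    mutations carried by the whole tumor share its purity. Subclonal
    patients draw the EZH2 VAF from the depressed distribution
    (truncated Normal(0.07, 0.02)) instead. Patient ids encode the
    truth (C*/S*) for recovery checks.
    """
    cfg = config or CohortConfig()
    calls = []
    for i in range(n_clonal + n_subclonal):
        sub = i >= n_clonal
        kind = "subclonal" if sub else "clonal"
        level = _draw_clonal_level(rng, cfg)
        n_assoc = 1 + int(rng.poisson(3))
        calls.append(
            ClonalityCall(
                patient_id=("S" if sub else "C") + f"{i + 1:02d}",
                ezh2_vaf=_draw_vaf(rng, cfg, kind, level),
                associated_vafs=[
                    _draw_vaf(rng, cfg, "clonal", level) for _ in range(n_assoc)
                ],
            )
        )
    return calls
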