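"""Readers, writers and the end-to-end pipeline orchestrator.

Patient tables are TSV/CSV (delimiter sniffed from the extension or the
header line); variant calls are VCF 4.2 (read through cyvcf2: QUAL is
the caller quality score, INFO keys PATIENT/FUNC_CLASS/DBSNP/COSMIC/
SIFT/AO/DP/CONFIRMED carry the annotations and read counts) or an
annotated TSV with the same columns. NA tokens are "", "NA" and ".".
All machine outputs are TSV; VAFs serialize as fractions with 4 decimals.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import clonality as clonality_mod
from . import decision as decision_mod
from . import ihc, stats, survival
from . import variants as variants_mod
from .config import PipelineConfig
from .exceptions import UndefinedVAFError, ValidationError

logger = logging.getLogger("ezh2screen")

NA_TOKENS = ["", "NA", "."]

_PATIENT_ENUMS = {
    "ezh2_sanger": {"WT", "Y641"},
    "coo": {"GCB", "ABC", "other"},
    "ipi_band": {"0-2", "3-5"},
}


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in (".tsv", ".txt"):
        return "\t"
    head = path.open().readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _to_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if pd.isna(v):
        return None
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def read_patient_table(path) -> pd.DataFrame:
    """Load and validate a patient table; aggregates every violation."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), na_values=NA_TOKENS,
                     keep_default_na=False)
    errors = []
    if "patient_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column patient_id")
    df["patient_id"] = df["patient_id"].astype(str)
    dups = df.patient_id[df.patient_id.duplicated()].unique()
    errors.extend(f"duplicate patient_id {d!r}" for d in dups)

    for col, allowed in _PATIENT_ENUMS.items():
        if col not in df.columns:
            continue
        for i, v in df[col].items():
            if pd.notna(v) and v not in allowed:
                errors.append(
                    f"row {i + 2}: {col}={v!r} not in {sorted(allowed)}"
                )

    if "t1418" in df.columns:
        for i, v in df["t1418"].items():
            try:
                df.loc[i, "t1418"] = _to_bool(v)
            except ValueError as e:
                errors.append(f"row {i + 2}: t1418 {e}")

    numeric = ["age", "os_time", "pfs_time", "ezh2_percent_stained"] + [
        f"{ab}_core{k}_{f}"
        for ab in ihc.ANTIBODIES
        for k in (1, 2, 3)
        for f in ("intensity", "proportion")
    ]
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        errors.extend(f"row {i + 2}: {col}={df.loc[i, col]!r} not numeric" for i in bad)
        df[col] = coerced

    for ep in ("os", "pfs"):
        t, e = f"{ep}_time", f"{ep}_event"
        if t in df.columns and e in df.columns:
            mism = df.index[df[t].isna() != df[e].isna()]
            errors.extend(
                f"row {i + 2}: {t}/{e} must be jointly present or absent"
                for i in mism
            )
            df[e] = df[e].map(lambda v: _to_bool(v))

    if errors:
        raise ValidationError([f"{path.name}: {m}" for m in errors])
    return df


def write_patient_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _record_from_row(row) -> variants_mod.VariantRecord:
    sift = row.get("sift")
    if sift is not None and (isinstance(sift, float) and math.isnan(sift)):
        sift = None
    return variants_mod.VariantRecord(
        patient_id=str(row["patient_id"]),
        gene=str(row["gene"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        func_class=str(row["func_class"]),
        in_dbsnp=bool(_to_bool(row["in_dbsnp"])),
        in_cosmic=bool(_to_bool(row["in_cosmic"])),
        sift=None if sift is None else float(sift),
        tvc_score=float(row["tvc_score"]),
        alt_reads=int(row["alt_reads"]),
        total_reads=int(row["total_reads"]),
        confirmed=str(row.get("confirmed") or "untested"),
    )


def variants_from_frame(df: pd.DataFrame) -> list:
    """VariantRecords from a tabular frame (simulator output or TSV)."""
    records, skipped = [], 0
    for i, row in df.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValidationError, UndefinedVAFError, ValueError, KeyError) as e:
            skipped += 1
            logger.warning("variant row %d skipped: %s", i + 2, e)
    if skipped:
        logger.warning("%d variant rows excluded by validation", skipped)
    return records


def read_variants(path) -> list:
    """Load VariantRecords from VCF 4.2 or an annotated TSV/CSV."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), na_values=NA_TOKENS,
                     keep_default_na=False)
    required = {"patient_id", "gene", "chrom", "pos", "ref", "alt",
                "func_class", "in_dbsnp", "in_cosmic", "tvc_score",
                "alt_reads", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path.name}: missing variant columns {sorted(missing)}"
        )
    if "sift" not in df.columns:
        df["sift"] = None
    return variants_from_frame(df)


def _read_vcf(path: Path) -> list:
    records, skipped = [], 0
    try:
        vcf = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare Exceptions on parse failure
        raise ValidationError(f"{path.name}: not a readable VCF: {e}") from e
    for n, v in enumerate(vcf, start=1):
        info = dict(v.INFO)
        try:
            total = int(info["DP"])
            alt_reads = int(info["AO"])
            records.append(
                variants_mod.VariantRecord(
                    patient_id=str(info.get("PATIENT", path.stem)),
                    gene=str(info["GENE"]),
                    chrom=str(v.CHROM),
                    pos=int(v.POS),
                    ref=str(v.REF),
                    alt=str(v.ALT[0]) if v.ALT else ".",
                    func_class=str(info["FUNC_CLASS"]),
                    in_dbsnp=bool(int(info.get("DBSNP", 0))),
                    in_cosmic=bool(int(info.get("COSMIC", 0))),
                    # htslib stores QUAL/INFO floats in single precision;
                    # round past the serialized decimals to undo the cast
                    sift=round(float(info["SIFT"]), 6) if "SIFT" in info else None,
                    tvc_score=round(float(v.QUAL), 4) if v.QUAL is not None else 0.0,
                    alt_reads=alt_reads,
                    total_reads=total,
                    confirmed=str(info.get("CONFIRMED", "untested")),
                )
            )
        except (ValidationError, UndefinedVAFError, ValueError, KeyError) as e:
            skipped += 1
            logger.warning("%s record %d skipped: %s", path.name, n, e)
    if skipped:
        logger.warning("%d VCF records excluded by validation", skipped)
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ezh2screen
##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">
##INFO=<ID=FUNC_CLASS,Number=1,Type=String,Description="Functional class">
##INFO=<ID=DBSNP,Number=1,Type=Integer,Description="Present in dbSNP138">
##INFO=<ID=COSMIC,Number=1,Type=Integer,Description="Present in COSMIC64">
##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate-allele read count">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=CONFIRMED,Number=1,Type=String,Description="Orthogonal confirmation status">
"""


def _contig_lines(df: pd.DataFrame) -> str:
    def key(c):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    return "".join(
        f"##contig=<ID={c}>\n" for c in sorted(df.chrom.astype(str).unique(), key=key)
    )


def write_variants_vcf(df: pd.DataFrame, path) -> None:
    """Emit a variant frame as a minimal, sorted VCF 4.2 text file."""
    lines = [_VCF_HEADER, _contig_lines(df),
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"]
    order = df.sort_values(["chrom", "pos", "patient_id"], kind="stable")
    for _, r in order.iterrows():
        info = [
            f"PATIENT={r.patient_id}",
            f"GENE={r.gene}",
            f"FUNC_CLASS={r.func_class}",
            f"DBSNP={int(_to_bool(r.in_dbsnp))}",
            f"COSMIC={int(_to_bool(r.in_cosmic))}",
        ]
        if pd.notna(r.get("sift")):
            info.append(f"SIFT={float(r.sift):g}")
        info.append(f"AO={int(r.alt_reads)}")
        info.append(f"DP={int(r.total_reads)}")
        conf = r.get("confirmed")
        if pd.notna(conf) and conf and conf != "untested":
            info.append(f"CONFIRMED={conf}")
        lines.append(
            f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t"
            f"{float(r.tvc_score):g}\t.\t{';'.join(info)}\n"
        )
    Path(path).write_text("".join(lines))


def variants_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id, "gene": r.gene, "chrom": r.chrom,
                "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "func_class": r.func_class, "in_dbsnp": r.in_dbsnp,
                "in_cosmic": r.in_cosmic, "sift": r.sift,
                "tvc_score": r.tvc_score, "alt_reads": r.alt_reads,
                "total_reads": r.total_reads, "vaf": round(r.vaf, 4),
                "confirmed": r.confirmed.value,
            }
        )
    return pd.DataFrame(rows)


def clonality_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "ezh2_vaf": round(c.ezh2_vaf, 4),
                "n_associated": len(c.associated_vafs),
                "mean_associated_vaf": (
                    round(c.mean_associated_vaf, 4)
                    if c.mean_associated_vaf is not None else None
                ),
                "log_ratio": (
                    round(c.log_ratio, 4) if math.isfinite(c.log_ratio) else None
                ),
                "cluster": c.cluster.value,
            }
            for c in calls
        ]
    )


def write_cohort(bundle, out_dir) -> dict:
    """Write a simulated cohort: patients.tsv, variants.tsv/.vcf, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.tsv",
        "variants_tsv": out / "variants.tsv",
        "variants_vcf": out / "variants.vcf",
        "truth_patients": out / "truth.tsv",
        "truth_variants": out / "truth_variants.tsv",
    }
    bundle.patients.to_csv(paths["patients"], sep="\t", index=False)
    bundle.variants.to_csv(paths["variants_tsv"], sep="\t", index=False)
    write_variants_vcf(bundle.variants, paths["variants_vcf"])
    bundle.truth_patients.to_csv(paths["truth_patients"], sep="\t", index=False)
    bundle.truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    return paths


def _config_hash(cfg: PipelineConfig) -> str:
    # hash the analysis parameters only, not filesystem paths
    blob = json.dumps(
        {k: str(v) for k, v in cfg.__dict__.items()
         if k not in ("patients", "variants", "out_dir")},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """score-ihc -> filter-variants -> clonality -> stats -> survival -> decide.

    Writes every stage's TSV under ``cfg.out_dir`` plus a plain-text
    summary; returns the in-memory results keyed by stage. Stages whose
    inputs are absent are skipped with a warning.
    """
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("ezh2screen %s | seed=%d | config=%s",
                __version__, cfg.seed, _config_hash(cfg))

    if cfg.patients is None:
        raise ValidationError("pipeline requires a patient table")
    patients = read_patient_table(cfg.patients)
    results: dict = {}

    scored = ihc.score_patient_table(patients)
    cohort = patients.merge(scored, on="patient_id")
    cohort.loc[~cohort.usable.astype(bool), "me3me2_score"] = np.nan
    scored.to_csv(out / "scores.tsv", sep="\t", index=False)
    results["scores"] = scored

    kept = []
    clon_calls = []
    if cfg.variants is not None:
        records = read_variants(cfg.variants)
        kept, audit = variants_mod.filter_variants(records)
        kept = [
            r for r in kept
            if variants_mod.triage_by_quality(r, cfg.quality)
            is variants_mod.Triage.ACCEPT
        ]
        variants_to_frame(kept).to_csv(out / "kept_variants.tsv", sep="\t", index=False)
        pd.DataFrame(audit).to_csv(out / "filter_audit.tsv", sep="\t", index=False)
        results["kept_variants"] = kept

        by_patient: dict[str, list] = {}
        for r in kept:
            by_patient.setdefault(r.patient_id, []).append(r)
        mutants = set(patients.patient_id[patients.ezh2_sanger == "Y641"])
        for pid in sorted(mutants & set(by_patient)):
            recs = by_patient[pid]
            ez = [r for r in recs if r.gene == "EZH2"]
            assoc = [r.vaf for r in recs if r.gene != "EZH2"]
            if cfg.cap_vaf_at_half:
                assoc = [min(v, 0.5) for v in assoc]
            if ez:
                clon_calls.append(
                    clonality_mod.ClonalityCall(
                        patient_id=pid, ezh2_vaf=ez[0].vaf, associated_vafs=assoc
                    )
                )
        clon_calls = clonality_mod.classify_clonality(
            clon_calls, min_separation=cfg.clonality_min_separation
        )
        clonality_to_frame(clon_calls).to_csv(out / "clonality.tsv", sep="\t", index=False)
        results["clonality"] = clon_calls

    summary = stats.build_summary_table(cohort)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    results["summary"] = summary

    surv_cols = {"ezh2_percent_stained", "os_time", "os_event"}
    if surv_cols <= set(cohort.columns):
        for ep in ("os", "pfs"):
            if f"{ep}_time" not in cohort.columns:
                continue
            try:
                res = survival.compare_survival(cohort, ep, cfg.expression_cutoff)
            except ValidationError as e:
                logger.warning("survival (%s) skipped: %s", ep, e)
                continue
            for grp in ("low", "high"):
                res[grp].table.to_csv(out / f"km_{ep}_{grp}.tsv", sep="\t", index=False)
            results[f"survival_{ep}"] = res
    else:
        logger.warning("survival columns absent; survival stage skipped")

    decisions = decision_mod.decide_cohort(
        cohort, clon_calls, kept, cfg.decision
    )
    dec_df = pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "verdict": d.verdict.value,
                "rationale": ",".join(f.value for f in d.rationale),
            }
            for d in decisions
        ]
    )
    dec_df.to_csv(out / "decisions.tsv", sep="\t", index=False)
    results["decisions"] = decisions

    _write_report(out / "report.txt", cfg, results, dec_df)
    return results


def _write_report(path, cfg, results, dec_df):
    from . import __version__

    lines = [
        f"ezh2screen {__version__} pipeline report",
        f"seed: {cfg.seed}   config hash: {_config_hash(cfg)}",
        "",
        "== Cohort summary (by EZH2 Sanger status) ==",
        results["summary"].to_string(index=False),
        "",
    ]
    if "clonality" in results:
        lines += [
            "== EZH2 clonality ==",
            clonality_to_frame(results["clonality"]).to_string(index=False),
            "",
        ]
    for ep in ("os", "pfs"):
        key = f"survival_{ep}"
        if key in results:
            t = results[key]["test"]
            lines.append(
                f"{ep.upper()} log-rank (EZH2-low vs -high): "
                f"chi2={t.statistic:.3f}, p={stats.format_p(t.p_value)} "
                f"(n={results[key]['n']})"
            )
    if not dec_df.empty:
        counts = dec_df.verdict.value_counts().to_dict()
        lines += ["", "== Treatment-decision verdicts ==",
                  json.dumps(counts, indent=0), "", decision_mod.DISCLAIMER]
    Path(path).write_text("\n".join(lines) + "\n")
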