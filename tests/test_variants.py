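"""Somatic filter rules, quality triage and VAF computation."""

import itertools

import pytest

from ezh2screen import (
    QualityThresholds,
    Triage,
    UndefinedVAFError,
    ValidationError,
    VariantRecord,
    compute_vaf,
    derive_quality_thresholds,
    filter_variants,
    triage_by_quality,
)
from ezh2screen.variants import KEPT_CLASSES


@pytest.mark.parametrize(
    "alt,total,expected", [(0, 100, 0.0), (50, 100, 0.5), (24, 400, 0.06)]
)
def test_compute_vaf(alt, total, expected):
    assert compute_vaf(alt, total) == pytest.approx(expected)


def test_compute_vaf_errors():
    with pytest.raises(UndefinedVAFError):
        compute_vaf(0, 0)
    with pytest.raises(ValidationError):
        compute_vaf(10, 5)
    with pytest.raises(ValidationError):
        compute_vaf(-1, 5)


def _rec(**kw):
    base = dict(
        patient_id="P1", gene="EZH2", chrom="7", pos=148508727, ref="T",
        alt="A", func_class="nonsynonymous_SNV", in_dbsnp=False,
        in_cosmic=False, sift=None, tvc_score=30.0, alt_reads=40,
        total_reads=100,
    )
    base.update(kw)
    return VariantRecord(**base)


def test_unknown_functional_class_is_named_in_error():
    with pytest.raises(ValidationError, match="weird_class"):
        _rec(func_class="weird_class")


def test_sift_out_of_range_rejected():
    with pytest.raises(ValidationError):
        _rec(sift=1.5)


@pytest.mark.parametrize(
    "func,dbsnp,cosmic,sift,kept",
    [
        ("nonsynonymous_SNV", True, False, 0.01, False),  # dbSNP not COSMIC
        ("synonymous_SNV", False, False, 0.0, False),  # class not kept
        ("stopgain", True, True, None, True),  # COSMIC rescues dbSNP hit
        ("nonsynonymous_SNV", False, False, 0.06, False),  # tolerated SIFT
        ("frameshift_deletion", False, True, 0.05, True),  # boundary SIFT kept
        ("nonsynonymous_SNV", False, False, None, True),  # missing SIFT passes
    ],
)
def test_filter_rule_examples(func, dbsnp, cosmic, sift, kept):
    r = _rec(func_class=func, in_dbsnp=dbsnp, in_cosmic=cosmic, sift=sift)
    out, audit = filter_variants([r])
    assert (len(out) == 1) is kept
    assert audit[0]["kept"] is kept


def test_filter_matches_truth_table_over_all_annotation_combos():
    classes = sorted(KEPT_CLASSES) + ["synonymous_SNV", "other"]
    sifts = [None, 0.0, 0.05, 0.051, 0.9]
    records, expected = [], []
    for func, dbsnp, cosmic, sift in itertools.product(
        classes, [False, True], [False, True], sifts
    ):
        records.append(
            _rec(func_class=func, in_dbsnp=dbsnp, in_cosmic=cosmic, sift=sift)
        )
        # independently coded truth table of the three conjunctive rules
        expected.append(
            func in KEPT_CLASSES
            and not (dbsnp and not cosmic)
            and not (sift is not None and sift > 0.05)
        )
    kept, audit = filter_variants(records)
    assert [a["kept"] for a in audit] == expected
    assert len(kept) == sum(expected)


def test_filter_is_idempotent_order_independent_and_audits_each_record(rng):
    records = [
        _rec(
            pos=int(1000 + i),
            func_class=str(rng.choice(sorted(KEPT_CLASSES) + ["synonymous_SNV"])),
            in_dbsnp=bool(rng.integers(2)),
            in_cosmic=bool(rng.integers(2)),
            sift=None if rng.random() < 0.3 else float(rng.random()),
        )
        for i in range(50)
    ]
    kept, audit = filter_variants(records)
    assert len(audit) == len(records)
    kept2, _ = filter_variants(kept)
    assert kept2 == kept
    rev_kept, rev_audit = filter_variants(records[::-1])
    assert rev_kept == kept[::-1]
    assert rev_audit == audit[::-1]


@pytest.mark.parametrize(
    "score,confirmed,expected",
    [
        (25.0, "untested", Triage.ACCEPT),
        (5.0, "untested", Triage.REJECT),
        (15.0, "untested", Triage.CONFIRM_REQUIRED),
        (15.0, "sanger_confirmed", Triage.ACCEPT),
        (15.0, "pyro_confirmed", Triage.ACCEPT),
        (15.0, "sanger_refuted", Triage.REJECT),
        (22.0, "untested", Triage.ACCEPT),  # boundary: >= accepts
        (9.5, "untested", Triage.CONFIRM_REQUIRED),  # boundary: not below
    ],
)
def test_triage_zones_and_confirmation(score, confirmed, expected):
    r = _rec(tvc_score=score, confirmed=confirmed)
    assert triage_by_quality(r) is expected


def test_triage_partitions_and_is_monotone():
    order = {Triage.REJECT: 0, Triage.CONFIRM_REQUIRED: 1, Triage.ACCEPT: 2}
    prev = -1
    for s in [x / 2 for x in range(0, 61)]:
        t = triage_by_quality(_rec(tvc_score=s))
        assert order[t] >= prev
        prev = order[t]


def test_derive_thresholds_published_zone():
    t = derive_quality_thresholds([22.0, 30.0, 55.0], [1.0, 4.2, 9.4])
    assert (t.reject_below, t.accept_at_or_above) == (9.5, 22.0)
    assert t.derived


def test_derive_thresholds_simple_separation():
    t = derive_quality_thresholds([30.0, 40.0], [1.0, 2.0])
    assert (t.reject_below, t.accept_at_or_above) == (2.1, 30.0)


def test_derive_thresholds_interleaved_falls_back_with_warning():
    with pytest.warns(UserWarning, match="defaults"):
        t = derive_quality_thresholds([5.0, 15.0], [10.0, 20.0])
    assert (t.reject_below, t.accept_at_or_above) == (9.5, 22.0)
    assert not t.derived and t.warning


def test_thresholds_invariant():
    with pytest.raises(ValidationError):
        QualityThresholds(reject_below=25.0, accept_at_or_above=22.0)


def test_generated_decoys_match_truth_table_oracle(default_bundle):
    """On simulated calls, the filter decision equals the generator's truth."""
    from ezh2screen.io import variants_from_frame

    records = variants_from_frame(default_bundle.variants)
    assert len(records) == len(default_bundle.variants) >= 400
    _, audit = filter_variants(records)
    truth = default_bundle.truth_variants
    key = lambda pid, chrom, pos, gene: (pid, chrom, pos, gene)
    decoy = {
        key(r.patient_id, str(r.chrom), r.pos, r.gene): r.is_decoy
        for r in truth.itertuples()
    }
    for a in audit:
        assert a["kept"] == (not decoy[key(a["patient_id"], str(a["chrom"]),
                                           a["pos"], a["gene"])])
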