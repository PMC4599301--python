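"""Filter and triage annotated panel variants for one patient.

The somatic filter keeps protein-affecting classes, drops dbSNP entries
absent from COSMIC and tolerated SIFT predictions; survivors are binned
by caller quality: >= 22 accepted, < 9.5 rejected, gray zone in between
needing Sanger/pyrosequencing confirmation.
"""

from ezh2screen import VariantRecord, filter_variants, triage_by_quality

calls = [
    VariantRecord("P1", "EZH2", "7", 148508727, "T", "A", "nonsynonymous_SNV",
                  in_dbsnp=False, in_cosmic=True, sift=0.0, tvc_score=88.0,
                  alt_reads=160, total_reads=400),
    VariantRecord("P1", "KMT2D", "12", 49420000, "C", "T", "stopgain",
                  in_dbsnp=False, in_cosmic=False, sift=None, tvc_score=15.0,
                  alt_reads=80, total_reads=230, confirmed="sanger_confirmed"),
    VariantRecord("P1", "TP53", "17", 7578000, "G", "A", "nonsynonymous_SNV",
                  in_dbsnp=True, in_cosmic=False, sift=0.01, tvc_score=60.0,
                  alt_reads=90, total_reads=250),  # known SNP, not in COSMIC
    VariantRecord("P1", "GNA13", "17", 63010000, "A", "G", "synonymous_SNV",
                  in_dbsnp=False, in_cosmic=False, sift=None, tvc_score=45.0,
                  alt_reads=70, total_reads=200),  # silent -> dropped
]

kept, audit = filter_variants(calls)
for a in audit:
    print(f"{a['gene']:7s} kept={a['kept']}  "
          f"(class={a['pass_func_class']}, dbsnp_rule={a['pass_dbsnp_not_cosmic']}, "
          f"sift={a['pass_sift']})")
for r in kept:
    print(f"{r.gene:7s} VAF={r.vaf:.1%}  quality triage -> "
          f"{triage_by_quality(r).value}")
# the gray-zone KMT2D call is promoted to accept by its Sanger confirmation
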