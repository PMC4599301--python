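"""Call clonal vs subclonal EZH2 mutations from relative VAFs.

For each EZH2-mutant patient, the EZH2 VAF is compared with the mean VAF
of the patient's other validated mutations via log2(EZH2/mean); exact
1-D 2-means splits the cohort and the lower-center cluster is subclonal
(the mutation sits in a minority tumor subpopulation, so inhibitor
benefit is expected to be reduced).
"""

from ezh2screen import ClonalityCall, Clonality, classify_clonality

cohort = [
    # VAF pairs echoing reported patients: similar VAFs = clonal ...
    ClonalityCall("1639", ezh2_vaf=0.389, associated_vafs=[0.364]),
    ClonalityCall("1478", ezh2_vaf=0.238, associated_vafs=[0.274]),
    ClonalityCall("445", ezh2_vaf=0.41, associated_vafs=[0.37, 0.44]),
    ClonalityCall("1687", ezh2_vaf=0.12, associated_vafs=[0.10, 0.13]),
    # ... depressed EZH2 VAF against clonal associates = subclonal
    ClonalityCall("1528", ezh2_vaf=0.06, associated_vafs=[0.381]),
    ClonalityCall("1623", ezh2_vaf=0.084, associated_vafs=[0.35, 0.30]),
]

for c in classify_clonality(cohort):
    print(f"patient {c.patient_id:>5s}: EZH2 VAF {c.ezh2_vaf:.1%}, "
          f"mean associated {c.mean_associated_vaf:.1%}, "
          f"log ratio {c.log_ratio:+.2f} -> {c.cluster.value}")
n_sub = sum(c.cluster is Clonality.SUBCLONAL for c in cohort)
print(f"{n_sub}/{len(cohort)} subclonal EZH2 mutations")
# note patient 1687: low VAFs across the board (low tumor content) still
# cluster as clonal because the *ratio* to associated mutations is ~1
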