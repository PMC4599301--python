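"""Score IHC cores and call methylation profiles for a tiny cohort.

Each tumor is stained for H3K27me2 and H3K27me3 on triplicate TMA cores;
the per-antibody score is intensity (0-3) x proportion decile (0-10),
max over cores, and the me3/me2 score log2((me3+1)/(me2+1)) calls the
methylation profile: > 0 mutant-like, = 0 intermediate, < 0 WT-like.
"""

from ezh2screen import CoreStain, classify_profile, me3me2_score, patient_score

# a Y641-mutant-looking tumor: strong me3, weak me2
me3 = patient_score([CoreStain("me3", 3, 9), CoreStain("me3", 3, 7), CoreStain("me3", 0, 0)])
me2 = patient_score([CoreStain("me2", 1, 9), CoreStain("me2", 2, 3)])
score = me3me2_score(me3, me2)
call = classify_profile(score)
print(f"me3 score {me3}/30, me2 score {me2}/30")
print(f"me3/me2 score = {score:+.3f} -> profile {call.profile.value} "
      f"(merged {call.merged.value})")
# a positive score means trimethylation dominates dimethylation, the
# in-vivo signature of an EZH2 gain-of-function mutation

# the score range bound: strongest possible me3 staining with negative me2
print(f"range bound: {me3me2_score(27, 0):.1f} log2 units")
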