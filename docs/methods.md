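# Methods

## The screening problem

EZH2 Y641 gain-of-function mutations shift the H3K27 methylation
equilibrium: trimethylation (H3K27me3) accumulates while the
dimethylated intermediate (H3K27me2) is depleted. Because EZH2
inhibitors act on this hyperactive enzyme, a practical screen wants
three complementary readouts per patient: (i) whether the *protein-level
phenotype* is present (IHC), (ii) whether the *mutation* is present
(Sanger of the Y641 hotspot), and (iii) when the two disagree, what
targeted sequencing says about clonality, VAF and associated mutations.
`ezh2screen` implements the quantitative parts of that screen.

## IHC scoring model

A core's score is `intensity × proportion` on the 0–3 × 0–10 grid
(range 0–30). Intensity 0 extends the instrument's 1–3 scale so a fully
negative core can be encoded in either field; a 0 in one field forces
the other to 0 at load, making the two conventions equivalent. The
patient-level score per antibody is the maximum over up to three
replicate cores; a patient missing every core for H3K27me2 or H3K27me3
is flagged unusable and excluded from score analyses.

The balance score is `log2((me3+1)/(me2+1))`, bounded by ±log2(31) ≈
±4.95; the +1 offsets keep negative staining finite. It is antisymmetric
and strictly monotone in each argument (property-tested over the full
grid). Profiles are called by sign; the merged two-class rule
(mutant-like iff score > 0) is the screening operating point. The
threshold sweep evaluates every distinct classification (`score > t`)
induced by midpoints of adjacent unique scores plus 0 itself; ties break
toward fewer false negatives (a screen prefers not to miss mutants),
then the smaller threshold.

Inter-rater agreement uses weighted Cohen kappa, linear disagreement
weights by default (quadratic selectable). The rated objects are the
three profiles. K<sub>max</sub> is computed exactly by linear
programming: maximize weighted agreement over all confusion matrices
with the observed marginals; kappa/K<sub>max</sub> then separates
genuine disagreement from marginal imbalance. With rater-level raw data
unavailable, the kappa code is validated against a hand-computed
confusion-matrix fixture, not a published value.

## Variant filtering and triage

Three conjunctive rules: functional class in the protein-affecting set
(frameshift/nonframeshift indels and substitutions, splicing,
nonsynonymous, stopgain, stoploss); not (in dbSNP and absent from
COSMIC); not (SIFT present and > 0.05). A missing SIFT passes, since
the rule only discards predictions above the cutoff. Database
memberships are input annotations, not live lookups, keeping the
pipeline hermetic and version-frozen. Filtering is per-record, hence
idempotent and order-independent; an audit row per input records each
rule's outcome.

Quality triage partitions the caller-score line at 9.5 and 22 (the
published bands, kept as defaults): below 9.5 reject, at or above 22
accept, between them a gray zone resolved by orthogonal confirmation
(Sanger/pyro confirmation promotes, Sanger refutation demotes). The
band-derivation helper reconstructs thresholds from validated calls by
empirical separation — one decimal step above the worst refuted score,
and the smallest confirmed score exceeding every refuted one — because
the original normal-probability-plot procedure is not recoverable in
detail; when the two sets interleave it falls back to the defaults with
a warning.

VAF is `alt_reads / total_reads`, stored as a fraction in [0, 1]
(rendered as percent in human reports); zero-depth sites raise an
explicit undefined-VAF error rather than silently scoring 0.

## Clonality

Per EZH2-mutant patient, `log2(EZH2 VAF / mean(associated VAFs))`. Log
base 2 (unstated convention; the base only rescales, labels are
unaffected). The arithmetic mean is taken on the fraction scale; VAFs
above 0.5 (possible copy-number effects — VAFs are deliberately not
CNV-corrected) enter unchanged, with an optional cap-at-0.5 flag.
Patients with no associated mutation or a zero VAF are indeterminate
and excluded from clustering. No tumor-purity adjustment is applied:
a low-purity sample depresses EZH2 and associated VAFs together, so the
ratio is already purity-robust to first order.

Clustering is exact 1-D 2-means: optimal clusters are contiguous in
sorted order, so scanning the n−1 contiguous splits finds the global
within-cluster-sum-of-squares optimum deterministically — strictly
stronger than seeded Lloyd iterations, and validated against full
2^n partition enumeration for n ≤ 15. The lower-center cluster is
subclonal. Because 2-means always splits, a minimum-separation guard
(default 0.5 log2 units between centers, configurable) declares a
unimodal cohort all-clonal; the default is half the typical gap between
a clonal ratio (≈0) and the observed subclonal ratios (≈−2 to −2.7).

## Cohort statistics

scipy.stats supplies the machinery; the conventions pinned here are the
substance: Fisher exact is two-sided by minimum likelihood (sum of
hypergeometric probabilities of same-margin tables no more probable
than observed, with 1e−7 relative tolerance) — the convention that
reproduces all four published 2×2 p-values at their printed precision.
Chi-square carries no continuity correction (df = 2 on the 2×3 profile
table, giving the published 1e−5 order). An exact 2×3 Freeman–Halton
test is provided alongside (enumeration with the same minimum-likelihood
rule; it matches R's `fisher.test` on the profile table at 3.82e−5 —
note it sits ~3.5× above the chi-square p, so the two tests agree in
order of magnitude, not to a factor of 3). The rank-sum test uses the
normal approximation with tie and continuity corrections, appropriate
for 0–30 IHC scores with heavy ties, and is validated against a
10^5-draw Monte-Carlo permutation oracle. p-values display with 2
significant figures, scientific below 1e−3.

## Survival

Patients dichotomize on the raw percentage of EZH2-stained tumor cells
(< 70% low, ≥ 70% high); the raw percent is carried through the patient
table precisely so this cutoff never depends on the 0–10 decile binning.
Kaplan–Meier estimation and the log-rank test come from lifelines;
ties between events and censorings resolve events-first. The published
3-year OS/PFS percentages require patient-level survival data that is
not available, so the module is validated by construction properties
(product-limit equals empirical survival without censoring, nominal
rejection rate under label permutation) and hand-computed fixtures.

## Decision algorithm

The Sanger × merged-profile grid: concordant mutant → recommend;
concordant WT → deny; discordant without NGS → NGS required. With NGS:
a Sanger-mutant, WT-like-profile patient whose EZH2 mutation is
subclonal or below the low-VAF cutoff (default 10%, bracketing the
observed 6% and 8.4% subclonal VAFs) is recommended with caution and
the explaining flags; if NGS instead shows a clonal, high-VAF mutation,
nothing explains the WT-like profile, so the verdict is
recommend-with-caution flagged `no_explanatory_finding` — plain
`recommend` stays reserved for concordant mutants. A Sanger-WT,
mutant-like-profile patient with a validated hit in the activating-gene
watch list (default {MYD88, PIM1, PRDM1, MYC}, fully configurable since
the evidence is anecdotal) is "consider despite WT"; with no hit, deny
with the same flag. Verdicts are advisory research labels and carry an
explicit disclaimer.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, with
defaults fixed to the study conditions: 92 patients, mutant fraction
14/92; GCB fraction 36/75 among WT and 12/13 among mutants; t(14;18)
probability 8/78 (WT) and 9/14 (mutant); validated-variant means 5.2
(GCB) and 2.9 (ABC); clonal VAFs ~ Normal(0.35, 0.08) truncated to
(0.02, 0.6) and subclonal ~ Normal(0.07, 0.02) truncated to
(0.01, 0.15), anchored to the reported per-patient VAFs; subclonal
fraction 3/15 among mutants; read depth ~ negative binomial with mean
215; decoy (filter-failing) rate 0.30 of raw calls.

VAFs are generated hierarchically: each tumor draws a clonal VAF
*level* from the anchored truncated Normal(0.35, 0.08) — the level a
fully clonal heterozygous mutation shows at that tumor's purity — and
every clonal mutation in the patient (associated mutations always, EZH2
when clonal) scatters around it with within-patient standard deviation
0.03, matching the reported clonal pairs (38.9/36.4 and 23.8/27.4 VAF
percent). A subclonal EZH2 VAF is drawn from the depressed truncated
Normal(0.07, 0.02) instead. The shared level is what makes the
log-ratio statistic work: purity cancels in the ratio, so clonal log
ratios concentrate near 0 (sd ≈ 0.13) while subclonal ones land near
−2.3 with the wider spread (sd ≈ 0.5) induced by the independence of
the subclonal VAF from the patient's level. Under these conditions the
exact-recovery rate of the 3 planted subclonal patients is ≈94–95% of
seeded 15-patient cohorts, sitting at the boundary of the ≥95% recovery
check — the residual misses are subclonal draws near the 0.15
truncation bound inside low-purity tumors.

IHC is generated as categorical draws over joint (me2, me3) score pairs
on the instrument's discrete grid — mutant-pattern pairs always have
me3 > me2 and WT-pattern me3 ≤ me2, with pair weights set so group
medians land on the published 27/18 vs 18/27 and the WT
intermediate:negative split is ≈0.4:0.6. Each patient draws the
opposite group's pattern with `discordant_profile_rate` (default 0.10),
which makes profile concordance an exact Bernoulli quantity for
recovery tests and yields ≈88–90% threshold accuracy at 0. This
symmetric rate is a simplification: in the real cohort discordance was
asymmetric (5/12 mutants ≤ 0 vs 5/70 WT > 0). Replicate cores keep the
drawn intensity and lose staining proportion, so the per-patient max
realizes the drawn score. Survival times are exponential per EZH2
expression group with uniform censoring — enough to exercise the
KM/log-rank code, with no claim of matching published curves. Quality
scores mix Normal(50, 15) for true calls (gray-zone draws get
confirmation labels) and Normal(6, 2) for decoys.

What the generator does *not* emulate: inter-rater noise, tumor purity,
copy-number distortion of VAFs, panel-specific gene mutation
frequencies, non-exponential hazards, or correlated missingness. Tests
passing on these cohorts therefore demonstrate correctness of the
pipeline's computations and recoverability under the assumed structure,
not performance on real tissue.

## Numerical and testing choices

* Every stochastic test is seeded; the simulator is byte-reproducible
  for a given seed (same seed + config → identical output files).
* The kappa LP runs on k ≤ 4 category transportation polytopes and is
  exact to solver tolerance; kappa_max is clamped to [kappa, 1] to
  absorb solver epsilons.
* The exact 2-means uses prefix sums; degenerate all-identical input
  returns a flagged single cluster, which the separation guard maps to
  all-clonal.
* htslib stores VCF QUAL/INFO floats in single precision; the reader
  rounds past the serialized decimals so VCF and TSV loaders produce
  identical records.
* Test problem sizes: the profile-concordance calibration uses one
  2000-patient cohort (≈1000 mutants) rather than hundreds of small
  replicates — the same binomial check at tighter Monte-Carlo error;
  the best-threshold recovery property is checked at n = 20000, because
  discordant WT and concordant mutant patients share the same discrete
  score atoms at a fixed ~1.6:1 mass ratio, so the accuracy margin past
  an atom grows only as √n — at n = 92 a single seed has a material
  chance of shifting the argmax one atom above zero. Clonality recovery
  uses 200 seeded 15-patient cohorts, matching the scale of the
  original comparison.

## Known limitations

* The kappa reference values (0.55, K<sub>max</sub> 0.8) and 3-year
  survival percentages are not recomputable without rater-level and
  patient-level data; the corresponding modules are validated by
  oracles and properties instead.
* The decision algorithm's branch for unexplained discordance is a
  documented design choice; the source strategy does not fully specify
  it.
* COO subtype is consumed as an input label; the expression assay that
  produces it is out of scope, as are base calling, alignment, variant
  calling and annotation themselves.
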