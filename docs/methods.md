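# Methods

## The score model

Each patient record carries five raw bedside measurements (BMI,
retrognathia, ULBT class, TMD, HMD) and the MMC reference class. The
predictors are dichotomised at fixed cutoffs and summed into a 0–5
composite; a total ≥ 1 is a positive prediction. The reference is the
dichotomised MMC (3/4 difficult, 1/2 easy). Boundary conventions, chosen
where the printed rules leave the exact-cutoff case open and applied
consistently everywhere:

- BMI exactly 30 kg/m² scores 0 (the positive condition is strictly "> 30");
- TMD exactly 7 cm scores 0 (strictly "< 7");
- HMD exactly 6 cm scores 1 (grade 2 is the closed range 4–6 cm);
- ULBT classes 1 and 2 both score 0; only class 3 scores 1.

All cutoffs are configurable (`ScoreThresholds`) with these defaults;
the reproduction harness always uses the defaults.

## Cohort reconstruction

The published evaluation releases only margins: per-group score
histograms are implied by the cumulative cutoff sweep (sensitivity and
1−specificity per cutoff, printed at 1 decimal), and each predictor's
positive count per group by its 2×2 table. Every reported statistic is a
function of those margins, so a patient-level cohort matching them
reproduces the entire results section exactly.

**Percentage inversion.** A cumulative percentage p at group size n is
inverted to the count round_half_up(p·n/100). The inversion self-checks:
re-expressing each count as a percentage of n at 1 decimal must
reproduce the printed value, otherwise the function refuses. At n = 82
and n = 118 all ten printed percentages invert uniquely, giving score
histograms (17, 14, 21, 24, 6, 0) for the difficult group and
(84, 11, 19, 3, 1, 0) for the easy group. The easy-group score-4 patient
is kept as printed; no smoothing.

**Feasibility.** Total flags implied by the histogram (Σ s·count[s])
must equal the sum of the predictor margins per group: 152 = 39+17+17+40+39
(difficult) and 62 = 9+11+6+19+17 (easy). `check_flag_consistency`
computes both sides independently.

**Flag assignment.** Finding patient-level 5-bit vectors with prescribed
row sums (the scores) and column sums (the predictor margins) is a 0/1
matrix problem with given margins. The solver uses the Gale–Ryser greedy
construction — satisfy rows in decreasing row-sum order, each taking the
columns with the largest residual demand, index-ordered tie-break — which
is exact: it finds a solution whenever one exists and raises
`InfeasibleAssignmentError` (naming the violated margin) otherwise. The
joint distribution across predictors is genuinely under-determined by
the margins; since no published statistic depends on it, any feasible
assignment is valid, and the seed only permutes exchangeable patients
(equal scores within a group) to pick a canonical one reproducibly.

**Realization.** Continuous measurements are drawn uniformly inside
flag-consistent intervals kept 0.1 units clear of each cutoff (BMI
(30.5, 39.5] vs [19, 29.5]; TMD [5, 6.9] vs [7.1, 9]; HMD [4, 5.9] vs
[6.1, 8]), then rounded to 2 decimals, so re-scoring the emitted records
recovers the flag assignment exactly (round-trip identity, asserted in
tests). MMC sub-classes within the difficult (3/4) and easy (1/2) pairs
are split uniformly; the published report gives no split.

## Diagnostic metrics and intervals

Sensitivity, specificity, PPV, NPV, accuracy and prevalence are the
usual ratios of the 2×2 cells. Confidence intervals use the Wilson score
interval (default 95%), chosen for its small-sample behaviour and
because it never leaves [0,1]; Clopper–Pearson is available as an
option. The interval method for the published CIs is unstated, so no
printed CI is asserted. A metric with an empty denominator is reported
as explicitly undefined, never as 0 or 1. Printed-precision comparisons
round half-up (74.495 → 74.50), matching how the published tables print.

## Agreement statistics

McNemar's test uses the discordant cells b = fp, c = fn. The default is
the *uncorrected* statistic (b−c)²/(b+c), since only it reproduces the
published χ² = 5.67 / p = 0.017 on the composite table (the continuity
corrected value is 5.02); correction is a flag. p comes from the χ²(1)
upper tail. Kappa is computed from observed vs chance agreement; the
closed form 2(tp·tn − fp·fn)/((tp+fp)(fp+tn)+(tp+fn)(fn+tn)) is asserted
against it to 1e−12. The published effect size "g = 0.085" does not
match the classical Cohen's g (max(b,c)/(b+c) − ½ = 0.167 on this
table) but equals |b−c|/n exactly; both variants are implemented,
labelled, and always reported together — neither is silently preferred.
The published abstract and results sections disagree on p (0.006 vs
0.017) and κ (0.522 vs 0.489); the results-section values are adopted as
ground truth because they are mutually consistent with the printed 2×2.

## ROC analysis

The ordinal ROC is built from cutoffs 6 down to 0 so the curve runs
(0,0) → (1,1); its trapezoidal area must equal the brute-force pairwise
concordance (ties ½) to 1e−12, and does, on the study distribution
(0.7894) and on randomised distributions. The published AUC 0.752 equals
(sensitivity+specificity)/2 of the dichotomised classifier — the area of
the single-interior-point ROC — not the full ordinal area. Both are
computed and labelled ("binary, as published" vs "ordinal, full curve");
the discrepancy is surfaced, not hidden. The AUC standard error uses the
Hanley–McNeil formula (the published method is unstated); it gives 0.036
on the study groups, agreeing with the printed value at 2 significant
figures, and is checked only at that precision. The normal CI
auc ± z·se is clipped to [0,1]; it lands within 0.001 of the printed
bounds, which were presumably computed by different software, so the
printed CI is not asserted.

## Synthetic cohorts

`generate` draws reference status Bernoulli(prevalence = 0.41 by
default), maps it to an MMC class, and draws each predictor flag
Bernoulli at that predictor's published sensitivity (difficult) or
1−specificity (easy); continuous fields are realized as in the
reconstruction. The defaults are deliberately the published operating
points, so an argument-free simulation emulates the study conditions.

Conditional independence given reference status is the `dependence = 0`
case. Under it the composite (any-flag) sensitivity is analytically
1 − Π(1−sᵢ) = 0.9115 — well above the observed 0.7927, which shows the
real predictors are positively dependent. The `dependence` weight
d ∈ [0,1) mixes each flag probability toward a patient-level latent
severity u ~ Uniform(0,1): pᵢ′ = (1−d)pᵢ + d·u. This is a bounded,
qualitative stand-in (it also pulls marginals toward ½ as d grows), not
an inferred joint model; it exists so tests can demonstrate the
direction of the dependence effect. What the generator does **not**
emulate: demographics, presenting complaints, missing data,
measurement error in the continuous values, or any realistic
inter-predictor correlation structure — so passing recovery tests
validate the estimation code, not the clinical model.

## Problem sizes and numerical choices

The reconstruction and the full reproduction run on the study-sized
cohort (n = 200) and complete in well under a second. Parameter-recovery
checks use n = 20,000 with a 3-binomial-SE band; Wilson coverage is
checked over 2,000 simulated proportions with true sensitivity drawn
uniformly on (0.2, 0.8) and group sizes 50–200, against the 93–97% band;
AUC equivalence is checked on 500 random score distributions. All
simulations are seeded (`numpy.random.default_rng`), and equal seeds
give byte-identical outputs. Exactness tolerances for algebraic
identities are 1e−12; printed-value comparisons are exact at printed
precision after half-up rounding.

## Known limitations

- The reconstruction recovers the *statistical* cohort, not true patient
  measurements; ages, sexes and complaints are out of scope.
- The flag assignment is one canonical member of a large feasible set;
  analyses depending on the inter-predictor joint distribution (e.g.
  predictor correlations) are not identified by the printed margins and
  should not be read off the reconstructed cohort.
- The published AUC interpretation (binary vs ordinal) cannot be
  confirmed beyond the numerical identity with (sens+spec)/2.
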