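# Methods

## The maturity-score model

A child's dental maturity is summarized by staging the seven left permanent
mandibular teeth (FDI 31–37) on the nine-state scale `0 < A < … < H`
(pre-calcification through apical closure) and summing sex-specific
self-weighted stage scores. A valid score table is non-decreasing in stage
for every (sex, tooth), scores 0 at the pre-calcification state, and its
seven H-stage scores sum to exactly 100 per sex, so the dental maturity
score (DMS) lives on [0, 100] with full maturity at 100. When a left tooth
is missing or unreadable the mirror-image right tooth (41–47) is scored
instead; "unreadable" is treated identically to absent. A tooth with
neither side readable makes the whole record unscorable, and the pipeline
excludes it — the same effect as a quality-based exclusion criterion at
data collection. Substitution is mandible-internal; maxillary teeth are
never consulted.

Chronological age (CA) is the exact day difference DOR − DOB divided by
365.25, rounded half-up to two decimals (half-even available; with the
365.25 divisor exact ties cannot occur, so the choice is cosmetic). Cohorts
are stratified into yearly exclusive class intervals [k, k+1), k = 3…10;
the boundary age belongs to the upper group.

## Age conversion and the prediction model

Two DMS→age routes are implemented. The *conversion table* route
interpolates linearly between monotone (DMS, age) knots — exact at knots;
scores outside the knot span either raise an error or clamp, by policy. The
original percentile curves are smooth, but no functional form is published,
so piecewise-linear is the assumption-light choice. The *prediction model*
route evaluates the logistic growth curve `age = 1/(a + b·c^DMS)`
(`a, b > 0`, `0 < c < 1`), strictly increasing with asymptotes `1/(a+b)`
and `1/a`, with the exact algebraic inverse
`DMS = ln((1/age − a)/b) / ln c`. Coefficients are stored at their
published 3-decimal precision; no hidden digits. Inversion accepts ages up
to 0.005 years (half a 2-dp rounding step) below the DMS = 0 value, because
presentation-rounded ages can land marginally below the curve's floor;
anything else outside the open asymptote interval is an error.

## Calibration

"Logistic regression" here means logistic *curve estimation* with a
continuous age response — not binary-outcome logistic regression, which
this package deliberately does not implement. With the upper asymptote `u`
fixed, `ln(1/CA − 1/u)` is linear in DMS and the fit is plain OLS
(`a = 1/u`, intercept `ln b`, slope `ln c`). The free-asymptote fit is
nonlinear least squares over (a, b, c), initialized from the linearized fit
at `u₀ = 1.05·max(CA)`; an unconstrained Levenberg–Marquardt pass is tried
first and, if it leaves the valid region, a bounded trust-region pass
follows. Both published coefficients `a = 0.083 ≈ 1/12` suggest the
original fit may have fixed a 12-year ceiling, so the pipeline's default
reproduction mode uses `u = 12`; the free mode exists because the procedure
is not documented. Individual children or per-group mean points are both
accepted as input. Fit quality is R² = 1 − SSE/SST on the age scale plus
Spearman's ρ (mid-rank ties); a constant response (SST = 0) is rejected as
degenerate rather than reported as a perfect fit.

## Accuracy assessment

Each (sex, yearly group) stratum compares its EDA column against its CA
column with a pooled-variance Student's independent-samples t-test
(df = n₁+n₂−2, two-sided p) — the conventional default for this reporting
style, applied to paired-by-child columns exactly as the classical tables
do; Welch and paired-t variants are available but not default. p-values are
bucketed as ns (≥0.05), significant (<0.05), highly (<0.01), very highly
(<0.001), most extreme label winning. Degenerate conventions: both SDs zero
with equal means → (t, p) = (0, 1); unequal → (±∞, 0), flagged. Strata with
n = 1 are reported descriptively without a test. Overall bias per sex is
the OLS line of (EDA − CA) on CA plus the mean ± SD (n−1) of the
differences. No multiple-testing correction is applied across strata, by
design, to mirror the classical presentation.

## Reliability

A `round(0.2·n)` (half-up) simple random subsample is re-rated; stage
labels are pooled across the seven teeth (per-tooth agreement is also
emitted since the pooling convention is not standardized). Reported:
percent exact agreement with counts of one-stage-ahead/behind offsets,
unweighted Cohen's κ with the Fleiss large-sample z-test against κ = 0, and
Pearson r between the two passes' DMS values. When both raters are constant
and identical, chance agreement is 1 and κ is undefined; it is reported as
1 with a degenerate flag.

## Sample size

`n = ceil(DEFF·N·p(1−p) / ((d²/Z²)(N−1) + p(1−p)))` — the finite-population
proportion formula with design effect. Ceiling is used because the source
calculators' rounding is unspecified and rounding up is conservative. Z is
supplied directly (default 1.96) rather than derived from α.

## The synthetic cohort generator

The generator emulates the structure of a 160-child cross-sectional study:
default cell counts of 74 boys / 86 girls across the eight yearly groups,
default per-cell EDA−CA biases showing the typical overestimation pattern
(largest in the youngest boys, mild underestimation in the oldest cells),
CA uniform within each yearly interval, and Gaussian year-scale noise
(SD 0.30 y, matching the residual spread implied by per-stratum SDs of
0.3–1.0 y) on the latent dental age before it is inverted to a DMS. Birth
dates sit on a first-of-month grid and the radiograph date is derived from
the drawn CA, avoiding calendar ambiguity. Default missing-left-tooth rate
is 0.05 (exercising contralateral substitution); the both-sides-missing
rate defaults to 0 because the emulated cohort has already passed the
"all seven teeth scorable" inclusion screen. The retest stage-flip rate
defaults to 0.107, reproducing the ~89% retest agreement reported for this
kind of scoring.

Two deliberate design choices:

- **Age map.** The latent dental age is inverted through the packaged
  conversion table (strictly increasing, top knot ≈ 12–12.4 y), not through
  the bundled prediction models. The models' ceilings at DMS = 100 are
  10.2 y (male) and 10.0 y (female), below the oldest study cells, so a
  stage representation capped at DMS 100 could not carry their configured
  biases; real percentile tables extend far above age 11, and the packaged
  table mirrors that. Any invertible map can be supplied instead; a cell
  whose age span falls outside the map's range is a configuration error.
- **Stage realization.** `assign_stages_from_dms` floors each tooth at its
  proportional score share, then packs the leftover mass greedily
  (smallest fitting single-stage step first). This never overshoots and
  provably undershoots by less than the smallest remaining stage step.
  Because even that residual is one-sided, the generator itself applies one
  further nearest-score refinement (promote a stage when it shrinks
  |realized − latent|) so cohort-level biases stay centred on their
  configured values. Stage quantization still adds small lumpy
  perturbations on top of the Gaussian noise — visible as extra spread, not
  as bias.

What the generator does *not* emulate: biological tooth-mineralization
dynamics, within-group non-uniform age distributions (archive cohorts
cluster near referral ages; some real strata have near-integer CAs with
tiny SDs), correlated per-tooth stage errors, and secular or socioeconomic
covariates. Passing end-to-end tests therefore demonstrates that the
analysis machinery recovers known truth under the stated statistical
structure — not that any particular population follows that structure.

## Numerical conventions and limitations

- Sample SDs use the n−1 denominator throughout.
- Score-table validation tolerates 1e-9 on the sum-to-100 invariant;
  conversion knots must be strictly increasing in DMS to be invertible.
- Pipeline randomness derives from one root seed with independent
  per-stage streams (generation, subsample selection, retest jitter), so
  reports are byte-identical across runs at a fixed seed.
- Default problem sizes (160-child cohorts, 20-seed recovery averages)
  keep every analysis comfortably desk-scale while matching the emulated
  study's dimensions.
- The per-stratum t-test treats the CA and EDA columns as independent
  samples although they are paired by child; this mirrors the classical
  tables (a paired option exists). Interpret stratum p-values accordingly.
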