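# Methods

## Model

RMRS quantifies metabolic-syndrome severity as agreement between a
subject's measurements and the diagnostic thresholds, computed on
radar-chart geometry rather than on sample statistics.

**Scaling.** Each factor is normalized so its AHA/NHLBI cutpoint maps to
0 and 10 % of the cutpoint is one unit; the HDL axis is sign-flipped
(low HDL is the risk); blood pressure takes the larger of the systolic
and diastolic threshold exceedances, with one unit defined as 10 % of
the 45 mmHg gap between the two cutpoints (4.5 mmHg). The Elliot sigmoid
S = 0.5·Z/(1+|Z|) + 0.5 maps the normalized deviation into (0, 1) with
the threshold at 0.5 and one unit below/above at exactly 0.25/0.75. The
sigmoid is bounded, so outliers saturate instead of dominating, and it
is steepest near the threshold, where clinical sensitivity matters most.
Scaled vectors admit exact 0 and 1 as limit inputs for analytic
configurations even though the sigmoid's range is open.

**TAS.** On a three-axis radar chart (axes 120° apart) the triangle
through radii (x₁, x₂, x₃) has area ½ sin(π/3)(x₁x₂ + x₂x₃ + x₃x₁).
Because every TAS term is a ratio of such areas, the common geometric
factor cancels and the score works in pairwise-product-sum units:
the threshold triangle has mass C_α = 0.75 and the severity capacity is
C_β = 3 C_α = 2.25. With X the product-sum of the raw scaled values and
X′ of the values clipped at 0.5,

- closeness = X / (C_α + X − X′) ∈ [0, 1]: proximity of the internal
  (clipped) triangle to the threshold triangle, discounted by the excess
  mass X − X′;
- severity = I · (X − X′)/C_β ∈ [0, 1]: the excess mass relative to its
  maximum, active only when the triad is "diagnosed" (indicator I = 1
  iff all three axes ≥ 0.5);
- TAS = (closeness + severity)/2.

The published expanded formula omits the overall ½ that the prose
definition ("average of closeness and severity") requires; this package
applies the ½, which is the only reading that reproduces the published
anchor values 0.387/0.707/0.547 and every theoretical range endpoint.
The same convention is applied to the interaction reformulation so the
two routes agree identically.

**Indicator convention.** I is evaluated as "all three scaled values
≥ 0.5" rather than as a floating-point equality test on X′ = 0.75; the
two are equivalent in exact arithmetic.

**RMRS.** The square root of the mean TAS over all 10 triads. The square
root spreads the lower range; each supra-threshold factor appears in 6
of the 10 triads (and each pair in 3), which is how the score weights
factors beyond threshold without sample-derived loadings.

**Fixed cutoff.** The minimum score carrying a count-based diagnosis is
RMRS(0.5, 0.5, 0.5, 0, 0) = √0.15 ≈ 0.387; the supremum score without
one is the ε→0 limit of RMRS(1, 1, 0.5−ε, 0.5−ε, 0.5−ε) = √0.5 ≈ 0.707.
The diagnostic cutoff is their midpoint, 0.547. Limits are evaluated at
ε = 1e−9; printed comparisons use 3 decimal places with half-away-from-
zero rounding (no reported value is sensitive to the half rule). A
figure caption in the source literature prints the cutoff as 0.574; the
derivation yields 0.547 and that value is used.

The theoretical RMRS range per risk-factor count k follows from the same
boundary configurations: √0.05–√0.5 for k = 2, √0.15–√0.55 for k = 3,
√0.3–√0.7 for k = 4, √0.5–1 for k = 5 (0–√0.5 for k = 0, 1).

## Diagnostic counting

The count-based diagnosis operates in raw measurement space with the
tabulated inequality directions: GL ≥ 100 mg/dl, SBP ≥ 130 or DBP ≥ 85
mmHg, TG ≥ 150 mg/dl, HDL strictly below 40 (male) / 50 (female) mg/dl,
WC ≥ 102/88 cm (American male/female) or 90/85 cm (Korean). HDL exactly
at its cutoff is therefore *normal* even though its scaled axis sits at
0.5; a record with all five factors exactly at threshold counts 4, not
5. When only a scaled vector is available (no raw record), the count
falls back to the number of axes ≥ 0.5.

Count and score can disagree at the boundaries by construction: three
factors exactly at threshold give RMRS 0.387 < 0.547 (positive by count,
negative by score), and conversely several strongly elevated factors
under a count of two can exceed the cutoff. This is the intended
behaviour of a continuous severity score, not an error.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| factor cutpoints | AHA/NHLBI values above | overridable per factor via config |
| unit size | 10 % of the cutpoint | clinical convention; not individually tuned |
| diagnostic cutoff | 0.547 | structural midpoint; overridable |
| ε (limit evaluation) | 1e−9 | small enough that 3-d.p. values are converged |

## Synthetic cohorts

No real cohort ships with the package. `rmrs.simulate` draws subjects
from a Gaussian copula with per-sex marginal means and SDs taken from
published Korean and American cohort summaries. Triglycerides use a
moment-matched lognormal marginal (their SD approaches their mean, so a
Gaussian would put substantial mass below zero); the other five
measurements are Gaussian. The default latent correlation matrix (mild
positive co-occurrence among GL/WC/TG/BP, negative HDL loadings, strong
SBP–DBP coupling) is a stated modelling assumption — the source
summaries report no inter-factor correlations. Measurements are clipped
to fixed clinically plausible bounds (e.g. WC 40–200 cm, HDL < 200
mg/dl) to keep normalized deviations finite, and rows violating
SBP > DBP are resampled.

What this emulates: realistic marginal locations and spreads, right-
skewed triglycerides, plausible co-occurrence, and hence a realistic
spectrum of risk-factor counts. What it does not: true joint
distributions, age/race structure, measurement error, or real MetS
prevalences. Passing tests on synthetic cohorts therefore demonstrate
the score's structural behaviour (monotone count–score relationship,
range containment, discrimination of the count diagnosis), not clinical
performance on any real population. Empirical cohort statistics from the
source literature are correspondingly out of scope.

A second generator draws scaled five-vectors with an exact number k of
components at or above 0.5 (uniform on [0.5, 1] and [0, 0.5)
respectively, positions shuffled), used to probe per-count ranges.

## Evaluation conventions

- Score-positive iff score ≥ threshold, uniformly.
- AUC is the rank-based (Mann–Whitney) statistic with tied pairs
  counting ½; tests cross-check it against brute-force pairwise counting.
- Youden's J is maximized over midpoints of adjacent distinct scores
  plus sentinels beyond the extremes; ties break toward the lower
  cutoff.
- Adjusted R² comes from the single-predictor linear fit of score on
  count.
- Subgroups with a single diagnostic class or fewer than `min_n`
  subjects are reported as undefined rather than raising.

## Problem sizes

Property tests run on a few thousand random vectors per invariant; the
range-containment check uses 10,000 draws per risk-factor count; the
interaction-equivalence oracle uses 10,000 random triples at 1e−12
tolerance. The full suite completes in well under a minute on one CPU.

## Known limitations

- The 10 % unit size and equal per-factor weighting are conventions
  inherited from the score's definition, not clinically validated here.
- The copula correlation matrix is assumed, not estimated; evaluation
  numbers on synthetic cohorts shift with it (the structural anchor
  values do not).
- Scores are reported at full precision; 3-d.p. rounding is a
  presentation option, so downstream comparisons at other precisions are
  the caller's responsibility.
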