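# Methods and numerical conventions

This note documents the model conventions, discretizations and design
choices behind the package, in the spirit of a statistical package's model
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Lexis geometry

Ages and years are integers labelling the intervals [x, x+1) and [t, t+1).
A cohort born in year c is assigned the hazard m(a, c+a) for the whole of
age a — one Lexis cell per age, with no triangle splitting, because
single-year rate matrices do not resolve triangles. Missing cells are a hard
error, never imputed: a silent gap in one cohort's history would contaminate
every later cross-sectional measure.

## Life-table construction

* **Within-interval hazard**: piecewise constant, ℓ(x+s) = ℓ(x)·e^(−m(x)s)
  for 0 ≤ s ≤ 1. One convention is applied uniformly instead of the aₓ = 0.5
  device; on smooth schedules the difference is far below the tolerances the
  package tests at. A consequence worth knowing: feeding point values of a
  continuous hazard at integer ages biases cumulative hazards (for a
  Gompertz schedule with slope b ≈ 0.1, e₀ is off by ~10⁻² years). The
  unbiased discretization of a continuous schedule is its interval-average
  hazard, which the oracle tests use; observed rates (HMD-style m(x)) *are*
  interval averages, so no correction applies to real inputs.
* **Integration**: trapezoidal rule on the (optionally step-refined) age
  grid, for both e₀ = ∫ℓ and e† = −∫ℓ·lnℓ, with 0·ln0 ≡ 0 and 1·ln1 ≡ 0
  (the analytic limits; implemented via `scipy.special.xlogy`). The trapezoid
  is exact for piecewise-linear ℓ and converges quadratically on the
  piecewise-exponential curves built here. The default step is 1 year
  (HMD-like); analytic-limit checks use 0.1 years.
* **Terminal closure**: beyond the last supplied age, the terminal hazard is
  extended until ℓ < 10⁻¹², capped at 150 years past the last age; remaining
  mass is dropped. A zero terminal hazard disables extension. The entropy of
  a curve is flagged with a warning when outside [0, 1] (possible under
  extreme infant mortality), never clamped.

## CAL measures

CAL(t) is assembled age by age from distinct cohorts: the node at integer
age x is exp(−Σ_{a<x} m(a, t−x+a)), the exact survival of the cohort aged x
at time t, sampled at exact integer ages (whether mid-year exposure ages were
intended in the source literature is unstated; integer ages are used and
documented). The spliced curve is *not* a single cohort's survival and need
not be monotone; it is validated only for v(0)=1, v∈[0,1].

With a refinement step below 1 year, the curve inside [x, x+1) decays with
m(x, t) — the hazard the cohort occupying that segment experiences during
year t. Integer-age nodes always come from the exact cohort formula, so the
refined curve can be discontinuous at integer ages on non-stationary
surfaces (the jumps are first-order in the annual rate change). Under a
time-invariant surface this construction reproduces the refined period curve
exactly, which is the package's central consistency oracle: (CAL, CAL†,
H_CAL) = (e₀, e†, H) to 10⁻⁶ on stationary surfaces.

ω defaults to 110 (the usual open-age boundary of single-year national data),
configurable. The tail beyond ω is closed by extending m(min(ω, top age), t),
the oldest cohort's current hazard, under the life-table closure rule.

## Gap decomposition

The continuous theory differentiates H_CAL along a population index; the
package realizes the relative derivatives Ẋ/X as log-ratios between the
population and the benchmark. Writing R† = ln(CAL†_p/CAL†_b),
R = ln(CAL_p/CAL_b) and D = R† − R, the entropy scale is the logarithmic
mean H̃ = (H_p − H_b)/D, so that

  contrib_variation = H̃·R†,  contrib_longevity = −H̃·R

sum to the gap H_p − H_b *exactly*, for any benchmark — including the
default mean-of-entropy benchmark, whose H is the arithmetic mean of member
entropies and therefore not CAL†_b/CAL_b. (Defining H̃ through D rather than
ln(H_p/H_b) is what preserves exact additivity in that case; the two
definitions coincide for ratio-consistent benchmarks.) When |D| < 10⁻¹² the
arithmetic mean of the two entropies is used instead and additivity is
enforced through the longevity term; this branch is exercised by the
canonical same-entropy pair (CAL†, CAL) = (10, 50) vs (15, 75), where the
gap is zero and the decomposition returns ±0.2·ln(2/3) ≈ ∓0.0811.

## Change-of-gap decomposition

The gap equals H̃·D, and the discrete product rule
Δ(ab) = Δa·b̄ + ā·Δb — an *identity* when the non-differenced factors are
two-year midpoint averages — splits the year-over-year change into

  term_benchmark = ΔH̃·D̄,  term_variation = H̃̄·ΔR†,  term_longevity = −H̃̄·ΔR.

Because the identity is exact, the reported residual is numerical roundoff
(≲10⁻¹⁶), not a second-order discretization error; it is still computed and
reported rather than folded into a term. The benchmark term tracks the
change in the pooled entropy level, matching its interpretation as the
contribution of benchmark-average entropy improvement.

Component shares are |cᵢ|/Σ|cⱼ| per year (two components for gaps, three
terms for changes), then a centered rolling mean of odd width — default 5
years, shrinking at the edges — chosen as a conventional smoothing width for
annual demographic series. Years where every component is zero have
undefined shares and are excluded from the rolling mean. Crossover detection
reports years where the gap's sign flips; zero gaps attach to the following
sign.

## Benchmarks

Default: the unweighted arithmetic mean of member populations' H_CAL (CAL
and CAL† means are carried for the log-ratios). Sensitivity mode: average
the rate surfaces cell-wise and compute the CAL measures of the averaged
surface (`benchmark_from_surfaces`; it needs the surfaces, not just the
per-population results).

## Trend summaries

* `fit_linear`: OLS, ≥3 points.
* `fit_piecewise`: continuous hinge model y = b₀ + b₁t + b₂·max(t−τ, 0),
  τ searched exhaustively over interior observation years with ≥3 points per
  segment (≥7 points total), ties to the earliest year. Continuity at the
  breakpoint is a deliberate choice — a single turning point is the object
  of interest — and because the hinge nests the plain line, the piecewise
  SSE never exceeds the linear SSE.
* `intrinsic_rate`: ln(v(t₂)/v(t₁))/(t₂−t₁), exact for exponential
  trajectories and invariant to rescaling the series; percent-per-year paces
  are these rates ×100.

## Synthetic surfaces

`build_surface` generates m(x,t) = (a·e^{bx} + c)·e^{−ρ(t−t₀)}·cohort(t−x)·
shock(t)·noise(x,t). Defaults (a = 3×10⁻⁵, b = 0.095, c = 2×10⁻⁴, ρ = 0.012,
ages 0–110, years 1870–2020, seed 20240725) describe a stylized
20th-century low-mortality population and are the fixed test scenario, so
derived expectations are reproducible verbatim. Noise is mean-one lognormal
(chosen for positivity; observed rates carry no canonical noise model, so
this is the package's own choice). Identical spec and seed give bit-identical
surfaces.

What the generator does **not** emulate: the infant/child mortality hump and
its historical decline (the main driver of real-world entropy declines — the
worked example's near-flat H_CAL under purely proportional improvement is a
direct consequence), accident humps, heterogeneity/frailty, and small-
population stochasticity. Passing tests therefore validate the measures'
algebra, limits and internal consistency, not any claim about a specific
country's inequality trends.

`divergence_pair` constructs controlled attribution fixtures. In
variation-only mode, population B receives a growing age-pivoted log-linear
hazard tilt (pivot 70 years) and each calendar column is calibrated by a
scalar (Brent root-finding, sequential in time, one knob per covered year)
so CAL_B tracks CAL_A to ~10⁻⁶ years while CAL† diverges; in longevity-only
mode B's log-hazard schedule is shifted along the age axis — a pure location
shift of the death distribution, which moves CAL while preserving CAL† —
and the preservation is verified against a 0.05-year tolerance, raising a
construction error if missed. The default tilt strength targets a final
relative divergence of a few percent in the moving component: large enough
to dominate the gap-change decomposition, small enough that the
second-order benchmark-entropy term (≈ half the log-divergence, relatively)
stays marginal.

## Problem sizes and runtime

Tests run on surfaces of at most 111 ages × 221 years; the full suite
completes in seconds and the acceptance script (largest case: 301 ages ×
302 years at step 0.1) in well under a minute.

## Known limitations

* The open age class is closed by hazard extension, not by old-age
  smoothing; inputs are taken as given (rate smoothing is an input-
  preparation concern).
* CAL needs ω+1 years of history before its first computable year; no
  truncated-CAL variant is provided for short series.
* H_CAL values outside [0,1] are flagged, not corrected.
* The piecewise fit reports no uncertainty for the breakpoint and fits at
  most two segments.
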