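# Methods

This note documents the statistical model behind `chromodr`, the choices
made where the design was genuinely open, and what the tests do and do not
demonstrate.

## Design and coding

The experimental plan is a face-centered central composite design in three
continuous factors: 8 factorial corners (±1, ±1, ±1), 6 axial points on the
cube faces (±1 on one axis, 0 elsewhere) and replicated center points
(default 4, giving 18 runs). Natural units map linearly to coded units,
`x = (v − mid) / half-range`, so the coded design is orthogonal in its
linear columns. The builder emits a fixed canonical run order (factorial
block with flow varying fastest, then the axial pairs per factor, then the
centers) so that runs compare bit-for-bit across sessions; a seeded shuffle
is available when a randomized execution order is wanted. Coded levels are
stored next to the natural values rather than recomputed, which keeps
serialization round-trips exact.

## Response models

Each response is modeled on a transformed scale as a reduced quadratic in
the coded factors, fitted by OLS (statsmodels). The transform is part of
the model: `identity`, `reciprocal` (1/y) or `log10`; prediction
back-transforms to the measurement scale. Transforms stabilize variance and
linearize retention behavior — reciprocal time is a natural scale for
boundary times of early-eluting peaks (roughly proportional to flow), and
log-retention is close to linear in mobile-phase composition for the later
peaks.

Reproduction of the study's coefficient table uses the *fixed* term sets
read from that table, not automatic selection, because the exact selection
rule used there is not stated. Two convenience tools are provided:

* `suggest_transform` profiles the Box-Cox log-likelihood of the regression
  over λ ∈ [−2, 2] (with the Jacobian term) and maps the 95 % confidence
  region to a named transform: reciprocal if it covers −1 but not 0 or 1,
  log10 if it covers 0 but not 1, identity otherwise. Ties resolve toward
  identity, so weakly-informative data keep the raw scale. On the bundled
  data this picks identity for the first boundary time (the confidence
  region is wide because the residual noise is tiny relative to a narrow
  response range and several transforms fit almost equally well); the fixed
  published structures are used for reproduction regardless.
* `backward_eliminate` drops, one at a time, the non-intercept term with the
  largest p-value above α (default 0.05), never removing a linear term while
  a surviving interaction or quadratic contains it. On the bundled
  retention-factor data it recovers exactly the published reduced set
  {x₁, x₂, x₃, x₂x₃, x₂²}.

### Diagnostics

R² = 1 − SSres/SStot; adjusted R² penalizes by degrees of freedom; predicted
R² uses PRESS = Σ(eᵢ/(1−hᵢᵢ))² with hᵢᵢ the leverage (exact leave-one-out).
The lack-of-fit F-test splits residual variance into pure error (from runs
with identical coded settings — here the 4 center replicates) and model
inadequacy. With no replicates the p-value is reported as undefined
(`None`), never silently 1. For a saturated interpolating fit (n = p) the
coefficient uncertainty is zero by construction and PRESS/predicted R² are
NaN (leave-one-out is undefined at an interpolated run).

Refitting the five published structures to the bundled 18-run table
reproduces **all 34 printed coefficients at their printed precision**. The
four boundary-time models also reproduce all printed diagnostics to 4
decimals. The retention-factor model's diagnostics differ in the fourth
decimal (R² 0.9901 vs 0.9902, adjusted 0.9860 vs 0.9861, predicted 0.9803
vs 0.9805, lack-of-fit p 0.9704 vs 0.9718): the bundled responses are
printed to 2 decimals whereas the original fits used unrounded instrument
data, and the retention factors (≈ 14–20) lose the most relative precision
to that rounding. Tests therefore assert these four values within ±0.002.

## Critical method attributes

Separation is measured by S = t₂,start − t₁,end for each critical peak
pair; S > 0 means baseline resolution and negative values (overlap) are
legitimate outcomes, not errors. S is modeled indirectly — four boundary
times get their own response models and S is formed from predictions —
because directly-modeled S surfaces have poor predictive quality when the
time differences are small. The retention factor of the last peak is
modeled directly; no dead time is needed. The gradient-composition
arithmetic φe = φi + (φf − φi)/t_grad · (t_r − t_D) is exact for a linear
gradient with dwell time t_D and raises outside the gradient window rather
than clamping. Dwell time is treated as a constant of the reference flow
condition; a helper rescales it as 1/flow when needed.

## Monte Carlo design space

The factor space is discretized on inclusive colon-range grids (flow
[0.5:0.01:0.7], gradient time [8:0.35:15], temperature [30:1:40]; 4851
points). Each Monte Carlo iteration draws **one perturbed coefficient
vector per response model** and evaluates all criteria at every grid point;
a point passes the iteration iff all rules hold jointly in that perturbed
world. The probability map is the pass fraction over iterations (default
5000), and the MODR is its ≥ 0.90 superlevel set.

**Perturbation default.** Coefficients are drawn from the multivariate
normal with the full OLS coefficient covariance. This is the exact sampling
distribution of the estimates under the model; for the orthogonal term sets
here it reduces to independent per-coefficient Normal(b, SE) draws, which
remain available as `perturbation="independent"`. The distinction matters
for the two 9-term log models, where the intercept and the quadratic terms
are negatively correlated: treating them as independent overstates the
spread of predicted boundary times and, through the S₆₋₇ difference,
deflates the pass probability at the working point from 0.92 to ≈ 0.88 —
below the threshold that the study reports the point as satisfying. The
covariance draw is therefore both the statistically correct propagation and
the one that reproduces the published conclusion.

Draws are made with a single seeded generator in a fixed order (model by
model), so identical settings give bit-identical maps regardless of
evaluation chunking. Zero-uncertainty models degenerate to exact 0/1
probabilities.

**Zones and working point.** MODR cells whose six face-neighbors are all in
the region are *interior*; the rest are *edge* (array-boundary cells are
conservatively edge). The automatic working-point suggestion takes the cell
maximizing the city-block distance to the nearest out-of-region cell, with
ties broken by higher probability, then lower flow (solvent economy), then
lexicographic order for determinism. On the bundled data this lands at
(0.56 mL/min, 12.9 min, 32 °C) — deeper in the region than the study's own
choice (0.575, 14.2, 33), which sits two cells inside the boundary and was
evidently picked by eye; both are operable, and the published point's
probability and region membership are what the acceptance checks assert.

The probability map is smooth along the finely-discretized flow axis
(adjacent cells differ by < 0.25). Along temperature, one 1 °C step moves
the predicted retention factor by ≈ 0.27 while its prediction sd is ≈ 0.1,
so the k < 18.8 rule genuinely switches within a single step — a steep
criterion boundary, not Monte Carlo noise.

## Synthetic data

The generator draws each response from a known polynomial truth on its
transformed scale plus homoscedastic Gaussian noise **on that same scale**
(where the linear model holds, consistent with the Box-Cox rationale), then
back-transforms. Alternatively, peak-apex surfaces with a half-width emit
boundary columns (end = apex + half-width, start = apex − half-width). An
option rounds the emitted table to 2 decimals to mimic printed-data
precision. Truth surfaces must be positive over the coded cube (checked at
construction); generated non-positive values name the offending run.

`make_published_truth` uses the published coefficient table as ground truth
with noise matched to the residual sd of each refit (≈ 0.001 on the
reciprocal scale, ≈ 0.0013 in log₁₀, ≈ 0.175 on k): the conditions the
real data exhibit.

What passing synthetic tests show — and what they do not: noise-free
generation and refit recover coefficients to 1e−9, estimates are unbiased
over seeds, and the matched-noise pipeline selects working points that are
operable under the true surfaces. They do not show robustness to
misspecified surfaces, heteroscedastic or non-Gaussian measurement error,
drifts between runs, or peak-integration artefacts in real chromatograms.
A caution from the matched-noise experiments: the published working point's
true pass probability (0.92) is so close to the 0.90 threshold that
refitting on re-measured data of the same quality frequently moves that
single point below threshold — the MODR's *edges* are genuinely uncertain
at this data precision, which is exactly why a deeper interior point is the
safer choice.

## Problem sizes and runtime

Default sizes follow the study: 18 runs, 4851 grid points, 5000 Monte Carlo
iterations (full pipeline ≈ 1.5 s). Tests use reduced iteration counts
(200–1000) for map-level checks and 50 000 draws for single-point
closed-form comparisons, chosen so that binomial error bounds are sharp.

## Known limitations

* Only 3-factor face-centered CCDs are constructed (no rotatable or
  Box-Behnken designs, no >3 factors).
* OLS only — no weighted or robust fits; transforms are limited to the three
  named ones.
* The design space is evaluated on the grid; no continuous optimization
  between grid points.
* Coefficient uncertainty is propagated, residual/measurement noise is not
  added on top: the probability is about the *mean* response surfaces.
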