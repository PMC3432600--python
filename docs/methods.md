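# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `selsurf`.

## Trait index

Each pond collection is analyzed separately. The allometric size
correction regresses ln OH on ln SVL by OLS within the pond and keeps the
residuals; this removes the strong positive scaling of jaw-muscle width
with body length so that the index measures shape, not size. The index is
the first principal component of (MP, residual ln OH, DR) computed from the
**correlation** matrix (the three variables are on incommensurate scales),
with the ordinal MP score treated as numeric. Scores are divided by their
sample SD (ddof = 1) rather than scaled by the eigenvalue, so SD(scores) = 1
exactly. PCA sign indeterminacy is resolved by forcing the MP loading
positive on every component; on PC1 this makes larger scores more
carnivore-like, and with strongly inter-correlated inputs the DR loading
then comes out negative (carnivores have fewer denticle rows). If any DR
value is missing in a pond, DR is dropped for that whole pond and the
two-variable (MP, residual OH) index is used. A zero-variance input is an
error naming the offending variable, not a silent drop.

## Selection differentials

Relative fitness is w = ln SVL / mean ln SVL, so mean(w) = 1 by
construction; body size at a fixed time after breeding is the fitness
proxy. Two separate OLS regressions are fitted: β is the slope of the
linear-only model (n − 2 df), and γ is **twice** the z² coefficient of the
model containing both terms (n − 3 df), with its SE doubled as well — the
doubling makes the coefficient estimate the curvature of the individual
fitness surface, and cancels in the t ratio. β is deliberately *not* the
linear term of the quadratic model. Significance is two-tailed at α = 0.05
with no multiple-testing correction across collections (each pond is a
separate inference).

## Fitness surfaces and the interior-extremum decision

The nonparametric surface is a penalized cubic smoothing spline minimizing
Σ(w − f(z))² + λ∫f″², fitted with `scipy.interpolate.make_smoothing_spline`
after collapsing tied trait values to their count-weighted mean. λ is
selected by generalized cross-validation over 41 log-spaced values spanning
1e−4…1e4 × a data-scaled reference (range(z)³/100); the GCV denominator
uses the exact smoother trace obtained by pushing the identity matrix
through the same banded solve. The selected λ is reported and reused for
the bootstrap: 95% pointwise bands are percentile intervals over resamples
of individuals (default 200 replicates, seeded), widened where necessary so
they always bracket the point fit. "Visual inspection" of the surface is
operationalized deterministically: an interior minimum (maximum) is flagged
when the grid argmin (argmax) on a 100-point grid lies farther than 1% of
the trait range from both endpoints.

The Mitchell–Olds & Shaw test compares the free quadratic regression
(RSS_f) against the model whose stationary point −b/(2c) is constrained to
an observed trait boundary: substituting b = −2c·z_bound yields
w = a + c(z² − 2 z_bound z), fitted by OLS (RSS_c). For each boundary,
F = (RSS_c − RSS_f)/(RSS_f/(n − 3)) on (1, n − 3) df; rejecting both
boundaries jointly indicates an interior extremum. With |c| < 1e−12 the
extremum is undefined and the flag is false (F statistics still reported).
Where the spline flag and this parametric test disagree, classification
follows the spline: the constrained F test inherits the parametric model's
assumptions, the spline does not.

Mode classification: "disruptive" requires p_γ < α, γ > 0 and an interior
minimum; "stabilizing" requires p_γ < α, γ < 0 and an interior maximum;
anything else is "none". A directional flag (sign of a significant β) is
reported orthogonally. When no surface is available — notably when
reanalyzing published per-collection statistics without raw individuals —
counting falls back to sign-and-significance of γ alone and is labeled as
such.

## Competition measures

Vegetative cover (a detritus proxy) is binned at ≤ 0.33 / ≤ 0.66 / above
into categories 1–3; boundary values fall in the lower category (no
observed survey value sits on a boundary, so the convention is
documentation, not inference). Per-capita resource abundance is
(shrimp category + detritus category) / tadpole-density category, ranging
2/3 to 6; it decreases in density and increases in either resource, which
the tests assert.

## Cross-population regression and bootstrap

γ is regressed on each competition measure by weighted least squares. The
default weight is √n per collection; an n-weighted variant is exposed as a
sensitivity switch. On the packaged survey tables (γ printed to three
decimals) the √n weighting gives F(1,20) = 8.512 (per-capita resource) and
8.124 (density), while the n weighting gives 9.734 and 9.631 — within ~5%
of the published 9.861 and 10.088. The residual gap is consistent with
rounding of the published γ to three decimals; both variants agree on the
direction and significance of both associations, which is the substantive
conclusion.

The pond-level bootstrap draws one collection uniformly from each unique
physical pond per replicate, refits the weighted regression with the drawn
collections' own weights, and summarizes 1000 replicate slopes by the
median and percentile 2.5/97.5 interval (BCa offers no advantage at 15
ponds and is harder to reproduce). The packaged collection→pond mapping is
*inferred* from the pond naming convention (state prefix + trailing pond
number); it reproduces the published structure exactly — 15 unique ponds,
6 sampled in multiple years, 22 collections — but the original assignment
is not published, so bootstrap medians/CIs computed under it are reported
informationally and never asserted against the published values.

## Synthetic-data model

The generator emulates the study conditions, not any particular pond. Per
tadpole, a latent morph z* is drawn from a symmetric two-component normal
mixture with component means ±b/2 (unit component SD) and standardized by
√(1 + b²/4), so SD(z*) = 1 exactly for any separation b ≥ 0. The default
b = 3 gives clearly bimodal morphology (KDE finds two modes in ≥ 95% of
n = 500 samples). Observables: MP is z* cut at the mixture's
equal-probability quintiles (all five levels stay populated); DR =
round(6 − 2z*) floored at 0; ln SVL = 3.22 + β_true z* + (γ_true/2) z*² +
N(0, 0.15) (≈ 25 mm mean size, ~15% size CV); ln OH = −1.6 + 0.8 ln SVL +
0.12 z* + N(0, 0.05). Pond i uses RNG seed `seed + i`; the ecology table
uses `seed + 100003`, keeping streams disjoint. Pond ecology is linked to
the pond's true quadratic effect through a rank-based latent with link
strength L ∈ [0, 1]: density rises, and shrimp/cover fall, with γ_true.

What the generator does **not** emulate: measurement error in the
morphometrics beyond residual noise, within-pond spatial structure,
development-stage covariates, non-quadratic fitness surfaces, and
frequency-dependence (γ_true is fixed, not emergent). Passing tests
therefore validate the estimators and the pipeline wiring, not the
biological claims on real ponds.

## Problem sizes and defaults

Monte-Carlo checks use 200 single-pond surveys of n = 200 for γ-recovery,
1000 null samples of n = 100 for calibration of both the quadratic t test
and the constrained-regression test, and 200 (tests) / 100 (acceptance
script) twenty-pond surveys for cross-population sign recovery; these sizes
put binomial error well below the asserted margins while keeping a desk-run
fast. Spline bootstrap default is 200 replicates. All defaults are plain
function arguments and can be raised freely.

## Known limitations

- The ordinal MP score is treated as numeric in the PCA, as in the original
  analysis; a polychoric treatment might differ for coarse scales.
- GCV can undersmooth small ponds with heavy ties; the λ grid bounds the
  damage but extremum flags near the 1% margin deserve a look at the curve.
- The published F statistics are reproduced only to within rounding of the
  published inputs (see above); exact agreement would require the authors'
  unrounded differentials.
- The collection→pond mapping is inferred; any cross-population quantity
  that depends on it (bootstrap only — the full-sample regressions do not)
  carries that caveat.
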