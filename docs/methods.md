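# Methods

## Task geometry and notation

A reach starts at a table edge, passes a fronto-parallel *obstacle
plane* halfway to an upright screen, and ends on the *target plane* (the
screen). Only horizontal coordinates matter: target and obstacle are
elongated vertically. Coordinates are stored relative to the structures
that define payoffs — the excursion x₁ relative to the obstacle's left
edge (negative = left of, i.e. clear of, the obstacle) and the endpoint
x₂ relative to target center — so conditions are directly comparable.
Screen-absolute positions appear only in the condition table. The nine
conditions cross target centers {0, 38, 75} mm with obstacle costs
{−1, −2, −5} points; the obstacle edge is always 6.6 mm right of the
target center, the target strip is 6.5 mm wide, and a target hit earns
+2 points. Four outcomes are possible on a trial because the regions
overlap: hit both, hit target only, hit obstacle only, miss both. An
obstacle hit requires strictly x₁ > 0 and a target hit |x₂| ≤ w/2
(boundary inclusive); the boundary convention has measure zero under the
model and matters only when classifying discrete samples.

The reward region is assumed to coincide with the 6.5 mm visual strip;
`target_width_mm` is configurable should that identification need
revisiting.

## Expected gain and hit probabilities

A strategy s fixes the mean (x̄₁, x̄₂) of a bivariate Gaussian over
(x₁, x₂) with standard deviations σ₁, σ₂ and correlation ρ. Expected
gain is V_T·P(target) + V_O·P(obstacle). Both probabilities are
one-dimensional Gaussian integrals: P(obstacle) = Φ(μ₁/σ₁) and
P(target) = Φ((w/2 − μ₂)/σ₂) − Φ((−w/2 − μ₂)/σ₂). Because the gain is
additive in the two hit indicators it is exactly invariant to ρ, which
is therefore fixed at 0 in all optimization (the empirical cross-plane
correlation is small). Joint outcome probabilities — needed for outcome
bookkeeping, not for gain — factor into products of marginals at ρ = 0
and are otherwise computed by `scipy.stats.multivariate_normal`
rectangle integration; the four joint probabilities are required to sum
to 1 within 10⁻⁹ and tiny negative quadrature residues are clipped.

## The noise model: six sigma lines

Crossing variability grows with detour size. Per obstacle location
(1–3) and plane (obstacle, target), the sample SD of pooled crossings is
regressed on the signed mean excursion across the three cost levels:
σ = a + b·ē₁, with b typically negative (leftward = negative
excursions). Fits use weighted least squares (statsmodels WLS) with
weights 1/SE(σ̂)², where SE(σ̂) = s/√(2(n−1)) is the delta-method
standard error of a Gaussian sample SD; the weighting scheme is a
package choice, as is the decision to fit the three cost levels of the
pooled summaries rather than per-subject points. No cross-location
pooling into a single two-variable model is attempted — locations are
allowed to differ freely. Predictions at excursions where a fitted line
implies σ ≤ 0.05 mm raise a domain error rather than extrapolate;
optimizer search ranges are intersected with the σ-positive interval.

## MEG optimization

For each condition the theoretical excursion e′ ∈ [−40, 0] mm (clipped
to the σ-positive range) induces a crossing distribution with mean
(e′, μ₂) and SDs from the fitted lines; μ₂ is fixed at the condition's
observed mean endpoint error rather than optimized — the planner is
assumed to aim at the target center with its empirical bias. The
maximizer e* is located by a 0.5 mm grid scan refined with bounded
scalar minimization (xatol 10⁻⁴), with the guarantee that refinement
never returns a worse point than the scan. Flat maxima resolve toward
the smallest |e*| (minimal-deviation convention). The −40 mm search
floor is configurable via `GridSpec`.

## Dominance Test

The empirical menu of strategies a subject demonstrably possesses is the
set of observed per-condition mean excursions. G[i][j] is the expected
gain in condition i (its costs, its σ lines, its endpoint bias) of the
obstacle-relative excursion observed in condition j; strategies transfer
as obstacle-relative coordinates because payoffs are defined relative to
the obstacle edge and target center. Condition i is *dominated* —
provably not gain-maximizing — if some off-diagonal entry beats the
diagonal by more than ε (default 10⁻⁶ points; the margin threshold and
the trial-resampling bootstrap that accompanies the point-estimate flags
are additions of this package, since no threshold is stated for the
original procedure). Entries whose excursion leaves the σ-positive range
of the applied-in condition are marked not-evaluable and excluded from
the row maximum.

When the gain matrix is built from a *fitted* σ model, estimation error
displaces each row's gain peak by a few tenths of a millimetre, so even
a perfectly optimal agent accrues apparent margins of order 10⁻³ points
— far above ε. Dominance flags from fitted models should therefore be
read together with the bootstrap fractions; the false-alarm calibration
of the test itself is established under the generating noise model,
where an optimal agent is flagged in under 5% of replicate experiments.

## Evidence in decibels

Evidence for the optimal-planning account is 10·log₁₀ of the posterior
odds between M₀ — observed mean excursions scatter around the identity
line through the MEG predictions — and M₁, a free line. Observations are
modelled as Gaussian around the line with known SDs equal to their
per-point standard errors. M₀ has no free parameters; M₁ marginalizes
slope ~ U(0, 2) and intercept ~ U(−20, 20) mm by trapezoidal integration
on a 201² grid (log-sum-exp). The uniform priors are weakly informative
and centered on M₀; they are a documented stand-in, not a reconstruction
of any particular published prior, and are configurable (zero-width
ranges degenerate to point priors, which reproduces the 0 dB identity
check). By construction the measure is antisymmetric under model
exchange, and 3–4.77 dB (odds 2:1–3:1) is the conventional floor for
significant evidence.

## Synthetic experiments

The generator emulates the study design exactly: 7 subjects, 9
conditions in randomized blocked order, 4 blocks × 30 reaches per
condition (1080 per subject). An agent policy supplies planned
excursions — `optimal` plans each condition's e* under the ground-truth
σ lines, `scaled(κ)` plans κ·e* (κ = 0.8 emulates stopping 80% of the
way to the optimum), `fixed` takes user values — and trials are drawn
from the implied bivariate Gaussian, labelled by the outcome
classifier, reproducibly for a given seed.

Ground-truth σ lines (no published coefficients exist for this task, so
these are the package's fixture): intercepts (3.4, 3.7, 3.9) mm for
locations 1–3, obstacle-plane slopes (−0.165, −0.158, −0.169), target-
plane slopes (−0.165, −0.148, −0.133). They were chosen once, by design,
to satisfy two study-like properties: the nine MEG excursions (−5.2 to
−13.7 mm) are separated pairwise by at least ~3 standard errors of a
pooled condition mean, so optima are genuinely distinct across
conditions; and the σ-signal across each location's three cost levels is
7–8.5× the sampling error of a pooled SD estimate, which centers the
fitted-line R² distribution in the 0.8–0.99 band characteristic of such
fits. Intercepts grow with eccentricity (longer, faster reaches are
noisier) and σ roughly doubles over a 20 mm excursion.

Defaults deliberately omit features of real data: subjects are
homogeneous (`between_subject_sd_mm = 0`), trials are serially
independent (an AR(1) switch exists solely to exercise the
autocorrelation diagnostic), crossings are exactly Gaussian with exactly
linear σ(ē₁), and ρ = 0. Passing tests therefore demonstrate that the
estimators recover a data-generating process of the assumed form — not
that real reaches satisfy those assumptions; the diagnostics module is
what interrogates the assumptions on real data. One practical
consequence: with homogeneous subjects the across-subject SEs entering
the evidence stage are unrealistically small, so end-to-end evidence on
default synthetic data is dominated by σ-fit propagation error and
strongly negative even for optimal agents. Enable subject heterogeneity
for realistic evidence magnitudes.

## Summaries

Per condition, `pooled` mode centers each subject's trials on that
subject's own mean before pooling second moments (mirroring pooled
value-diagram figures); `per_subject` mode averages within-subject
summaries and takes SEs across subjects. Sample SDs use the n−1
denominator. Endpoint means are summarized per condition independent of
excursion, following the empirical observation that endpoint bias
depends on target position only. Both SE flavors (across-trial and
across-subject) are emitted since figure conventions differ.

## Diagnostics

*Stationarity*: excursions are centered per block and averaged by
within-block position (1–30); a straight-line fit to the profile
summarizes drift (slope ± SE). *Autocorrelation*: biased (1/n) sample
autocorrelations to lag 15 with ±1.96/√n white-noise bounds (statsmodels
`acf`). In 30-trial blocks the biased estimator shrinks lag-k
coefficients by (n−k)/n, so the empirical breach rate is ~4% at lags 1–5
and ~2% over all 15 lags rather than the asymptotic 5%. *Gaussianity*:
values are standardized and paired with standard-normal quantiles at
plotting positions (i − 0.5)/n (Weibull positions i/(n+1) behind a
flag); the correlation of the QQ pairs is the linearity coefficient,
>0.995 for Gaussian samples of the sizes used here.

## Numerical choices and degenerate inputs

All APIs reject NaN/Inf coordinates. Units are mm and points throughout.
Probabilities are clipped to [0, 1] only to absorb quadrature residues
below 10⁻⁹. The MEG tie-break, σ-positivity floor (0.05 mm), dominance ε
(10⁻⁶ points), evidence priors and grid (201²), and ACF normalization
are as stated above. Replicated studies in the test-suite use 200
recovery replicates and 100 dominance replicates at the full design size
(7 × 1080 trials); Monte-Carlo oracles use 10⁶ draws, matching
closed-form probabilities within three binomial standard errors. The
pipeline derives one 31-bit sub-seed per stage from the run seed via
SHA-256, so stages are independently reproducible and a rerun with the
same config and seed is byte-identical.

## Known limitations

- Only horizontal coordinates at the two critical planes are modelled;
  trajectory shape between planes, timing, and the timeout cost are out
  of scope.
- The σ model is an empirical interpolation; no mechanistic claim is
  made about noise origins, and extrapolation beyond the σ-positive
  range is refused rather than modelled.
- With three summary points per line, per-line R² and parameter CIs have
  one residual degree of freedom and are individually volatile; all
  calibration statements are distributional, over replicate experiments.
- The evidence construction is a documented stand-in for unity-line
  model comparison, not a reconstruction of any specific published
  computation; conclusions should be robust to reasonable prior ranges,
  which are configurable.
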