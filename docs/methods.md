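# Methods

## Model

Each individual is a renewal process: waiting times between consecutive
events are i.i.d. draws from the distribution induced by the hazard

    λ(τ | θ) = λ₀ / ((τ/t₀)^α + 1) + λ∞,    θ = {λ₀, t₀, α, λ∞}, all > 0.

Survival function, CDF and density follow from the standard identities
S(τ) = exp(−Λ(τ)), Λ(τ) = ∫₀^τ λ(t)dt, P(τ) = λ(τ)S(τ). The model is
stationary in waiting time: no calendar-time (circadian/weekly) modulation,
no memory across intervals, no coupling between individuals. Those are
modelling assumptions, not numerical limitations.

Parameter roles and units (seconds throughout):

* **λ₀** (1/s) — quick-response rate; P(0) = λ₀ + λ∞.
* **t₀** (s) — critical timescale where the power-law burst regime begins.
* **α** (–) — heterogeneity exponent; the intermediate-regime log–log
  density slope is ≈ −α when the plateau and tail are well separated.
* **λ∞** (1/s) — long-time rate; sets the exponential tail and (for
  λ₀t₀ not too large) dominates the mean interevent time E[τ] = ∫₀^∞ S.

Interpretation assumes λ∞ ≪ λ₀. That is deliberately *not* enforced as a
constraint — a fit may legitimately land in the near-exponential corner —
but construction of a parameter set with λ∞ ≥ λ₀ raises a diagnostic
warning and sets a `tail_dominant` flag.

Exact zeros are disallowed; "λ₀ = 0" limits are represented by the floor
1e-12. This keeps every log-likelihood finite and the optimizer's log-space
domain open, at the cost of a λ∞τ = 1e-12·τ nuisance term that is
negligible at any realistic τ.

## Cumulative hazard evaluation

Λ(τ) = λ∞τ + λ₀t₀·φ(τ/t₀; α) with φ(u; α) = ∫₀^u ds/(1+s^α). φ has no
elementary antiderivative for general α; it does have the closed form
u·₂F₁(1, 1/α; 1+1/α; −u^α). The implementation evaluates that
hypergeometric form (scipy's `hyp2f1`), with three refinements:

* α = 1 and α = 2 use the exact elementary forms ln(1+u) and arctan(u)
  (the hypergeometric parameter combination is logarithmically degenerate
  there and loses ~8 digits at large u);
* for u^α > 10³⁰ with α > 1 the two-term tail expansion
  φ(∞;α) − u^{1−α}/(α−1) + u^{1−2α}/(2α−1), with
  φ(∞;α) = (π/α)/sin(π/α), avoids extreme hypergeometric arguments;
* the argument is clipped to avoid overflow in the remaining region.

A dense sweep against 30-digit `mpmath` quadrature (α ∈ [0.31, 7],
u ∈ [1e-8, 1e8]) shows ≤ 2.3e-14 relative error, comfortably inside the
1e-8 accuracy contract. Adaptive quadrature (`scipy.integrate.quad` at
epsrel 1e-11) is retained as the independent slow path used by the test
oracles, never by the main code path. The closed form was chosen over
quadrature as the primary path because it is vectorized (≈1 µs/point),
which is what makes desk-scale maximum-likelihood fitting and the
million-draw simulations feasible.

E[τ] integrates S by adaptive quadrature under x = log(1+τ) (taming the
many-decade support), switching to the closed-form exponential tail
S(A)/λ∞ beyond A = 35/λ∞ (truncation error O(e⁻³⁵)).

## Maximum-likelihood fitting

ln L(θ) = Σᵢ [ln λ(τᵢ) − Λ(τᵢ)], maximized in log-parameters
(ln λ₀, ln t₀, ln α, ln λ∞) so positivity vanishes and the
orders-of-magnitude parameter ranges become well scaled. Repeated durations
are collapsed to unique values with multiplicities first (relevant for
1-second-resolution data).

Optimizer: L-BFGS-B, box bounds λ₀, λ∞ ∈ [1e-12, 1e3] 1/s,
t₀ ∈ [1e-3, 1e9] s, α ∈ [0.05, 20]; gradient tolerance 1e-6, relative
function-reduction cutoff 1e-14 (the likelihood is extremely flat along
the λ₀ → 0 ridge on near-exponential data; the default cutoff stops
~1e-5 short of the nested exponential MLE), at most 500 iterations per
start. The gradient is analytic in ln λ₀, ln t₀, ln λ∞ — note
∂Λ/∂t₀ = λ₀[φ − u/(1+u^α)] is closed-form — while ∂φ/∂α is taken by
central differences (relative step 1e-5), so one objective-plus-gradient
evaluation costs three φ sweeps.

Multi-start: the critical-timescale axis is the one direction where a
single heuristic start can land in the wrong basin (observed failure mode:
everything collapses to an effectively exponential corner solution). The
five default starts therefore anchor t₀ at the duration quantiles
0.5, 0.1, 0.25, 0.75, 0.05, with λ₀ tied to each candidate as
1/(mean of durations below it + 1 s resolution), α = 1.5, and
λ∞ = 1/mean(τ). Starts beyond five add seeded N(0, 0.5) log-space jitter.
Per-series seeds for cohort analyses derive from a CRC of the sorted
durations, making every population summary invariant to cohort and
within-series ordering.

Fits on fewer than 20 observations carry a warning; per-user analyses use
an activity filter of more than 100 events by default. No standard errors
are produced (out of scope); `FitResult.warnings` flags λ∞ at its floor
(unidentified tail) and λ∞ ≥ λ₀.

## Baselines

Exponential and log-normal MLEs are closed form. The Weibull shape solves
the standard 1-D profile equation by bracketed Brent root-finding (scale
profiled out); zero durations are clipped up to the smallest positive value
inside the log terms, a pragmatic regularization since the Weibull MLE is
ill-posed at τ = 0 for shape < 1. The Pareto tail exponent is the
conditional (Hill) MLE 1 + n_tail/Σ ln(τᵢ/x_m) given the cutoff; `tune_xm`
scans candidate cutoffs over (at most 200) order statistics and minimizes
the KS distance between the tail data and the fitted tail — the standard
power-law fitting convention, and exactly the quantity the cropping curve
plots. Zeros are dropped (with a logged count) for the log-supported
families only.

## Goodness of fit

Three one-sample tests per (user, model):

* **KS**: D from both one-sided step discrepancies at the order
  statistics; p-value from the exact small-sample distribution below
  n = 100 and the asymptotic Kolmogorov distribution above. The implied
  5% critical D follows the classical ≈1.358/√n form.
* **Chi-square**: k = min(⌊n/5⌋, 50) equal-probability bins under the
  fitted model (expected count ≥ 5 by construction) via the probability
  integral transform; dof = k − 1 − (#fitted parameters).
* **Cramér–von Mises**: W² = 1/(12n) + Σ(F(τ₍ᵢ₎) − (2i−1)/(2n))², with
  the standard asymptotic W² distribution for the p-value (valid down to
  n = 1, where W² = 1/12 + (F(x) − ½)²).

Default p-values are classical, i.e. they do not account for the
parameters having been fitted to the same data — matching the protocol the
comparison tables and critical-value curves assume. This makes the
absolute pass rates anti-conservative for well-specified models; they are
used comparatively across models evaluated under the same convention. An
optional parametric bootstrap (resimulate from the fitted model, refit,
recompute; 199 resamples recommended) provides calibrated p-values; both
are reported when enabled, with `passed` tied to the classical value.

`evaluate_population` fits every family per user and reports the
arithmetic-mean statistic and pass-rate fraction per family — the
model × {ks, chi-square, CvM} summary table — excluding inactive users and
fit failures with logged counts. `crop_curve` drops each user's smallest
⌊fn⌋ durations, refits the chosen baseline (Pareto support shifted to the
new minimum), and reports the average KS p-value *and* average KS
statistic per fraction; the multiscale model is never cropped and its
uncropped average p-value is the reference line. On modest per-user
samples the p-value keeps rising slowly with f simply because n shrinks;
the statistic column is the sample-size-free measure of fit quality and is
the right place to read off the "most of the improvement by ~30%
cropping" behaviour.

## Simulator

Waiting times are drawn exactly by inverse transform on the cumulative
hazard: with E ~ Exp(1), solve Λ(τ) = E. The solver interpolates an
initial guess from a 600-point geometric grid spanning the analytic root
bounds E/(λ₀+λ∞) ≤ τ ≤ E/λ∞, then applies Newton iteration with a
multiplicative-floor safeguard to relative tolerance 1e-12; because Λ is
increasing and concave-to-linear, the iteration converges monotonically
once left of the root. Inversion was chosen over Ogata thinning because Λ
is cheap and monotone, giving one exact draw per event and bit-for-bit
reproducibility.

`sample_population` emulates the population heterogeneity reported for
large messaging cohorts, with defaults declared once:

* log₁₀ λ₀ ~ N(−1.7, 0.3) — quick responses every ~10–250 s;
* log₁₀ t₀ ~ N(1.7, 0.3) — modal critical timescale near 100 s;
* log₁₀ λ∞ ~ N(−4, 0.3), truncated below at 1e-6/s (mimicking the
  sampling bias against near-inactive users);
* α ~ skew-normal parameterized by (mean 1.45, sd 0.3, shape 3, i.e.
  positive skew), truncated to α > 0.2;
* events per user uniform on [200, 1000].

Truncations are enforced by rejection (error after 1000 tries). Per-user
generators are spawned from the master seed via `SeedSequence`, so cohorts
are reproducible and order-independent. Timestamps are real-valued by
default; an optional quantization mode floors them to whole seconds.

What the generator does *not* emulate: circadian and weekly rhythms,
nonstationarity over the observation window, within-user correlation
between successive intervals, cross-user correlation, and finite
observation windows (series have a fixed event count, not a fixed
duration). Passing tests on this synthetic cohort therefore demonstrate
self-consistency of the estimation and evaluation pipeline under the
model's own assumptions — not that real chat data satisfies them.

A consequence of drawing λ₀ and t₀ independently: a few percent of
synthetic users get λ₀t₀ ≫ 1, exhausting their waiting-time mass inside
the quick-response plateau. Their induced distribution is intrinsically
near-exponential, so the exponential baseline's population pass rate is
small but not exactly zero on synthetic cohorts.

## Problem sizes and numerical choices in the validation suite

The test suite and the acceptance script size their simulations for a
single CPU: 50 replicate series of n = 5000 for parameter recovery,
200-user cohorts for the population protocol, 10⁶ draws for the
burst-regime slope, 1000 replicates of n = 500 for type-I calibration of
KS and CvM against the true generating parameters (no refit). The
burst-regime slope is read off a log-binned density (20 bins/decade,
geometric bin centers, empty bins dropped) by least squares on the
stated window. When the fit window is chosen where the plateau correction
(1+u^{−α})⁻¹ and the λ∞ floor are both ≲1% — e.g. λ₀ = 0.02/s, t₀ = 3 s,
λ∞ = 1e-8/s over τ ∈ [10², 10⁴] — the slope reproduces −α to within
±0.02 in expectation; with a heavier floor (λ∞ = 1e-6/s) or a window
closer to t₀ the measured slope is systematically shallower than −α
because both window ends bend upward, a property of the distribution
itself rather than of the estimator.

## Known limitations

* λ∞ is weakly identified when λ₀t₀ is large (survival underflows before
  the tail matters); the fit then reports λ∞ at its floor with a warning
  rather than attempting regularization.
* The pure power-law hazard γ/τ has a divergent cumulative hazard at 0;
  the special-case density makes its lower cutoff τ_min explicit.
* Classical (non-bootstrap) p-values after fitting are anti-conservative;
  see above.
* Event-log ingestion expects times already in seconds; calendar parsing
  is deliberately out of scope.
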