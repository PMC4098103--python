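# Methods

## Model

The package models exposure–lag–response associations: the risk measured at
time *t* is the accumulation, over a lag window [ℓ₀, L], of contributions
from past exposure increments.  Writing the exposure history as
**q**ₓ,ₜ = (x_{t−ℓ₀}, …, x_{t−L}) on a yearly grid, the association is the
cross-basis function s(x,t;η) = Σ_ℓ f·w(x_{t−ℓ}, ℓ), with the bidimensional
surface f·w expanded on the tensor product of an exposure basis (dimension
vₓ) and a lag basis (dimension v_ℓ).  The model is linear in its vₓ·v_ℓ
coefficients, so estimation reduces to a standard regression with the
cross-basis block in the design matrix; no custom optimization is needed.
The lag convention is backward and discrete: lag ℓ refers to exposure
received during year t−ℓ, with ℓ₀ = 0 (or 2 for the cohort pipeline, where
a minimal latency of two years is assumed) and closed integer lags up to L.

Assumptions worth keeping in mind:

* the surface is *bilinear in the chosen bases* — flexibility is bounded by
  the basis dimensions, and lack of fit shows up as bias (visible in the
  simulation study for log-shaped exposure responses fitted with quadratic
  splines);
* contributions of different exposure increments act additively on the
  linear predictor (log-hazard) scale;
* the Cox fit assumes proportional hazards given the time-varying
  cross-basis covariates, with age (cohort pipeline) or follow-up time
  (simulation) as the time axis and delayed entry handled by left
  truncation.

## Bases and constraints

`basis.BasisSpec` supports linear, constant, step (piecewise constant),
threshold (hinge), B-splines of configurable degree (default quadratic,
the working choice throughout), natural cubic splines and log(x+shift)
transforms.  Conventions that matter:

* **Identifiability.** The exposure basis never carries an intercept: each
  of its columns multiplies every lag-basis column, so an intercept in f
  reproduces the whole lag basis and makes the cross-basis rank deficient.
  `build_crossbasis` rejects such specs and warns on residual rank
  deficiency, naming the offending column pairs.
* **Left constraint.** A spline basis without intercept is parameterized by
  dropping the left-terminal function of the full B-spline system; every
  remaining function vanishes at the left boundary, so the fitted
  lag–response curve starts from zero risk at ℓ₀ for any coefficients.
* **Right constraint.** Dropping the right-terminal B-spline function
  forces the curve to zero at L (used to encode washout of very remote
  exposures).  Both constraints are exact: the basis row at the constrained
  boundary is identically zero.
* **Natural cubic splines** are built as cardinal natural-spline
  interpolants of unit vectors on the sites (boundary, interior knots,
  boundary), giving df = #knots + 1 + [intercept]; dropping the intercept
  removes the left-boundary cardinal function.
* **Step bases** with c cut-offs yield c+1 disjoint indicators as a lag
  basis (intercept=True) and c indicators with the lowest stratum as
  reference as an exposure basis (intercept=False).
* **No silent extrapolation.** Evaluating any bounded basis outside its
  boundary raises; prediction grids must stay inside the observed exposure
  range.  Spline boundaries default to the observed range of the history
  matrix (exposure) or the lag window (lag).

## Prediction

All risk summaries are linear forms b'η with delta-method variance b'V(η)b:
lag–response curves at a fixed exposure, exposure–response curves at a
fixed lag, the full (exposure × lag) surface, the overall cumulative effect
of an arbitrary history (the sum of its per-lag contributions — an identity
that is tested), and risk trajectories along a profile.  Exposure-basis
rows are centered at a reference x₀ (default 0, the natural reference for
occupational exposures), so predictions are log-hazard ratios versus a
never-exposed subject and the curve at x₀ is exactly zero.  Confidence
intervals use the two-sided normal quantile (1.96 at the default 95%
level); pointwise, not simultaneous.

## Cox fitting

Cohorts are expanded to one row per subject per risk-set time (the
counting-process layout restricted to event times, which is all the partial
likelihood needs).  The fitter maximizes the Cox partial likelihood by
Newton–Raphson with step-halving, analytic gradient and observed
information, Efron's correction for tied event times (Breslow available for
cross-checks; the two coincide on tie-free data, which is tested), per-risk-set
max-centering of the exponentials, convergence at 1e-9 relative
log-likelihood change, at most 100 iterations.  The variance estimate is
the inverse observed information.  The implementation is validated against
lifelines' time-varying Cox fitter (agreement to ~1e-6 with tied data) and
against brute-force maximization on tiny examples.

AIC = −2logL̂ + 2k and BIC = −2logL̂ + log(d)·k, where k counts **all**
estimated coefficients (exposure cross-basis + confounder cross-basis +
calendar term in the cohort pipeline) and d the uncensored events.
Selection minimizes the criterion; ties break toward smaller k, then
candidate order.  Calendar time enters the cohort model as a linear term
evaluated at the risk-set age (the alternative — year at entry — is a
configuration choice).

## Simulation design

`simulate` generates time-varying exposure profiles on t = 1..100:
per subject a Poisson(5) number of spells with uniform start, geometric
(mean 10 years) duration and Uniform(0, 10) intensity, overlaps resolved by
the maximum.  This yields serially correlated, occupational-looking
exposure with roughly half the years exposed, so a 41-year lag window
essentially always contains exposure and cumulative effects are rarely
degenerate at zero.

True associations are the separable form f_s(x)·w_s(ℓ) on lags 0–40.
Exposure responses (normalized to f(10) = 1): linear x/10, plateau
log(1+x)/log(11), exponential (e^{3x/10}−1)/(e³−1).  Lag responses
(normalized to unit sum): constant, exponential decay with 10-year time
constant, and a Gaussian bump centered at lag 15 with width 7, zero-anchored
at lag 40.  A single magnitude parameter (default 6.0 — the log-HR of a
subject held at the maximum intensity over the whole window) scales every
scenario; it is chosen so that cumulative hazard ratios across realistic
histories span ~1–e³ and the selection criteria detect non-constant lag
structures with power near one at a few hundred events, while the true
hypotheses of linearity/constancy are still rejected at a small rate.  The
nine scenario shapes are this package's own surrogates for the study
conditions; their exact functional constants are configuration, not
estimates.

Event and censoring times are married to subjects by the permutational
algorithm: candidate times (uniform on (1, 100]; each subject independently
marked for censoring with probability 0.25) are processed in ascending
order, each event time assigned to an unassigned subject with probability
proportional to exp of its true cumulative effect at that time, each
censoring time uniformly.  Under a null association this is a uniform
random permutation (tested by goodness-of-fit); with ~400 subjects it
yields ≈300 uncensored events.  Covariates at a continuous time t use the
exposure history of year ⌊t⌋, identically in generation and estimation.
Each replicate draws from an independent substream spawned from the study
seed.

## Simulation study

Per replicate the 36-model grid is fitted: exposure bases {linear;
quadratic B-splines without intercept, 0 knots, 1 knot at 3.3/5/6.7, 2
knots at 3.3 and 6.7} × lag bases {constant; quadratic B-splines with
intercept, 0 knots, 1 knot at 13.3/20/26.7, 2 knots at 13.3 and 26.7},
spanning 1 to 20 df.  Performance is scored on the overall cumulative
effect β_c of a random subject's history at a random integer time in
[41, 100]: per-replicate relative errors give relative bias and relative
RMSE; coverage uses |β̂−β| ≤ z·SE with the two-sided 0.975 quantile
(the one-sided variant is available behind a switch); rejection rates are
the share of replicates whose selected model is non-linear in x or
non-constant in ℓ.  Replicates with |β_c| < 1e-8 are excluded from the
relative metrics (logged count) but still count toward coverage and
rejection rates.  Default problem sizes in the shipped scripts are m = 100
replicates for the linear-constant scenario and m = 50 for power scenarios
at nₛ = 400 (the full-scale study uses m = 500); the per-dimension design
build uses a sliding-window contraction on the (subject × year) grid that
is tested for exact agreement with the reference cross-basis construction.

## What the synthetic data do and do not show

The generator reproduces the structural features the estimators care about:
serially correlated bounded intensities, protracted histories evaluated at
many risk sets, ~25% random censoring, separable true surfaces.  It does
not emulate measurement error in reconstructed histories, informative
censoring, cohort entry dynamics (simulated subjects are all at risk from
t = 0), competing risks, or confounding (the simulation fits the exposure
cross-basis alone).  Passing tests therefore demonstrate correctness of the
estimation and selection machinery under the stated sampling scheme, not
robustness to those real-data complications.  Because the scenario
functions are configurable surrogates, quantitative operating
characteristics are reproducible only where the truth lies inside the
candidate grid (linear-constant); for log/exponential shapes the
qualitative pattern (stronger BIC underfitting bias, lower BIC coverage)
is the reproducible content.

## Numerical choices and degenerate inputs

* B-spline evaluation at the exact right boundary is overwritten with the
  exact limit (terminal function 1, others 0) to keep constraints exact.
* Degenerate observed exposure ranges (constant histories) widen the
  default basis boundary by one unit instead of failing.
* Risk sets with a single member contribute no information; a model whose
  information matrix is singular raises with the suspect columns named.
* The cohort reader validates consecutive 5-year intervals and
  non-decreasing cumulative exposures, reporting subject and row on error;
  within-interval allocation is uniform (increment/5), smoking is held
  constant after the last reported interval, exposure before the recorded
  span is zero.

## Known limitations

Penalized (smoothing) spline bases, non-negativity or monotonicity
constraints on w(ℓ), stratified/frailty Cox models, formal post-selection
inference corrections, and 3-D rendering are out of scope (numeric grids
are exported instead).  Knot placement for the lag dimension follows the
13.3/20/26.7 convention; the near-equivalent 26.6 placement used in parts
of the cohort analysis is available through configuration.
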