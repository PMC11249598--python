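# Methods

## Biological age via residual life

The package treats biological age as a population-referenced summary of
remaining lifespan. Let T be age-at-death, C chronological age at study
entry and X a vector of markers assumed constant over life. Mean
residual life is `mrl(t) = E(T − t | T > t)`; median residual life
`medrl(t)` is the m with `S(t + m) = S(t)/2`. A subject has biological
age b when their conditional residual life at entry equals the reference
population's residual life at age b. Prediction therefore factors into
(1) estimating `rl(c|x)` from a survival regression and (2) inverting
the reference population's residual-life curve at that value.

Both residual-life kinds are supported. The median is the default in
simulation code paths: it requires no integration, and under
Gompertz-type adult mortality the two differ by well under 15% at the
ages that matter (asserted in the test suite). The mean is the natural
default when an external national-statistics table supplying life
expectancy is the reference.

## Models

**Gompertz AFT** (the centerpiece). Baseline hazard `h0(t) = a·e^{bt}`,
a, b > 0; covariates rescale age, `S(t|x) = S0(t·θ)` with
`θ = exp(βᵀx)`. The Gompertz family is closed under this rescaling: the
conditional law is Gompertz(aθ, bθ), so conditional residual life has a
closed form for the median and a one-dimensional integral for the mean.
The delayed-entry log-likelihood

    Σ_i δ_i·log h(t_i|x_i) − [H(t_i|x_i) − H(c_i|x_i)]

conditions each subject on survival to their entry age c_i, which is
what makes estimates valid under the cohort's left truncation.
Optimization is over (log a, log b, β): positivity is free and the
conditioning is far better than on the natural scale (a ≈ 1.2e−4).
Standard errors come from the inverse observed information (central
finite differences of the analytic score). This model is numerically
delicate; see *Numerical choices*.

**Cox on the age axis** (PH-semipar comparator). Partial likelihood with
delayed-entry risk sets (subject i is at risk at event age t iff
`entry_i < t ≤ exit_i`), fitted by lifelines; the baseline cumulative
hazard is the Breslow estimator computed here with uncentered linear
predictors. Ties are handled by Breslow throughout: simulated event
times are continuous, so ties are measure-zero; for empirical data this
choice is simply documented. Residual life follows from the
step-function survival `exp(−Ĥ0(t)·e^{β̂ᵀx})`. When the Breslow support
ends before the conditional survival reaches the required level the
prediction is *unsupported*: the default is a hard
`InsufficientTailSupportError`, with an opt-in `missing="nan"` that
flags the affected subjects instead. Silent tail extrapolation is never
performed — a semiparametric model fitted to data that do not cover the
tail of lifespan genuinely cannot predict residual life there.

**GrimAge-type clock** (comparator). Stage one is a Cox model on
time-on-study (entry is time zero) with covariates [entry age, markers];
stage two maps the full linear predictor affinely onto the training
set's chronological-age mean and SD. The published recipe leaves open
whether the age term is removed before standardization; this
reconstruction standardizes the full linear predictor, which reproduces
the training-set moment identity exactly and is documented as the
package's reading. No life table or residual-life value is involved, and
none is reported for it.

## Life tables

A `LifeTable` is population survival on a regular age grid, default
[0, 120] years at step 0.05 (0.01-year inversion accuracy at modest
size). Sources: parametric (baseline `S0`, or marginal
`E_Z[S(t|lp = Z)]` with `Z ~ N(0, σ_lp²)` by 80-node Gauss–Hermite
quadrature — independent normal markers enter only through βᵀX, which is
univariate normal), empirical (Kaplan–Meier with delayed entry, survival
fixed at 1 below the earliest entry age, with a warning when the curve
never reaches half its initial value), or files in survival / lx / qx
dialects.

Mean residual life uses the trapezoidal rule and refuses to answer when
the relative survival mass beyond the grid end exceeds 1e−6; the median
uses the interpolated first crossing of `S(t)/2`. Inversion takes the
*first downward crossing* of the tabulated residual-life curve (via a
running minimum), which resolves numerical wiggles in the ragged tail of
empirical tables; a flat curve (exponential law) is reported as not
invertible. Out-of-range values raise by default; prediction code flags
them as missing rather than clipping, because clipping would silently
distort calibration. An optional Gompertz tail extension (log-linear fit
on the last 15 years of informative support) exists for empirical tables
but is off by default — extrapolating an undefined tail would hide
exactly the failure mode that disqualifies semiparametric predictors on
cohorts with narrow age ranges.

## The simulator

`draw_cohort` emulates a prospective cohort: markers X₁, X₂ ~ N(0, 1)
drawn at birth and constant over life; entry age C ~ U(20, 80);
age-at-death by inverse-cumulative-hazard sampling,

    PH:  t = H0⁻¹(−log U / e^{βᵀx}),      AFT: t = H0⁻¹(−log U) / e^{βᵀx};

draws with T < C discarded (people who already died cannot be enrolled)
and counted as attrition; administrative censoring 20 years after entry.
Baselines: Gompertz a = e⁻⁹, b = 0.085 per year; Weibull rate form
`h0(t) = λνt^{ν−1}` with λ = 34⁻¹⁰, ν = 8 (the printed rate mixes
exponent 10 with shape 8, but as printed it puts the median lifespan
near 78 years, so it is used verbatim). Effect sizes: β = (0.3, 0.3)
Gompertz-PH, (0.05, 0.05) Gompertz-AFT, (0.35, 0.35) Weibull-PH (its AFT
dual is β/ν). `n_obs` counts *retained* subjects — sample sizes describe
analyzable cohorts — and the generator draws until it has exactly that
many, so every cohort is bit-reproducible from its seed.

True biological age inverts each subject's analytic conditional residual
life in the true-parameter population table, marginal over the marker
distribution by default (the baseline mode is exposed as an option). The
truth table's grid runs to 140 years so strongly accelerated late
entrants stay inside the invertible range; the few-in-a-million subjects
whose residual life still falls outside (e.g. a ~4σ decelerated ager
whose remaining life exceeds a newborn's) have their truth saturated at
the table bounds rather than erroring.

What the simulator does *not* emulate: time-varying markers, competing
risks, informative censoring, measurement error, or the correlated
high-dimensional marker panels of real omics data. Passing tests
demonstrate correctness of the machinery under the stated mechanisms,
not predictive performance on real cohorts.

## Evaluation

RMSE is computed against the simulator's truth; flagged predictions must
be excluded by the caller (their presence is an error, not a silent
drop). Uno's IPCW concordance is computed on time-on-study: weights
1/Ĝ(T_i−)² with Ĝ the Kaplan–Meier of the censoring distribution
(events and censorings swapped; no delayed entry on this scale),
comparable pairs (T_i < T_j, T_i < τ, δ_i = 1), score ties counted one
half. τ defaults to the largest event time with Ĝ ≥ 0.1, capping weight
explosion; the standard error is a leave-one-subject-out jackknife with
the weights held fixed. The implementation agrees with an independent
brute-force double sum to 1e−12 and with scikit-survival's estimator
exactly. Calibration bins subjects into equally sized groups (sizes
differ by at most one) on the life-table predicted X-year mortality
`1 − S_pop(b̂+X)/S_pop(b̂)` and compares group means with the
Kaplan–Meier complement at the horizon, which stays unbiased under
censoring inside the horizon. The age-acceleration Δ is the per-sample
OLS residual of b̂ on C (the regression is not frozen on a training set;
whether it should be is left open in the field, and the per-sample
definition is the literal one); its association with mortality is
reported as the hazard ratio per SD of Δ in a Cox model on time-on-study
adjusted for entry age and stratum.

## The experiment harness

`run_experiment` crosses mechanisms × training sizes × predictors. Per
replicate, a fresh training cohort and an independent 5000-subject test
cohort are drawn (the test cohort is shared across training sizes within
a replicate, which removes a nuisance source of Monte-Carlo noise from
size-trend comparisons). Residual-life predictors translate through the
true-mechanism marginal life table, isolating model-fit error from
life-table estimation error. Failed fits (singular Hessian,
non-convergence, missing tail support) are excluded from the cell mean
and reported as counts. The replicate seed scheme is a plain counter —
SeedSequence((root, mechanism_index, replicate, role)) — so any cell can
be reproduced in isolation. The default of 20 replicates per cell keeps
a full grid in the minutes range while leaving the orderings between
predictors far outside replicate noise; the replicate count is a config
field.

## Numerical choices

- Overflow: all survival evaluations go through log-survival and
  exponentiate last; the Gompertz exponent is capped at age 200, beyond
  which survival is treated as exactly 0 (double precision overflows
  near bt ≈ 700).
- Gompertz AFT fitting: start from a marginal (covariate-free) Gompertz
  fit, itself started at a = e⁻⁹, b = 0.085, with β = 0; L-BFGS-B with
  the analytic score, then Newton polishing until the score norm is
  below 1e−5 (typically 1e−12). Convergence failures and singular
  Hessians raise with diagnostics; they are never imputed.
- Inversion tie-break: first downward crossing with linear interpolation
  between grid ages; round trips are exact to within one grid step.
- Degenerate inputs rejected with named rows/lines: exit ≤ entry,
  status outside {0, 1}, missing markers, non-monotone table ages,
  increasing survival, constant chronological age in the Δ regression.

## Known limitations

Lifespan only — no healthspan tables. Single measurement per subject; no
within-person trajectories. No penalized fitting for high-dimensional
markers. Only Gompertz and Weibull baselines; no flexible-parametric or
semiparametric AFT variants, whose fitting is known to be unstable. The
GrimAge-type stage-two transform is a documented reconstruction, not the
original proprietary recipe.
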