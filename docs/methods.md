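# Methods

`dynasig` audits annual scalar time series for two dynamical signatures —
out-of-sample predictability and state-dependent (nonlinear) dynamics —
and compares those signatures between groups of series, e.g. observed
fisheries data versus the outputs of assessment or ecosystem models fitted
to such data. This note records the model, its assumptions, the default
parameters and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions in the implementation.

## Preparation

Each raw series is (optionally) trimmed to an explicit year range, then
standardized to zero mean and unit sample (n−1) standard deviation, then
first-differenced. Differencing removes first-order autocorrelation and
trend so that forecast skill measures dynamics rather than persistence;
the differenced series is deliberately not re-standardized, so that added
observation noise keeps a fixed scale relative to the signal.
Trimming is configuration, not inference: deciding when a fishery became
"fully developed" is a judgment call, so the package only exposes a
per-series start year. Year gaps are an error — the embedding assumes
unit-lag contiguity — and constant or very short (<10 post-trim
observations) series are excluded with a reason rather than analyzed.

## Forecasting model

State is reconstructed by time-delay embedding: vectors
x_t = (y_t, y_{t−τ}, …, y_{t−(E−1)τ}) with targets y_{t+tp}, defaults
τ = tp = 1 for annual one-step forecasts. All forecasts are leave-one-out
cross-validated; the withheld unit is the predictee's own (vector, target)
pair. An optional exclusion radius (default 0) can additionally withhold
temporally adjacent pairs for sensitivity analysis.

**Simplex projection** predicts from the E+1 nearest neighbors (Euclidean
distance) with weights u_i = exp(−d_i/d_1), d_1 the nearest distance.
Zero-distance neighbors take all the weight; other weights are floored at
1e−6 against exponential underflow. The embedding dimension E is scanned
from 1 to E_max = 10 and chosen to maximize LOOCV rho (forecast–observation
Pearson correlation), ties to the smaller E; selection by minimum MAE is
available by configuration. E_max = 10 with the minimum series length of
10 + 1 keeps at least E + 2 usable pairs at every candidate dimension.

**S-map** fits, per predictee, a weighted linear regression of targets on
(1, x) over all remaining library points, with weights
w_i = exp(−θ d_i / d̄), d̄ the predictee's mean distance to the library.
θ = 0 gives a single global linear autoregression; larger θ localizes the
map. The θ grid is the conventional scan
{0, 1e−4, 3e−4, 1e−3, 3e−3, 0.01, 0.03, 0.1, 0.3, 0.5, 0.75, 1, 1.5, 2,
3, 4, 6, 8}.

Skill is summarized by rho, MAE and RMSE, with a one-sided p-value for
rho > 0 from Fisher's z (z = atanh ρ, statistic z√(n−3), upper-tail
normal). Series with p ≥ 0.05 or non-positive best rho are screened out of
the nonlinearity analysis: without significant predictive signal the θ
scan compares noise against noise.

## Nonlinearity test

The statistic is ΔMAE = MAE(θ=0) − min_{θ>0} MAE. Its null distribution
comes from surrogate series that share the original's amplitude
distribution and linear autocorrelation but none of its state-dependent
structure. p = (1 + #{ΔMAE_sur ≥ ΔMAE_obs})/(1 + S) with S = 500
surrogates by default; the observed statistic enters its own null, so
p > 0 always. A series is classified nonlinear when p < α = 0.05.

Design choices worth making explicit:

- The default surrogate is the **iterated amplitude-adjusted Fourier**
  (IAAFT) construction: it preserves the amplitude distribution exactly
  and the power spectrum to convergence, realizing the null "a static
  transform of a linear Gaussian process". A plain uniform shuffle is
  available behind `surrogate_scheme="shuffle"`, but shuffling also
  destroys *linear* autocorrelation, and differenced series retain some
  (differenced AR(1) with φ = 0.5 keeps lag-1 autocorrelation ≈ −0.25);
  against the shuffle null the test's measured type-I rate on such series
  was ≈ 11% at nominal α = 5%, versus ≈ 6% under IAAFT. Calibration
  against the linear-stochastic null is the property the classification
  rests on, so IAAFT is the default.
- Each surrogate re-runs the embedding-dimension selection before its θ
  scan, mirroring the pipeline that produced the observed statistic.
  This matters: the observed series gets to choose its most forecastable
  E, and surrogates denied the same choice produce too small a null —
  with inherited E the measured false-nonlinear rate on AR(1) series was
  ≈ 10% at nominal 5%, versus ≈ 4% with re-selection. The cheaper
  fixed-E mode remains available (`surrogate_reselect_E=False`) with
  that caveat.
- An optional early stop (`surrogate_early_stop`) halts the surrogate
  loop once enough surrogate statistics exceed the observed one that
  ``p >= alpha`` is guaranteed. Surrogates are consumed in a fixed
  seeded order, so the linear/nonlinear classification is identical to
  the full run; only the reported p-value is then based on the truncated
  null sample (flagged). Large simulation studies enable it.
- Per-surrogate random streams are spawned from one seed
  (`numpy.random.SeedSequence.spawn`), so results are independent of
  evaluation order.
- Under the null the p-value is approximately Uniform on its discrete
  support; the test's measured type-I rate on AR(1) series sits at the
  nominal 5% (see the calibration tests).

## Added-noise experiment

To ask whether smooth model outputs look linear merely because their
observation error was filtered out, i.i.d. N(0, 0.3²) noise is added to
the standardized (pre-differencing) series — sd 0.3 is therefore on the
standardized scale — and the full analysis (E re-selected per realization
by default) is repeated for 100 realizations, summarizing mean ± sd rho
and the fraction of realizations classified nonlinear. Realizations that
fail the skill screen count as linear in that fraction; realizations that
fail outright (degenerate geometry) are dropped and counted.

One subtlety: differenced i.i.d. noise is an MA(1) with lag-1
autocorrelation −1/2, which is itself partially predictable. Mean rho
therefore does not decay to zero as noise grows but to a floor around
0.25, and between sd ≈ 0.3 and 0.6 the mean-skill curve flattens and can
tick up slightly. The scientifically meaningful regime — noise small
enough that signal dominates — shows the expected strict decay.

## Group statistics

Per-category summaries report mean ± sd of the best-E simplex rho over all
series with defined skill, and percent nonlinear over screened-in series
(screened series are excluded from prevalence denominators but not from
skill summaries — screening speaks to signal reliability, not to skill
itself). Between-category machinery is standard: one-way ANOVA with
Tukey's HSD (studentized-range, classical pooled variance) for rho and for
series lengths, and logistic regression (Newton/IRLS) of the nonlinear
indicator on category contrasts with Wald z tests, the model-output
categories pooled as reference by default. Complete separation is detected
and reported with a Fisher's exact fallback on the collapsed 2×2 table.

## Synthetic generators

No real landings, survey, assessment or ecosystem-model series ship with
the package; generators emulate their statistical structure:

- **Noisy nonlinear** (data stand-ins): chaotic logistic map (r = 3.8),
  Ricker map (r = 3.0), or the Lorenz X coordinate (σ = 10, b = 8/3,
  r = 26; fixed-step RK4, step 0.01, 1000-step transient, every 10th step
  kept), plus additive Gaussian observation noise. The map parameters put
  the deterministic core in a chaotic regime so the nonlinearity detector
  has realistic power at series lengths of 50–200 years.
- **Linear-stochastic**: stationary AR(1) (φ = 0.5) — persistence typical
  of annual abundance indices; a Gaussian stochastic cycle (AR(2) with
  complex roots, period 20 y, root modulus 0.95) for slow multi-year
  oscillations; and sinusoids. A caution on sinusoids: a noisy
  deterministic oscillation is *not* a linear-stochastic process —
  recovering phase from noisy lags is a nonlinear filter — so noisy
  sines can legitimately be classified nonlinear. When a genuinely
  linear oscillatory series is needed, use the AR(2) cycle.
- **Model-output stand-ins**: centered moving averages (window shrinking
  symmetrically at the edges; even windows widened to odd) of a base
  series. Smoothing is what assessment and ecosystem models do to their
  inputs in the aggregate: variance shrinks, predictability rises,
  dynamics linearize. The reference model-output surrogate is a smoothed
  AR(2) stochastic cycle (period 15–25 y, window 5) rather than a
  smoothed AR(1): differencing strips AR(1) persistence almost
  completely, leaving nothing predictable to degrade, whereas stochastic
  cycles — resembling the slow oscillations real model-output biomass
  trajectories display — survive differencing with forecast skill near
  0.95 while remaining truly linear.

What the generators do **not** emulate: the red-noise spectra and
heavy-tailed errors of real landings data, effort-driven nonstationarity,
assessment-model autocorrelation structure, or any species interaction.
Passing tests therefore demonstrate that the *pipeline* behaves correctly
on series with known structure, not that real fisheries series would be
classified one way or another.

Every generator is a pure function of its spec, seed included; observation
noise is added to the trajectory after generation, on the trajectory's own
scale.

## Numerical choices

- The S-map weighted least-squares problems are solved through the normal
  equations, all θ values batched into one GEMM and one batched linear
  solve, with a truncated-eigendecomposition pseudo-inverse fallback
  (relative cutoff max(rcond², m·eps), rcond = 1e−10) for singular weight
  geometries. At θ = 0 this agrees with an SVD least-squares LOOCV oracle
  to ~1e−15 per prediction on standardized series; the batching is what
  makes 500-surrogate randomization tests affordable.
- Standardization uses the n−1 standard deviation; immaterial at these
  lengths but fixed for bit-reproducibility.
- rho is defined as 0 when either side of the correlation is constant;
  |rho| = 1 saturates Fisher's z and is reported with p = 0 and a flag.
- Ties in E selection go to the smaller E (parsimony). The E scan shares
  one pairwise-difference table across dimensions (squared lag-space
  distances at E+1 are those at E plus one shifted slice), so selection
  costs little more than a single simplex run.
- The whole pipeline is a pure function of (input table, configuration,
  master seed); per-series seeds are derived from the series id via CRC32
  so results do not depend on processing order.

## Problem sizes

The validation suite runs everything at desk scale on one CPU: 200-seed
size and 100-seed power studies with 200 surrogates each, 20-series noise
experiments with 100 realizations and 100 surrogates, and 500-simulation
null calibrations for the group statistics. The acceptance script analyzes
a 46-series synthetic study (14 landings-like, 10 survey-like, 10
assessment-like, 12 atlantis-like; lengths 50–60) with 100 surrogates and
the full 100-realization noise experiment on both model-output categories.

## Known limitations

- The rho screen and the nonlinearity call share α = 0.05; no
  multiple-testing correction is applied across series (matching standard
  practice for this audit, where per-series classification feeds group
  prevalence comparisons rather than standing alone).
- The IAAFT null covers static transforms of linear Gaussian processes;
  deterministic periodic signals in noise fall outside it and can be
  flagged nonlinear, which is mathematically defensible (their optimal
  predictor is nonlinear) but may surprise users thinking of "linear" as
  "non-chaotic". The shuffle scheme remains available for sensitivity
  checks and is stricter on autocorrelated series.
- The exclusion radius defaults to 0 ("all but one vector" LOOCV);
  temporally adjacent, dynamically correlated neighbors can flatter skill
  for strongly autocorrelated series.
- No convergent cross-mapping, multivariate embeddings, or
  Gaussian-process variants; single-series audit only.
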