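# dynasig

Dynamical-signature audit for annual population time series: how
predictable is a series out-of-sample, and are its dynamics state-dependent
(nonlinear) rather than linear-stochastic?

The package exists for a specific comparison that matters in fisheries
science: observed data (commercial landings, ichthyoplankton surveys)
versus the outputs of the models fitted to those data (single-species
stock assessments, end-to-end ecosystem models). Model outputs are
smoothed, aggregated, heavily parameterized transformations of their
inputs; if that processing strips nonlinear structure that the data
contain, the models overstate the stability and predictability of the
underlying system. `dynasig` quantifies both signatures per series and
compares them across categories. Because the real datasets are not
redistributable, the package ships generators that emulate their
statistical structure, so the entire pipeline is testable from scratch.

## Method

Series are standardized, first-differenced, and embedded in lag space
(Takens reconstruction): x_t = (y_t, y_{t−1}, …, y_{t−(E−1)}).

- **Simplex projection** forecasts each point from its E+1 nearest
  neighbors, weighted by u_i = exp(−d_i/d_1); scanning E = 1…10 and
  maximizing leave-one-out forecast skill ρ (Pearson correlation of
  predictions and observations) selects the embedding dimension.
  Significance of ρ > 0 comes from Fisher's z; series without significant
  skill are screened out.
- **S-map** fits one weighted linear regression per predictee over all
  library points, weights w_i = exp(−θ d_i/d̄). θ = 0 is a single global
  linear autoregression; θ > 0 lets the Jacobian vary with state. The
  nonlinearity statistic is ΔMAE = MAE(θ=0) − min_{θ>0} MAE, tested
  against a surrogate null (iterated amplitude-adjusted Fourier series,
  which keep the amplitudes and linear autocorrelation but no
  state-dependent structure):
  p = (1 + #{ΔMAE_sur ≥ ΔMAE_obs})/(1 + 500), nonlinear when p < 0.05.
- **Added-noise experiment**: N(0, 0.3²) noise on the standardized scale,
  100 realizations, full re-analysis each time — probing whether smooth
  model-like series owe their linearity to absent observation error.
- **Group statistics**: per-category mean ± sd ρ and % nonlinear, one-way
  ANOVA + Tukey HSD on ρ and on series lengths, logistic regression with
  Wald tests on nonlinearity prevalence.

See `docs/methods.md` for assumptions, defaults, and numerical details.

## Worked example

```python
import dynasig as ds

# a chaotic "landings-like" series: logistic map + observation noise
raw = ds.generate_map_series(
    ds.GeneratorSpec(kind="logistic_map", n=60, params={"r": 3.8},
                     seed=4, burn_in=100, obs_noise_sd=0.02)
)
verdict = ds.run_series(raw, ds.AnalysisConfig(n_surrogates=500, seed=0))
f, nl = verdict.forecast, verdict.nonlinearity
print(f"E = {f.E}, rho = {f.rho:.3f}, p_rho = {f.p_rho:.2e}")
print(f"delta_MAE = {nl.scan.delta_mae:.4f}, p = {nl.p_value:.4f}, "
      f"nonlinear = {nl.is_nonlinear}")
```

prints

```
E = 2, rho = 0.993, p_rho = 2.81e-94
delta_MAE = 0.6518, p = 0.0020, nonlinear = True
```

The best embedding dimension is 2 (the differenced logistic map needs two
lags), forecast skill is high and significant, and localizing the S-map
reduces error by 0.65 standardized units — far outside the surrogate
null (p = 0.002, the smallest value 500 surrogates can resolve), so the
series is classified nonlinear. Running the same audit on a smoothed
stochastic cycle (the model-output stand-in) yields comparable skill but
ΔMAE ≈ 0 and a linear classification.

The same pipeline runs from the shell:

```bash
dynasig simulate --config gen.yaml --out series.csv
dynasig analyze  --input series.csv --config analysis.yaml --out results/
dynasig compare  --verdicts results/verdicts.csv --out results/groups/
```

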