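# bayesgrowth

Bayesian nonlinear growth-curve analysis for poultry weight–age data, with
formal testing of sexual dimorphism in the growth parameters.

Body-weight growth in chickens follows a sigmoid trajectory that is usually
summarised by a three-parameter nonlinear model: an asymptotic mature weight
*A* (g), an inflection abscissa *B* (days, the age of fastest growth) and a
relative growth-rate constant *K* (/day). Whether males and females differ in
these parameters — sexual dimorphism — is typically discussed by eyeballing
separately fitted curves. This package implements the full Bayesian
alternative for mean weight–age series such as those recorded for free-range
Black Utrerana chickens (two sexes, 18 measurement ages from hatch to 336
days):

- **Growth models.** Four candidate mean functions with Gaussian
  observation error y<sub>i</sub> ~ N(μ(t<sub>i</sub>), σ²):

  | family | μ(t) | inflection |
  |---|---|---|
  | Logistic | A / (1 + e<sup>K(B−t)</sup>) | (B, A/2) |
  | Gompertz | A·e<sup>−e<sup>K(B−t)</sup></sup> | (B, A/e ≈ 0.368A) |
  | von Bertalanffy | A·(1 − ⅓e<sup>K(B−t)</sup>)³ | (B, (2/3)³A ≈ 0.296A) |
  | Brody | A·(1 − B·e<sup>−Kt</sup>) | none |

- **Elicited priors.** Informative sex-specific priors from a meta-analysis
  of comparable breeds: Normal for *A* and *B*, Gamma for *K*, and a
  weakly-informative half-t(3) on σ.
- **Posterior sampling.** An adaptive Metropolis–Hastings sampler (Laplace
  initialisation, cross-chain windowed adaptation, frozen mixed
  random-walk/independence kernel) with 4 chains × 4,000 iterations and 25 %
  warmup by default; Gelman–Rubin split-R̂ diagnostics and trace plots.
- **Model comparison.** ELPD, PSIS-LOO (Pareto-smoothed importance
  sampling) and WAIC with standard errors; ranking with a
  one-standard-error equivalence flag and combined two-sex ranking.
- **Dimorphism tests.** Savage–Dickey density-ratio Bayes factors for
  H0: θ<sub>male</sub> = θ<sub>female</sub> on each of *A*, *B*, *K*, the
  posterior probability of H0 (BF01/(1+BF01) at even prior odds), and
  Jeffreys-scale labels.
- **Synthetic data.** A generator that emulates the two-sex 18-age study
  design (421 female / 277 male birds, mean weights plus Gaussian noise, or
  individual birds with lognormal size variation), so the whole pipeline is
  testable against known truth.

## Worked example

```python
import bayesgrowth as bg

data = bg.generate_mean_weights(seed=1)          # one series per sex
fit = bg.fit_growth_model("von_bertalanffy", data["female"],
                          config=bg.ChainConfig(seed=1))
print(bg.summarize(fit.draws).round(4))
print(fit.convergence.rhat)
```

prints

```
                mean       sd    hpd_low   hpd_high
parameter
A          2103.3916  13.2613  2076.9224  2129.3237
B            63.5583   0.7012    62.1463    64.9530
K             0.0153   0.0003     0.0146     0.0160
sigma        20.2945   4.1825    13.0048    28.4121
{'A': 1.0006, 'B': 1.0019, 'K': 1.0006, 'sigma': 1.0009}
```

The posterior mean asymptote is ~2103 g with a 95 % HPD of roughly
[2077, 2129] g, the age of fastest growth ~64 days, and every split-R̂ sits
inside the accepted [0.99, 1.01] convergence band. Fitting the male series
the same way and running

```python
table = bg.run_dimorphism_suite(fit_male, fit_female, seed=0)
```

gives one row per parameter, e.g.

```
           hypothesis          bf01          p_h0                       label
A_male - A_female = 0 2.225074e-308 2.225074e-308    decisive evidence for H1
B_male - B_female = 0  8.330547e+00  8.928251e-01 substantial evidence for H0
K_male - K_female = 0  3.991106e+00  7.996436e-01 substantial evidence for H0
```

— the between-sex asymptote gap (~450 g in the generating truth) is detected
decisively (the posterior density of the difference at zero underflows, so
BF01 is numerically zero), while *B* and *K* show substantial evidence for
equality.

The `examples/` directory holds one short script per capability
(`01_growth_curves.py` … `05_full_pipeline.py`); each builds a small input,
runs the method and explains the numbers it prints.

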