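# Methods

## Model and inference

Each weight–age series (one per sex) is a set of mean body weights
y<sub>i</sub> at ages t<sub>i</sub> modelled as y<sub>i</sub> ~
N(μ(t<sub>i</sub>; A, B, K), σ²), independent across ages, where μ is one of
four sigmoidal families (logistic, Gompertz, von Bertalanffy, Brody; see the
README table). The posterior p(A, B, K, σ | y) ∝ L(y | θ) p(θ) combines this
Gaussian likelihood with independent priors per parameter. The two sexes are
always fitted independently; nothing is pooled across them except in the
model-comparison and dimorphism stages, which consume the per-sex fits.

### Von Bertalanffy parameterization

We use μ(t) = A·(1 − ⅓e<sup>K(B−t)</sup>)³. In this form B is exactly the
inflection abscissa and the inflection weight is (2/3)³A ≈ 0.296A, the
lower end of the 0.296–0.368 range usually quoted for the family. The
common alternative A·(1 − b·e<sup>−Kt</sup>)³ is equivalent up to a
reparameterization of B; we prefer the inflection-abscissa form because it
gives B the same reading ("age of fastest growth, in days") across the
logistic, Gompertz and von Bertalanffy families, which is what the
between-sex tests compare. Note the three-parameter form has a *fixed*
inflection fraction; a variable fraction would require a fourth (Richards)
parameter, which is out of scope.

### Brody's shape constant

Brody's B is not an inflection age but a dimensionless constant in (0, 1]
(weight at hatch is A(1−B)). The day-scale Normal prior used for the other
families is meaningless here, so Brody gets Normal(0.95, 0.05) truncated to
(0, 1] — hatch weight between roughly 0 and 10 % of the asymptote, which
covers real chicken data comfortably. Internally the sampler works on
logit(B) (with the change-of-variables Jacobian) so that the hard boundary
at 1, against which the posterior piles up, does not degrade
Gaussian-shaped proposals; draws are returned on the natural scale.

## Priors

Sex-specific elicited priors (meta-analytic, hard-coded defaults):

| parameter | female | male |
|---|---|---|
| A (g) | Normal(1950, 166.81) | Normal(2800, 290.62) |
| B (days) | Normal(62, 5.32) | Normal(70, 4.43) |
| K (/day) | Gamma(25.60, 1496.80) | Gamma(17.740, 1144.55) |

Gamma is shape/rate, so the implied prior means of K are 0.0171 (female)
and 0.0155 (male) per day — exactly the order observed in fitted chicken
growth curves. The Normal scale entries are standard deviations; read as
variances they would make the priors absurdly dogmatic (e.g. SD 13 g on a
2 kg asymptote). Two further reading decisions: the male K shape is 17.740
(a decimal comma; a shape of 17,740 would put the prior mean near 15/day,
i.e. full growth within hours), and the residual SD — for which no prior is
stated anywhere we could elicite from — gets a half-t(3, s) with s set to
the sample SD of the weights being fitted (the weakly-informative default
of mainstream Bayesian regression software; 700 g when no data are at
hand). All of these are configurable per `PriorSpec`.

## Sampler

The four-parameter posteriors here are smooth, unimodal and cheap to
evaluate, so the engine is an adaptive Metropolis–Hastings scheme rather
than gradient-based HMC; the contract is distributional and is pinned by a
conjugate closed-form oracle (a model linear in A with the other parameters
fixed), a parameter-recovery study, and an external cross-check against an
affine-invariant ensemble sampler on the identical log posterior.

1. **Laplace initialisation.** The posterior mode is found with L-BFGS-B in
   prior-standardised coordinates (raw scales span five orders of
   magnitude), and the inverse finite-difference Hessian gives an initial
   covariance. Mode coordinates pinned at a support boundary are nudged
   inside before differentiation; a non-PD Hessian falls back to the
   diagonal of prior variances.
2. **Warmup (25 % of iterations, three windows).** Chains start at
   independent prior draws — genuinely overdispersed, so R̂ is meaningful.
   From the first iteration each chain alternates random-walk steps
   (covariance 2.38²/d × Σ, global step size tuned by Robbins–Monro toward
   30 % acceptance, capped) with independence MH proposals from a
   multivariate t₅ approximation of the posterior — initially the Laplace
   approximation, so chains jump into the bulk almost immediately. After
   each window the covariance is re-estimated as the average *within*-chain
   covariance of the chains whose mean log posterior is within 100 of the
   best chain's (total pooled covariance would be inflated by residual
   between-chain dispersion; stranded chains are excluded and get pulled in
   by the next accepted independence jump), and both proposals are rebuilt.
3. **Sampling.** The kernel is frozen at the end of warmup (covariance,
   step size, and the independence-proposal frequency — 3 of 4 steps when
   its last-window acceptance exceeded 0.3, dropped entirely below 0.02), so
   the retained draws target the exact posterior. Draw counts are exact:
   chains × iterations × (1 − warmup fraction).

Typical behaviour at the default 4 × 4,000 configuration: independence
acceptance ≈ 0.5, effective sample sizes in the thousands, max split-R̂
≈ 1.001–1.005 across families and sexes.

All randomness flows from the `ChainConfig.seed` through
`numpy.random.SeedSequence`; there is no global state, and identical inputs
give bit-identical draws.

## Diagnostics and summaries

R̂ is the classic potential scale reduction
sqrt(((n−1)/n·W + B/n)/W) computed on split chains by default (each chain
halved, which also catches within-chain drift); the classic unsplit variant
is available for reference. The accepted band is [0.99, 1.01]. HPD
intervals are the shortest contiguous window over the sorted pooled draws
(first shortest window on ties). Trace plots overlay chains, one panel per
parameter.

## Model comparison

WAIC follows the standard decomposition (lppd − p<sub>waic</sub>, penalty =
summed pointwise draw-variance). PSIS-LOO uses importance ratios
1/p(y<sub>i</sub> | θ<sub>s</sub>) with the largest 20 % of each
observation's ratios replaced by expected order statistics of a
generalized Pareto fitted to that tail by the method of moments, capped at
the raw maximum; the fitted shape k is reported per observation and k > 0.7
is flagged (not fatal). Standard errors are √(n · var) over pointwise
contributions (doubled on the −2×ELPD scale); the convention behind any
particular published table is generally unstated, so SEs should be compared
qualitatively. Ranking is ascending LOO-IC with WAIC, then name, as
tie-breaks, and models within one SE of the best are flagged as equivalent.
Because the dimorphism stage requires one family for both sexes, rows can
be combined across sexes (indices summed, SEs in quadrature) and ranked
jointly — the pipeline selects the combined winner.

## Savage–Dickey dimorphism tests

For each θ ∈ {A, B, K}, difference draws δ = θ<sub>male</sub> −
θ<sub>female</sub> are formed by pairing the pooled per-sex draws after
independent seeded permutations (the fits are independent, so any pairing
is valid; permuting kills residual chain ordering). BF01 = posterior
density of δ at 0 (Gaussian KDE, Silverman bandwidth) over the prior
density of δ at 0. The prior difference density is exact for
Normal−Normal, a numerical convolution for Gamma−Gamma, and a seeded
Monte-Carlo KDE otherwise. P(H0 | y) = BF01/(1 + BF01) at even prior odds
— a choice forced by internal consistency of the published BF/probability
pairs this package's tests reproduce. Jeffreys bands are left-closed
([1,3) anecdotal, [3,10) substantial, [10,30) strong, [30,100) very
strong, ≥100 decisive, for H0), mirrored through 1/BF01 for evidence
toward H1. KDE density at a point far outside the draw bulk can underflow
to zero; BF01 is then clamped to the smallest positive float, which still
reads as decisive evidence for H1.

## Synthetic data

`generate_mean_weights` emulates the motivating study design: mean weights
of 421 female and 277 male birds at ages 0, 7, 14, 21, 28, 42, 56, 70, 84,
112, 140, 168, 196, 224, 252, 280, 308, 336 days, generated as the truth
curve plus i.i.d. N(0, 30²) g noise on each mean. The default truth is the
von Bertalanffy family at fitted posterior-mean values (female A=2109.8286,
B=64.2118, K=0.0152; male A=2560.5027, B=65.1733, K=0.0156). The 30 g
noise SD is our choice (no residual SD is published for the motivating
data); it yields posterior SDs on A of the published order (~40 g) from 18
observations and is exposed in `StudyDesign`. Negative simulated weights
(possible at age 0) are clamped to zero with a warning.

What the generator does *not* emulate: cohort attrition (group size is
constant across ages, whereas real group means may be weighted by survivors),
hatch-season effects, heteroscedasticity (real mean weights have
age-dependent SEs), and between-bird correlation structure beyond a single
lognormal size factor in `generate_individual_birds`. Passing tests
therefore demonstrate that the machinery is calibrated *under the model's
own assumptions*, not that those assumptions hold for any particular flock.

## Problem sizes used in tests

The acceptance checks run the reference configuration (4 chains × 4,000
iterations) where the claim concerns it — convergence of the von
Bertalanffy fit. Calibration studies that need many replicate fits use
reduced chains (4 × 2,000 for the 20-replicate recovery study, 2 × 2,000
for the 10-replicate model-ranking study); with ~0.2 s per 1,000 iterations
these sizes keep the whole suite in a few minutes while leaving Monte-Carlo
error well below the margins being asserted.

## Known limitations

- The random-walk/independence kernel is tuned for low-dimensional smooth
  posteriors; it is not a general-purpose replacement for NUTS on larger
  models.
- PSIS-LOO with 18 observations and informative priors rarely stresses the
  Pareto smoothing; the k > 0.7 path is exercised far less than the others.
- Mean-weight modelling discards individual-level variance information;
  `generate_individual_birds` exists precisely to study that gap, but the
  fitting pipeline itself consumes means only.
- BF01 under extreme separation is reported as the smallest positive float
  rather than a finite tail estimate; downstream only its order of
  magnitude ("decisive") is interpretable.
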