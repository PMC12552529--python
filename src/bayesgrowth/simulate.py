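"""Synthetic weight-age data emulating the Utrerana growth study design.

The study design being emulated: mean body weights of free-range Black
Utrerana chickens (421 females, 277 males) recorded at 18 ages from
hatch to 336 days.  The generator produces one mean-weight series per sex
from a chosen "truth" growth curve plus i.i.d. Gaussian noise on the
means — exactly the observation model the analysis assumes — so every
pipeline stage (fitting, comparison, dimorphism testing) can be exercised
and its calibration checked against known truth.

Defaults place the truth at the fitted von Bertalanffy posterior means
(female A=2109.8 g, B=64.2 d, K=0.0152/d; male A=2560.5 g, B=65.2 d,
K=0.0156/d) with a 30 g noise SD on the mean weights — a residual scale
that makes posterior parameter uncertainties of the reported order
attainable from 18 observations.

An individual-bird generator is also provided (lognormal bird-level size
factors around the sex curve) so mean-level fitting can be contrasted
with individual-level data, a limitation of analyses that only see group
means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import GrowthCurve, WeightSeries, mean_weight

#: Measurement ages (days after hatch) of the emulated study.
STUDY_AGES = (
    0, 7, 14, 21, 28, 42, 56, 70, 84, 112, 140, 168, 196, 224, 252, 280, 308, 336,
)

DEFAULT_NOISE_SD = 30.0  # grams, SD of the error on each mean weight


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    """Measurement schedule and cohort sizes."""

    ages: tuple[float, ...] = STUDY_AGES
    n_female: int = 421
    n_male: int = 277
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if len(self.ages) < 2 or any(np.diff(self.ages) <= 0):
            raise SimulationError("ages must be strictly increasing")
        if self.n_female < 1 or self.n_male < 1:
            raise SimulationError("need at least one bird per sex")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")

    def n_birds(self, sex: str) -> int:
        return {"female": self.n_female, "male": self.n_male}[sex]


@dataclass(frozen=True)
class TruthScenario:
    """Generating growth curves per sex (same family for both)."""

    female: GrowthCurve
    male: GrowthCurve

    def __post_init__(self) -> None:
        if self.female.family != self.male.family:
            raise SimulationError("both sexes must share one curve family")

    @property
    def family(self) -> str:
        return self.female.family

    def curve(self, sex: str) -> GrowthCurve:
        return {"female": self.female, "male": self.male}[sex]


def default_design() -> StudyDesign:
    """The 18-age, two-sex design of the emulated study."""
    return StudyDesign()


def default_scenario() -> TruthScenario:
    """Von Bertalanffy truth at the fitted posterior means per sex."""
    return TruthScenario(
        female=GrowthCurve("von_bertalanffy", A=2109.8286, B=64.2118, K=0.0152),
        male=GrowthCurve("von_bertalanffy", A=2560.5027, B=65.1733, K=0.0156),
    )


def generate_mean_weights(
    scenario: TruthScenario | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> dict[str, WeightSeries]:
    """One mean-weight series per sex: curve value + Gaussian noise.

    Weights that come out negative (possible at age 0 where the curve is
    near zero) are clamped to 0 with a warning rather than rejected.
    """
    scenario = scenario or default_scenario()
    design = design or default_design()
    rng = np.random.default_rng(seed)
    ages = np.asarray(design.ages, dtype=float)
    out = {}
    for sex in ("female", "male"):
        mu = mean_weight(scenario.curve(sex), ages)
        w = mu + design.noise_sd * rng.standard_normal(len(ages))
        if np.any(w < 0):
            warnings.warn(
                f"clamped {int((w < 0).sum())} negative simulated weight(s) "
                f"to 0 for sex={sex}",
                stacklevel=2,
            )
            w = np.maximum(w, 0.0)
        # keep post-hatch weights strictly positive for the series invariant
        w[1:] = np.maximum(w[1:], np.finfo(float).tiny)
        out[sex] = WeightSeries(ages=ages, weights=w, sex=sex)
    return out


def generate_individual_birds(
    scenario: TruthScenario | None = None,
    design: StudyDesign | None = None,
    between_bird_cv: float = 0.10,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-bird trajectories plus their per-age means, per sex.

    Each bird scales its sex's curve by a lognormal size factor with the
    given coefficient of variation, then adds measurement noise
    (``design.noise_sd``) at every age.  Returns, per sex, a dict with
    ``birds`` (n_birds x n_ages array) and ``means`` (WeightSeries of the
    per-age averages).
    """
    if between_bird_cv < 0:
        raise SimulationError("between_bird_cv must be non-negative")
    scenario = scenario or default_scenario()
    design = design or default_design()
    rng = np.random.default_rng(seed)
    ages = np.asarray(design.ages, dtype=float)
    out = {}
    for sex in ("female", "male"):
        n = design.n_birds(sex)
        mu = mean_weight(scenario.curve(sex), ages)
        if between_bird_cv > 0:
            s2 = np.log1p(between_bird_cv**2)
            factors = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=n)
        else:
            factors = np.ones(n)
        birds = factors[:, None] * mu[None, :]
        birds += design.noise_sd * rng.standard_normal(birds.shape)
        means = birds.mean(axis=0)
        means = np.maximum(means, 0.0)
        means[1:] = np.maximum(means[1:], np.finfo(float).tiny)
        out[sex] = {
            "birds": birds,
            "means": WeightSeries(ages=ages, weights=means, sex=sex),
        }
    return out
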