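"""Synthetic cohort and generic ordinal-GLM data with known ground truth.

The restricted clinical dataset motivating this package — a neonatal cohort
of extremely-low-birth-weight preterm infants scored for moderate/severe
bronchopulmonary dysplasia (BPD), with continuous/binary confounders and
three 7-level ordinal predictors giving the week (1..6, top-coded ">6" = 7)
a bacterial group was first detected in the upper airways — is available
only on request.  :func:`generate_bpd_like` emulates its *structure*:
a binary outcome linked through a logit model to weight, SGA status, sex,
multiples, steroid and antibiotic days, plus three correlated ordinal
predictors with sparse extreme levels (few subjects in week 1).

Defaults follow cohort-plausible choices: confounder effect sizes on the
logit scale mirror published estimates from such a cohort; covariate
distributions (not published) are truncated-normal weight below 1000 g,
Poisson day counts and Bernoulli binaries, all configurable.  Every draw
is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "BpdLikeConfig",
    "GroundTruth",
    "generate_bpd_like",
    "generate_ordinal_glm",
    "effect_vector",
]

#: default logit-scale confounder effects (intercept first)
DEFAULT_CONFOUNDER_EFFECTS = {
    "(Intercept)": 6.426,
    "weight_g": -0.012,
    "sga": 1.991,
    "sex_male": 2.107,
    "multiples": 1.054,
    "steroid_days": -0.174,
    "antibiotic_days": 0.079,
}

#: default level-occupancy profile: sparse first week, open-ended top level
DEFAULT_OCCUPANCY = (0.04, 0.08, 0.13, 0.17, 0.19, 0.17, 0.22)

ORDINAL_COLUMNS = ("gram_neg", "gram_pos", "pathogenic")


def effect_vector(shape, k: int, amplitude: float = 2.0) -> np.ndarray:
    """Centered level-coefficient vector for a named effect shape.

    ``"null"`` — all zeros; ``"linear"`` — linearly decreasing across
    levels with total range ``amplitude`` (later detection, lower risk);
    ``"decreasing_step"`` — elevated risk for the first half of the levels,
    step of size ``amplitude``; or a custom length-k vector (centered).
    """
    if isinstance(shape, str):
        if shape == "null":
            v = np.zeros(k)
        elif shape == "linear":
            v = -np.linspace(0.0, amplitude, k)
        elif shape == "decreasing_step":
            v = np.where(np.arange(k) < k // 2, amplitude, 0.0)
        else:
            raise ValueError(
                f"unknown effect shape {shape!r}; use 'null', 'linear', "
                "'decreasing_step' or a length-k vector"
            )
    else:
        v = np.asarray(shape, dtype=float)
        if v.shape != (k,):
            raise ValueError(f"custom effect vector must have length {k}, got {v.shape}")
    return v - v.mean()


@dataclass(frozen=True)
class BpdLikeConfig:
    """Configuration of the BPD-like cohort generator.

    ``ordinal_effects`` maps each ordinal predictor to an effect shape
    (``"null"``, ``"linear"``, ``"decreasing_step"`` or a length-k vector
    of level coefficients on the logit scale; vectors are centered).  The
    default carries a real effect only for pathogenic bacteria, matching
    the qualitative finding the cohort analyses report.
    """

    n: int = 100
    seed: int = 0
    k: int = 7
    confounder_effects: dict = field(default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS))
    ordinal_effects: dict = field(
        default_factory=lambda: {
            "gram_neg": "null",
            "gram_pos": "null",
            "pathogenic": "decreasing_step",
        }
    )
    effect_amplitude: float = 2.0
    occupancy: tuple = DEFAULT_OCCUPANCY
    #: latent-normal correlation among the three ordinal predictors
    ordinal_correlation: float = 0.3
    # covariate distribution knobs (cohort-plausible defaults)
    weight_mean: float = 780.0
    weight_sd: float = 180.0
    weight_range: tuple = (400.0, 1000.0)
    p_sga: float = 0.2
    p_male: float = 0.5
    p_multiples: float = 0.3
    steroid_rate: float = 4.0
    antibiotic_rate: float = 10.0

    def __post_init__(self):
        if self.n < 30:
            raise ValueError("need n >= 30 subjects")
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (self.k,) or np.any(occ <= 0) or abs(occ.sum() - 1.0) > 1e-8:
            raise ValueError(f"occupancy must be {self.k} positive probabilities summing to 1")
        if not -0.99 < self.ordinal_correlation < 0.99:
            raise ValueError("ordinal_correlation must be in (-0.99, 0.99)")


@dataclass(frozen=True)
class GroundTruth:
    """True data-generating quantities stored alongside a synthetic table."""

    effects: dict        # ordinal term name -> centered level coefficients
    coefficients: dict   # intercept + parametric effects (link scale)
    eta: np.ndarray      # true linear predictor per subject
    mu: np.ndarray       # true mean per subject


def _ordinal_levels(rng, n, occupancy, n_terms, correlation):
    """Correlated ordinal levels via a Gaussian copula over the occupancy."""
    occ = np.asarray(occupancy, dtype=float)
    R = np.full((n_terms, n_terms), correlation)
    np.fill_diagonal(R, 1.0)
    z = rng.multivariate_normal(np.zeros(n_terms), R, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    cuts = np.cumsum(occ)[:-1]
    return np.searchsorted(cuts, u) + 1  # n x n_terms, levels 1..k


def generate_bpd_like(config: BpdLikeConfig) -> tuple:
    """Draw one synthetic BPD-like cohort; returns ``(table, GroundTruth)``."""
    rng = np.random.default_rng(config.seed)
    n, k = config.n, config.k

    lo = (config.weight_range[0] - config.weight_mean) / config.weight_sd
    hi = (config.weight_range[1] - config.weight_mean) / config.weight_sd
    weight = stats.truncnorm.rvs(
        lo, hi, loc=config.weight_mean, scale=config.weight_sd, size=n, random_state=rng
    )
    sga = rng.binomial(1, config.p_sga, n)
    sex = rng.binomial(1, config.p_male, n)
    multiples = rng.binomial(1, config.p_multiples, n)
    steroids = rng.poisson(config.steroid_rate, n)
    antibiotics = rng.poisson(config.antibiotic_rate, n)

    levels = _ordinal_levels(rng, n, config.occupancy, len(ORDINAL_COLUMNS),
                             config.ordinal_correlation)

    ce = config.confounder_effects
    eta = np.full(n, ce["(Intercept)"], dtype=float)
    covariates = {
        "weight_g": weight, "sga": sga, "sex_male": sex, "multiples": multiples,
        "steroid_days": steroids, "antibiotic_days": antibiotics,
    }
    for name, v in covariates.items():
        eta += ce[name] * v

    effects = {}
    for j, name in enumerate(ORDINAL_COLUMNS):
        shape = config.ordinal_effects.get(name, "null")
        vec = effect_vector(shape, k, config.effect_amplitude)
        effects[name] = vec
        eta += vec[levels[:, j] - 1]

    mu = expit(eta)
    y = rng.binomial(1, mu)

    table = pd.DataFrame({"bpd": y, **covariates})
    for j, name in enumerate(ORDINAL_COLUMNS):
        table[name] = levels[:, j]

    expected = n * np.asarray(config.occupancy)
    if expected.min() < 0.5:
        import logging
        logging.getLogger(__name__).warning(
            "occupancy profile gives an expected count below 0.5 at some level "
            "(min %.2f); that level will often be unobserved", expected.min()
        )
    truth = GroundTruth(effects=effects, coefficients=dict(ce), eta=eta, mu=mu)
    return table, truth


def generate_ordinal_glm(
    n: int,
    k: int,
    family: str = "gaussian",
    effect="linear",
    seed: int = 0,
    occupancy=None,
    intercept: float = 0.0,
    noise_sd: float = 1.0,
    amplitude: float = 2.0,
) -> tuple:
    """Generic single-ordinal-predictor test-bed with exact ground truth.

    Columns ``y`` and ``x`` (levels 1..k, uniform occupancy unless given).
    ``effect`` is a shape name or a length-k vector; the stored ground
    truth holds the centered vector actually used.
    """
    rng = np.random.default_rng(seed)
    occ = np.full(k, 1.0 / k) if occupancy is None else np.asarray(occupancy, dtype=float)
    if occ.shape != (k,) or abs(occ.sum() - 1.0) > 1e-8:
        raise ValueError(f"occupancy must be {k} probabilities summing to 1")
    x = rng.choice(np.arange(1, k + 1), size=n, p=occ)
    vec = effect_vector(effect, k, amplitude)
    eta = intercept + vec[x - 1]
    fam = str(family).lower()
    if fam == "gaussian":
        mu = eta
        y = eta + rng.normal(0.0, noise_sd, n)
    elif fam == "binomial":
        mu = expit(eta)
        y = rng.binomial(1, mu)
    elif fam == "poisson":
        mu = np.exp(eta)
        y = rng.poisson(mu)
    else:
        raise ValueError(f"unsupported family {family!r}")
    table = pd.DataFrame({"y": y, "x": x})
    truth = GroundTruth(
        effects={"x": vec}, coefficients={"(Intercept)": intercept}, eta=eta, mu=mu
    )
    return table, truth
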