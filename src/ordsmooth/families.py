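"""Exponential families with canonical links for the penalized fitter.

Only the canonical pairs are supported: binomial/logit, gaussian/identity,
poisson/log.  Each family supplies what penalized IRLS and the Laplace
REML criterion need: mean/link maps, variance function, deviance and
log-likelihood, and a starting value for the mean.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

__all__ = ["Family", "Binomial", "Gaussian", "Poisson", "get_family"]

_MU_EPS = 1e-10


class Family:
    """Base class; subclasses implement the canonical-link quartet."""

    name: str = ""
    #: dispersion fixed at 1 (binomial, poisson) or estimated (gaussian)
    fixed_scale: bool = True

    def link(self, mu: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def inverse_link(self, eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def variance(self, mu: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def deviance(self, y: np.ndarray, mu: np.ndarray) -> float:
        raise NotImplementedError

    def loglik(self, y: np.ndarray, mu: np.ndarray, scale: float = 1.0) -> float:
        raise NotImplementedError

    def initialize(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def validate(self, y: np.ndarray) -> None:
        if not np.all(np.isfinite(y)):
            raise ValueError(f"{self.name} response contains non-finite values")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<family {self.name}>"


class Binomial(Family):
    """Bernoulli response with logit link (dispersion fixed at 1)."""

    name = "binomial"

    def link(self, mu):
        mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        return np.log(mu / (1 - mu))

    def inverse_link(self, eta):
        return expit(eta)

    def variance(self, mu):
        return np.clip(mu * (1 - mu), _MU_EPS, None)

    def deviance(self, y, mu):
        mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return float(2.0 * np.sum(t1 + t2))

    def loglik(self, y, mu, scale=1.0):
        mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    def initialize(self, y):
        # keeps the starting mean strictly inside (0, 1)
        return (y + 0.5) / 2.0

    def validate(self, y):
        super().validate(y)
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("binomial response must be coded 0/1")


class Gaussian(Family):
    """Gaussian response with identity link; dispersion estimated."""

    name = "gaussian"
    fixed_scale = False

    def link(self, mu):
        return np.asarray(mu, dtype=float)

    def inverse_link(self, eta):
        return np.asarray(eta, dtype=float)

    def variance(self, mu):
        return np.ones_like(np.asarray(mu, dtype=float))

    def deviance(self, y, mu):
        r = y - mu
        return float(r @ r)

    def loglik(self, y, mu, scale=1.0):
        n = y.shape[0]
        rss = self.deviance(y, mu)
        return float(-0.5 * rss / scale - 0.5 * n * np.log(2 * np.pi * scale))

    def initialize(self, y):
        return np.asarray(y, dtype=float)


class Poisson(Family):
    """Count response with log link (dispersion fixed at 1)."""

    name = "poisson"

    def link(self, mu):
        return np.log(np.clip(mu, _MU_EPS, None))

    def inverse_link(self, eta):
        return np.exp(np.clip(eta, -700, 700))

    def variance(self, mu):
        return np.clip(mu, _MU_EPS, None)

    def deviance(self, y, mu):
        mu = np.clip(mu, _MU_EPS, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(t - (y - mu)))

    def loglik(self, y, mu, scale=1.0):
        mu = np.clip(mu, _MU_EPS, None)
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))

    def initialize(self, y):
        return np.asarray(y, dtype=float) + 0.5

    def validate(self, y):
        super().validate(y)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson response must be nonnegative integers")


_FAMILIES = {"binomial": Binomial, "gaussian": Gaussian, "poisson": Poisson}


def get_family(family: "str | Family") -> Family:
    """Resolve a family name or instance to a :class:`Family`."""
    if isinstance(family, Family):
        return family
    try:
        return _FAMILIES[str(family).lower()]()
    except KeyError:
        raise ValueError(
            f"unsupported family {family!r}; choose from {sorted(_FAMILIES)} "
            "(canonical links only)"
        ) from None
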