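"""Null-simulation audit of smooth-term p-values.

The audit asks whether the Wald-type test of a penalized ordinal term is
calibrated: fit the confounder-only model (the tested term removed), so
the null hypothesis of no ordinal effect is true *by construction* — the
fitted means do not depend on the tested column given the confounders.
Then repeatedly (i) draw new responses from those fitted means at the
original covariate values, (ii) refit with the ordinal smooth added and
the smoothing parameter re-estimated, (iii) store the term's p-value.
Under a calibrated test the collected p-values are uniform; the empirical
rejection rates, a Kolmogorov-Smirnov distance to uniformity and a
QQ-table against the uniform quantiles summarize the outcome.

Randomness discipline: one master seed spawns an independent child stream
per replicate, so individual replicates can be reproduced in isolation and
the full run is bit-identical under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import OrdinalTerm
from .fit import GamFit, fit_gam
from .inference import smooth_test
from .model import ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["CalibrationConfig", "CalibrationResult", "fit_null_model", "run_calibration", "qq_uniform"]


@dataclass(frozen=True)
class CalibrationConfig:
    """Settings of one null-simulation run.

    ``base_spec`` is the confounder model (must not contain the tested
    term); ``test_term`` is the ordinal smooth added in each replicate.
    """

    base_spec: ModelSpec
    test_term: OrdinalTerm
    n_rep: int = 1000
    seed: int = 0
    method: str = "REML"
    alpha_grid: tuple = (0.01, 0.05, 0.1)

    def __post_init__(self):
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if any(not 0 < a < 1 for a in self.alpha_grid):
            raise ValueError("alpha_grid entries must lie in (0, 1)")
        names = set(self.base_spec.parametric_terms) | {
            t.name for t in self.base_spec.ordinal_terms
        }
        if self.test_term.name in names:
            raise ValueError(
                f"test term {self.test_term.name!r} must not appear in base_spec"
            )


@dataclass
class CalibrationResult:
    """Collected null p-values and calibration summaries."""

    p_values: np.ndarray
    rejection_rates: dict      # alpha -> empirical rate
    ks_distance: float
    n_failed: int
    n_rep: int
    alpha_grid: tuple

    def __post_init__(self):
        assert self.n_failed + len(self.p_values) == self.n_rep


def fit_null_model(base_spec: ModelSpec, data: pd.DataFrame, method: str = "REML") -> GamFit:
    """Fit the confounder-only model whose fitted means drive the resampling."""
    return fit_gam(base_spec, data, method=method)


def run_calibration(config: CalibrationConfig, data: pd.DataFrame) -> CalibrationResult:
    """Run the null simulation; returns collected p-values and summaries.

    Responses are redrawn at the original covariate values (no covariate
    resampling).  Replicates whose refit does not converge are excluded
    and counted; more than 20% failures aborts with an error since the
    configuration is then too unstable to audit.
    """
    spec = config.base_spec
    used = (
        [spec.response]
        + list(spec.parametric_terms)
        + [t.name for t in spec.ordinal_terms]
        + [config.test_term.name]
    )
    missing = [c for c in used if c not in data.columns]
    if missing:
        raise KeyError(f"column(s) {missing} not found in the data")
    complete = data.loc[~data[used].isna().any(axis=1), used].reset_index(drop=True)

    null_fit = fit_null_model(spec, complete, method=config.method)
    mu0 = null_fit.mu
    family = null_fit.design.family
    full_spec = spec.add_term(config.test_term)

    children = np.random.SeedSequence(config.seed).spawn(config.n_rep)
    p_values = []
    n_failed = 0
    sim = complete.copy()
    for r in range(config.n_rep):
        rng = np.random.default_rng(children[r])
        if family.name == "binomial":
            y_star = rng.binomial(1, mu0)
        elif family.name == "poisson":
            y_star = rng.poisson(mu0)
        else:
            y_star = mu0 + rng.normal(0.0, np.sqrt(null_fit.scale), mu0.shape[0])
        sim[spec.response] = y_star
        try:
            fit = fit_gam(full_spec, sim, method=config.method)
            if not fit.converged:
                raise RuntimeError("refit did not converge")
            p = float(smooth_test(fit, config.test_term.name)["p-value"])
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.warning("replicate %d excluded: %s", r, exc)
            n_failed += 1
            continue
        p_values.append(p)

    if n_failed > 0.2 * config.n_rep:
        raise RuntimeError(
            f"{n_failed}/{config.n_rep} replicates failed to converge; "
            "the configuration is too unstable for a calibration audit"
        )
    p_values = np.asarray(p_values)
    rates = {a: float(np.mean(p_values <= a)) for a in config.alpha_grid}
    ks = float(stats.kstest(p_values, "uniform").statistic) if len(p_values) else np.nan
    return CalibrationResult(
        p_values=p_values, rejection_rates=rates, ks_distance=ks,
        n_failed=n_failed, n_rep=config.n_rep, alpha_grid=tuple(config.alpha_grid),
    )


def qq_uniform(p_values: np.ndarray, upper: float = 0.1) -> pd.DataFrame:
    """Plot-ready QQ table of empirical vs uniform p-value quantiles.

    Rows are restricted to the ``[0, upper]`` corner on both axes — the
    region that matters for testing at conventional levels.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("p_values must be nonempty")
    theo = (np.arange(1, p.size + 1) - 0.5) / p.size
    keep = (theo <= upper) & (p <= upper)
    return pd.DataFrame({"theoretical": theo[keep], "empirical": p[keep]})
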