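"""Penalized GLM fitting and REML/ML smoothing-parameter selection.

For fixed smoothing parameters ``lambda`` the coefficients minimize the
penalized deviance ``D(beta) + sum_j lambda_j beta' S_j beta`` via penalized
iteratively reweighted least squares (PIRLS).  The smoothing parameters are
then chosen by minimizing the Laplace-approximate negative restricted
marginal likelihood (REML; exact for gaussian/identity)

    V(lambda) = -l(beta_hat) + beta_hat' S_lam beta_hat / (2 phi)
                + 1/2 log|H/phi| - 1/2 log|S_lam/phi|_+
                - M_p/2 log(2 pi),

where ``H = X'WX + S_lam`` is the penalized Hessian, ``|.|_+`` the product
of the positive eigenvalues over the penalized subspace, and ``M_p`` the
dimension of the total penalty null space (intercept, parametric columns,
and one direction per order-2 term).  The ML variant integrates only over
the penalized subspace, replacing ``log|H|`` by the log-determinant of the
Schur complement of the unpenalized block and dropping the ``M_p`` term.

Smoothing parameters are searched on the log scale over the box
``log lambda in [-12, 12]^J`` with a grid seed followed by Nelder-Mead
(dense for one or two terms, since the REML profile can hold a boundary
basin competing with an interior one); a solution at the box edge is
reported with a warning (the
term is effectively unpenalized, or shrunk to its penalty null space).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, qr

from .families import Family
from .model import DesignBundle, ModelSpec, build_design

logger = logging.getLogger(__name__)

__all__ = ["pirls", "reml_criterion", "optimize_smoothing", "fit_gam", "GamFit", "PirlsResult"]

LOG_LAMBDA_BOX = (-12.0, 12.0)
_BOUNDARY_MARGIN = 0.5
_GRID_POINTS = (-12.0, -6.0, 0.0, 6.0, 12.0)
_MAX_ITER = 200
_MAX_HALVINGS = 30
_DEV_RTOL = 1e-9
_COEF_TOL = 1e-8


@dataclass
class PirlsResult:
    beta: np.ndarray
    w: np.ndarray          # final working weights
    mu: np.ndarray
    eta: np.ndarray
    deviance: float
    penalized_deviance: float
    converged: bool
    iterations: int


@dataclass
class GamFit:
    """Fitted penalized GLM with ordinal smooth terms.

    Coefficients live on the link scale in the constrained parameterization;
    use :func:`ordsmooth.inference.coef_curve` to map an ordinal term back
    to its k level coefficients.  ``Vb`` is the Bayesian posterior
    covariance ``phi * (X'WX + S_lam)^-1`` underlying the confidence
    intervals and smooth tests.
    """

    spec: ModelSpec
    design: DesignBundle
    beta: np.ndarray
    lambda_: np.ndarray
    Vb: np.ndarray
    edf: dict            # per ordinal term
    edf_total: float
    edf_alt: dict        # per-term tr(2F - FF) block sums (alternative edf)
    deviance: float
    null_deviance: float
    scale: float
    method: str
    criterion: float
    converged: bool
    iterations: tuple    # (outer criterion evaluations, final inner iterations)
    w: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)
    eta: np.ndarray = field(repr=False, default=None)
    edf_diag: np.ndarray = field(repr=False, default=None)

    @property
    def coef_names(self):
        return self.design.column_names


def _working_quantities(y: np.ndarray, eta: np.ndarray, family: Family):
    """Canonical-link working weights and response: w = V(mu), z = eta + (y-mu)/w."""
    mu = family.inverse_link(eta)
    w = np.clip(family.variance(mu), 1e-10, None)
    z = eta + (y - mu) / w
    return mu, w, z


def pirls(
    design: DesignBundle,
    lam: np.ndarray,
    beta0: "np.ndarray | None" = None,
    max_iter: int = _MAX_ITER,
) -> PirlsResult:
    """Penalized IRLS for fixed smoothing parameters.

    Minimizes ``deviance(beta) + sum_j lambda_j beta' S_j beta`` with
    step-halving whenever a Newton step increases the penalized deviance.
    Non-convergence is reported through ``converged=False``, never silently.
    """
    X, y, family = design.X, design.y, design.family
    lam = np.asarray(lam, dtype=float)
    if lam.shape[0] != len(design.penalties):
        raise ValueError(f"expected {len(design.penalties)} smoothing parameters, got {lam.shape[0]}")
    if np.any(lam <= 0):
        raise ValueError("smoothing parameters must be strictly positive")
    Slam = design.penalty_total(lam)

    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float)
        eta = X @ beta
        mu = family.inverse_link(eta)
    else:
        beta = None
        mu = family.initialize(y)
        eta = family.link(mu)

    pen = 0.0 if beta is None else float(beta @ Slam @ beta)
    dev_pen = family.deviance(y, mu) + pen
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu, w, z = _working_quantities(y, eta, family)
        XtW = X.T * w
        A = XtW @ X + Slam
        rhs = XtW @ z
        try:
            c, low = cho_factor((A + A.T) / 2.0)
            beta_new = cho_solve((c, low), rhs)
        except np.linalg.LinAlgError:
            logger.warning("penalized Hessian not positive definite during PIRLS")
            break

        step = beta_new if beta is None else beta_new - beta
        base = np.zeros_like(beta_new) if beta is None else beta
        frac = 1.0
        for _ in range(_MAX_HALVINGS):
            cand = base + frac * step
            eta_c = X @ cand
            mu_c = family.inverse_link(eta_c)
            dev_c = design.family.deviance(y, mu_c) + float(cand @ Slam @ cand)
            if np.isfinite(dev_c) and dev_c <= dev_pen + 1e-12 * (abs(dev_pen) + 1.0):
                break
            frac *= 0.5
        else:
            # no decrease found: accept the smallest step and let the
            # convergence check decide
            cand = base + frac * step
            eta_c = X @ cand
            mu_c = family.inverse_link(eta_c)
            dev_c = design.family.deviance(y, mu_c) + float(cand @ Slam @ cand)

        coef_change = np.max(np.abs(cand - base)) if beta is not None else np.inf
        dev_change = abs(dev_pen - dev_c)
        beta, eta, mu = cand, eta_c, mu_c
        old_dev_pen, dev_pen = dev_pen, dev_c
        if beta0 is None and it == 1:
            continue  # first step from the family initialization is always large
        if dev_change <= _DEV_RTOL * (abs(old_dev_pen) + 0.1) and coef_change <= _COEF_TOL * (
            1.0 + np.max(np.abs(beta))
        ):
            converged = True
            break

    mu, w, _ = _working_quantities(y, eta, family)
    dev = family.deviance(y, mu)
    if not converged:
        logger.warning("PIRLS did not converge in %d iterations", it)
    return PirlsResult(
        beta=beta, w=w, mu=mu, eta=eta, deviance=dev,
        penalized_deviance=dev_pen, converged=converged, iterations=it,
    )


def _null_range_bases(design: DesignBundle):
    """Orthonormal bases of the total-penalty null space and its complement.

    The null space holds the intercept, parametric columns and each term's
    penalty null directions (order-2 terms contribute the linear-in-level
    direction).  Cached on the design (lambda-independent).
    """
    cached = getattr(design, "_nr_bases", None)
    if cached is not None:
        return cached
    p = design.p
    cols = []
    n_unpen = p - design.n_smooth_cols
    for j in range(n_unpen):
        e = np.zeros(p)
        e[j] = 1.0
        cols.append(e)
    for name, sl, Sj, block in design.penalties:
        if block.nullspace_dim > 0:
            evals, evecs = np.linalg.eigh(Sj)
            for idx in range(block.nullspace_dim):
                v = np.zeros(p)
                v[sl] = evecs[:, idx]
                cols.append(v)
    N = np.column_stack(cols)
    Q, _ = qr(N, mode="full")
    M_p = N.shape[1]
    bases = (Q[:, :M_p], Q[:, M_p:])
    design._nr_bases = bases
    return bases


def _log_det_S_plus(design: DesignBundle, log_lambda: np.ndarray) -> float:
    """log of the product of positive eigenvalues of sum_j lambda_j S_j."""
    total = 0.0
    for (name, sl, Sj, block), ll in zip(design.penalties, log_lambda):
        total += block.rank * ll + block.log_det_plus
    return total


def reml_criterion(
    design: DesignBundle,
    log_lambda: np.ndarray,
    method: str = "REML",
    scale: "float | None" = None,
    beta0: "np.ndarray | None" = None,
    _return_fit: bool = False,
):
    """Negative Laplace-approximate (restricted) marginal likelihood.

    For the gaussian family the criterion is exact and, with ``scale``
    supplied, matches the closed-form restricted log-likelihood of the
    equivalent linear mixed model; with ``scale=None`` the gaussian
    dispersion is profiled out analytically as
    ``(RSS + penalty)/(n - M_p)``.  Binomial and poisson use ``phi = 1``.
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be 'REML' or 'ML', got {method!r}")
    log_lambda = np.atleast_1d(np.asarray(log_lambda, dtype=float))
    lam = np.exp(log_lambda)
    fit = pirls(design, lam, beta0=beta0)
    if not fit.converged:
        logger.warning("inner PIRLS unconverged at log(lambda)=%s", np.round(log_lambda, 3))

    X, y, family = design.X, design.y, design.family
    p = design.p
    M_p = design.null_space_dim
    Slam = design.penalty_total(lam)
    pen = float(fit.beta @ Slam @ fit.beta)
    XtW = X.T * fit.w
    A = XtW @ X + Slam
    A = (A + A.T) / 2.0
    try:
        c, low = cho_factor(A)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "penalized Hessian is indefinite; the design may be rank deficient "
            "- consider a stronger smoothing-parameter floor"
        ) from None
    log_det_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    log_det_S = _log_det_S_plus(design, log_lambda)

    if family.fixed_scale:
        phi = 1.0
    elif scale is not None:
        phi = float(scale)
    else:
        rss = fit.deviance
        phi = (rss + pen) / (design.n - M_p)

    neg_ll = -family.loglik(y, fit.mu, phi)
    if method == "REML":
        value = (
            neg_ll
            + pen / (2.0 * phi)
            + 0.5 * (log_det_A - p * np.log(phi))
            - 0.5 * (log_det_S - (p - M_p) * np.log(phi))
            - 0.5 * M_p * np.log(2.0 * np.pi)
        )
    else:
        N, R = _null_range_bases(design)
        if R.shape[1] == 0:
            value = neg_ll
        else:
            Ann = N.T @ A @ N
            Anr = N.T @ A @ R
            Arr = R.T @ A @ R
            schur = Arr - Anr.T @ np.linalg.solve(Ann, Anr)
            sign, log_det_schur = np.linalg.slogdet((schur + schur.T) / 2.0)
            if sign <= 0:
                raise np.linalg.LinAlgError("ML Schur complement not positive definite")
            value = neg_ll + pen / (2.0 * phi) + 0.5 * log_det_schur - 0.5 * log_det_S
    value = float(value)
    if _return_fit:
        return value, fit
    return value


def optimize_smoothing(
    design: DesignBundle,
    method: str = "REML",
    scale: "float | None" = None,
) -> tuple:
    """Select smoothing parameters by minimizing the (RE)ML criterion.

    A grid over ``log lambda in [-12, 12]`` (step 1 for one term, step 3
    for two, a 5-point product for three, coordinate sweeps beyond) seeds a
    Nelder-Mead search; convergence at criterion change < 1e-7.
    Returns ``(lambda_hat, criterion_value, n_evaluations)``.
    """
    J = len(design.penalties)
    if J == 0:
        return np.empty(0), np.nan, 0

    state = {"beta": None, "evals": 0}

    def objective(ll):
        ll = np.clip(ll, *LOG_LAMBDA_BOX)
        state["evals"] += 1
        try:
            val, fit = reml_criterion(
                design, ll, method=method, scale=scale,
                beta0=state["beta"], _return_fit=True,
            )
        except np.linalg.LinAlgError:
            return 1e12
        state["beta"] = fit.beta
        return val

    # Grid seed before the local search: the REML profile can be multimodal
    # in log lambda (a boundary basin competing with an interior one), so a
    # sparse seed risks handing Nelder-Mead the wrong basin.  Use a dense
    # grid when one or two terms make that cheap, the full 5-point product
    # at three terms, and coordinate sweeps beyond.
    lo, hi = LOG_LAMBDA_BOX
    if J == 1:
        grid_1d: tuple = tuple(np.arange(lo, hi + 0.5, 1.0))
    elif J == 2:
        grid_1d = tuple(np.arange(lo, hi + 0.5, 3.0))
    else:
        grid_1d = _GRID_POINTS
    if len(grid_1d) ** J <= 150:
        candidates = list(itertools.product(grid_1d, repeat=J))
    else:
        candidates = [(0.0,) * J]
        for j in range(J):
            for g in grid_1d:
                pt = [0.0] * J
                pt[j] = g
                candidates.append(tuple(pt))
    best_ll, best_val = None, np.inf
    for cand in candidates:
        val = objective(np.asarray(cand, dtype=float))
        if val < best_val:
            best_val, best_ll = val, np.asarray(cand, dtype=float)

    res = optimize.minimize(
        objective, best_ll, method="Nelder-Mead",
        options={"fatol": 1e-7, "xatol": 1e-4, "maxiter": 250 * J,
                 "initial_simplex": _initial_simplex(best_ll)},
    )
    ll_hat = np.clip(res.x, *LOG_LAMBDA_BOX) if res.fun <= best_val else best_ll
    crit = min(float(res.fun), best_val)
    at_edge = np.abs(ll_hat) >= LOG_LAMBDA_BOX[1] - _BOUNDARY_MARGIN
    for j in np.flatnonzero(at_edge):
        name = design.penalties[j][0]
        side = "upper" if ll_hat[j] > 0 else "lower"
        logger.warning(
            "smoothing parameter for %r at the %s search boundary "
            "(log lambda = %.2f): term is effectively %s", name, side, ll_hat[j],
            "shrunk to its penalty null space" if ll_hat[j] > 0 else "unpenalized",
        )
    return np.exp(ll_hat), crit, state["evals"]


def _initial_simplex(x0: np.ndarray) -> np.ndarray:
    J = x0.shape[0]
    simplex = np.tile(x0, (J + 1, 1))
    for j in range(J):
        simplex[j + 1, j] = np.clip(simplex[j + 1, j] + 1.0, *LOG_LAMBDA_BOX)
        if simplex[j + 1, j] == simplex[0, j]:
            simplex[j + 1, j] -= 1.0
    return simplex


def _null_deviance(design: DesignBundle) -> float:
    """Deviance of the intercept-only unpenalized fit (same family)."""
    y, family = design.y, design.family
    ones = np.ones((design.n, 1))
    null_design = DesignBundle(
        X=ones, y=y, family=family, penalties=[], term_map={},
        column_names=["(Intercept)"], blocks={},
    )
    fit = pirls(null_design, np.empty(0))
    return fit.deviance


def fit_gam(
    spec: ModelSpec,
    data: pd.DataFrame,
    method: str = "REML",
    lambda_: "np.ndarray | None" = None,
    scale: "float | None" = None,
) -> GamFit:
    """Fit the penalized GLM: design assembly, smoothing selection, PIRLS.

    ``lambda_`` fixes the smoothing parameters (one per ordinal term) and
    skips (RE)ML selection — useful for exploring the unpenalized
    (``lambda -> 0``) and fully shrunk (``lambda -> infinity``) limits.
    """
    design = build_design(spec, data)
    J = len(design.penalties)
    n_evals = 0
    if lambda_ is not None:
        lam = np.atleast_1d(np.asarray(lambda_, dtype=float))
        if lam.shape[0] == 1 and J > 1:
            lam = np.repeat(lam, J)
        crit = reml_criterion(design, np.log(lam), method=method, scale=scale) if J else np.nan
    elif J:
        lam, crit, n_evals = optimize_smoothing(design, method=method, scale=scale)
    else:
        lam, crit = np.empty(0), np.nan

    fit = pirls(design, lam)
    X = design.X
    Slam = design.penalty_total(lam)
    XtW = X.T * fit.w
    XtWX = XtW @ X
    A = (XtWX + Slam + XtWX.T + Slam.T) / 2.0
    c, low = cho_factor(A)
    Ainv = cho_solve((c, low), np.eye(design.p))
    F = Ainv @ XtWX
    edf_diag = np.diag(F).copy()
    edf_total = float(edf_diag.sum())
    FF_diag = np.einsum("ij,ji->i", F, F)
    edf, edf_alt = {}, {}
    for name, sl, Sj, block in design.penalties:
        edf[name] = float(edf_diag[sl].sum())
        edf_alt[name] = float(2.0 * edf_diag[sl].sum() - FF_diag[sl].sum())

    if design.family.fixed_scale:
        phi = 1.0
    elif scale is not None:
        phi = float(scale)
    else:
        pen = float(fit.beta @ Slam @ fit.beta)
        phi = (fit.deviance + pen) / max(design.n - edf_total, 1.0)

    Vb = phi * Ainv
    Vb = (Vb + Vb.T) / 2.0

    return GamFit(
        spec=spec, design=design, beta=fit.beta, lambda_=lam, Vb=Vb,
        edf=edf, edf_total=edf_total, edf_alt=edf_alt,
        deviance=fit.deviance, null_deviance=_null_deviance(design),
        scale=phi, method=method.upper(), criterion=float(crit) if np.size(crit) else np.nan,
        converged=fit.converged, iterations=(n_evals, fit.iterations),
        w=fit.w, mu=fit.mu, eta=fit.eta, edf_diag=edf_diag,
    )
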