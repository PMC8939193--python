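"""Ordinal dummy basis and quadratic difference penalties.

An ordinal predictor with levels ``1..k`` enters the model through one
indicator (dummy) basis function per level.  Smoothness across adjacent
levels is imposed by a quadratic penalty on first- or second-order
differences of the level coefficients:

* order 1: ``J(beta) = sum_l (beta_l - beta_{l-1})^2`` — shrinks the effect
  toward a constant over levels;
* order 2: ``J(beta) = sum_l (beta_{l+1} - 2 beta_l + beta_{l-1})^2`` —
  shrinks toward a straight line in the level index.

Because the model carries an intercept, each dummy block is made
identifiable by a sum-to-zero constraint over the k level coefficients,
absorbed by reparameterizing onto the orthogonal complement of the ones
vector.  After that constraint the penalty null space has dimension 0
(order 1) or 1 (order 2) — the bookkeeping that drives both the effective
degrees of freedom and the boundary behaviour of smooth-term tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinalTerm",
    "BasisBlock",
    "indicator_matrix",
    "difference_matrix",
    "penalty_matrix",
    "penalty_value",
    "constrain",
]

#: eigenvalues above this (relative) threshold count toward the penalty rank
_RANK_RTOL = 1e-8
#: eigenvalues below -1e-10 fail the PSD check; anything in (-1e-10, 0) is clipped
_PSD_TOL = 1e-10


@dataclass(frozen=True)
class OrdinalTerm:
    """Declaration of one penalized ordinal smooth term.

    Parameters
    ----------
    name
        Column name of the predictor in the subject table.
    k
        Number of ordered levels, coded ``1..k``.  Must be >= 3; a 2-level
        factor has no interior structure to smooth — include it as a
        parametric binary term instead.
    order
        Difference-penalty order, 1 or 2.
    """

    name: str
    k: int
    order: int = 2

    def __post_init__(self) -> None:
        if not isinstance(self.k, (int, np.integer)) or self.k < 3:
            raise ValueError(
                f"ordinal term {self.name!r}: k must be an integer >= 3, got {self.k!r}; "
                "a 2-level ordinal factor carries no ordinal structure — "
                "use a parametric binary term instead"
            )
        if self.order not in (1, 2):
            raise ValueError(
                f"ordinal term {self.name!r}: penalty order must be 1 or 2, got {self.order!r}"
            )


@dataclass
class BasisBlock:
    """Constrained design/penalty block for one ordinal term.

    Attributes
    ----------
    term
        The :class:`OrdinalTerm` this block encodes.
    Z
        n x (k-1) constrained indicator matrix (raw indicators mapped onto
        the sum-to-zero subspace).
    S
        (k-1) x (k-1) constrained penalty matrix, symmetric PSD.
    transform
        k x (k-1) matrix ``C`` mapping constrained coefficients ``theta`` to
        full level coefficients ``beta = C theta`` (which sum to zero).
    nullspace_dim
        Dimension of the penalty null space after the constraint:
        0 for order 1, 1 for order 2.
    """

    term: OrdinalTerm
    Z: np.ndarray
    S: np.ndarray
    transform: np.ndarray
    nullspace_dim: int
    #: log product of the positive eigenvalues of S (cached for REML)
    log_det_plus: float = field(default=0.0)
    #: rank of S
    rank: int = field(default=0)


def indicator_matrix(x: np.ndarray, k: int) -> np.ndarray:
    """One-hot indicator matrix of an ordinal level vector.

    Row i has a single 1 in column ``x_i`` (1-based levels).  Levels absent
    from ``x`` are permitted — the corresponding column is all zero and a
    warning is logged, since such a level's coefficient is identified only
    through the penalty.
    """
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("level vector must be one-dimensional")
    xr = np.round(x.astype(float))
    bad = ~np.isfinite(x.astype(float)) | (np.abs(x.astype(float) - xr) > 0) \
        | (xr < 1) | (xr > k)
    if bad.any():
        rows = np.flatnonzero(bad)[:5]
        raise ValueError(
            f"ordinal levels must be integers in [1, {k}]; offending row(s) "
            f"{rows.tolist()} with value(s) {np.asarray(x)[rows].tolist()}"
        )
    xi = xr.astype(int)
    B = np.zeros((x.shape[0], k))
    B[np.arange(x.shape[0]), xi - 1] = 1.0
    observed = np.unique(xi)
    missing = sorted(set(range(1, k + 1)) - set(observed.tolist()))
    if missing:
        logger.warning(
            "ordinal level(s) %s unobserved in the data; their coefficients "
            "are identified only through the smoothing penalty", missing
        )
    return B


def difference_matrix(k: int, order: int) -> np.ndarray:
    """Order-m difference matrix ``D`` of shape (k-m) x k with ``D beta``
    the vector of adjacent order-m differences."""
    if order not in (1, 2):
        raise ValueError(f"penalty order must be 1 or 2, got {order!r}")
    if k <= order:
        raise ValueError(f"need k >= order + 1 levels, got k={k}, order={order}")
    return np.diff(np.eye(k), n=order, axis=0)


def penalty_matrix(k: int, order: int) -> np.ndarray:
    """Penalty matrix ``S = D'D`` so that ``beta' S beta`` equals the sum of
    squared order-m differences; symmetric PSD with rank ``k - order``."""
    D = difference_matrix(k, order)
    return D.T @ D


def penalty_value(beta: np.ndarray, order: int) -> float:
    """Direct evaluation of the difference penalty as an explicit sum.

    Equals ``beta' penalty_matrix(len(beta), order) beta`` up to rounding;
    kept as an independent closed form for testing and readability.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1:
        raise ValueError("beta must be one-dimensional")
    if beta.shape[0] <= order:
        raise ValueError(f"need len(beta) >= order + 1, got {beta.shape[0]}, order={order}")
    d = np.diff(beta, n=order)
    return float(d @ d)


def _sum_to_zero_basis(k: int) -> np.ndarray:
    """Orthonormal k x (k-1) basis of the complement of the ones vector."""
    C = null_space(np.ones((1, k)))
    # null_space is SVD-based; fix column signs for full determinism
    signs = np.sign(C[0, :])
    signs[signs == 0] = 1.0
    return C * signs


def constrain(term: OrdinalTerm, x: np.ndarray) -> BasisBlock:
    """Build the sum-to-zero-constrained basis block for one ordinal term.

    The raw n x k indicator matrix ``B`` and k x k penalty ``S0`` are
    reparameterized with an orthonormal basis ``C`` of the complement of the
    ones vector: ``Z = B C`` and ``S = C' S0 C``.  Full level coefficients
    are recovered as ``beta = C theta`` and automatically sum to zero; the
    span of (intercept, Z) equals the span of (intercept, B).
    """
    B = indicator_matrix(x, term.k)
    C = _sum_to_zero_basis(term.k)
    S0 = penalty_matrix(term.k, term.order)
    S = C.T @ S0 @ C
    S = (S + S.T) / 2.0
    evals = np.linalg.eigvalsh(S)
    if evals.min() < -_PSD_TOL:
        raise np.linalg.LinAlgError(
            f"constrained penalty for {term.name!r} is not PSD (min eigenvalue {evals.min():.3g})"
        )
    evals = np.clip(evals, 0.0, None)
    pos = evals > _RANK_RTOL * evals.max()
    rank = int(pos.sum())
    nullspace_dim = (term.k - 1) - rank
    return BasisBlock(
        term=term,
        Z=B @ C,
        S=S,
        transform=C,
        nullspace_dim=nullspace_dim,
        log_det_plus=float(np.log(evals[pos]).sum()),
        rank=rank,
    )
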