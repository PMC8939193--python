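"""Model specification and design assembly.

A :class:`ModelSpec` declares the additive predictor
``eta = alpha + x'gamma + f_1(o_1) + ... + f_J(o_J)`` with ``mu = h(eta)``:
an intercept, parametric (linear) covariates, and penalized ordinal smooth
terms.  :func:`build_design` turns a spec plus a subject table into a
:class:`DesignBundle`: the full model matrix with the intercept first,
parametric columns next (as supplied, no standardization) and one
sum-to-zero-constrained indicator block per ordinal term, together with the
aligned penalty blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BasisBlock, OrdinalTerm, constrain
from .families import Family, get_family

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "DesignBundle", "build_design"]


@dataclass(frozen=True)
class ModelSpec:
    """Response, family and additive structure of the model.

    Parameters
    ----------
    response
        Name of the response column.
    family
        ``"binomial"``, ``"gaussian"`` or ``"poisson"`` (canonical link).
    parametric_terms
        Column names entering the linear predictor linearly.
    ordinal_terms
        :class:`~ordsmooth.basis.OrdinalTerm` declarations, one per
        penalized ordinal predictor.
    """

    response: str
    family: str = "binomial"
    parametric_terms: tuple = ()
    ordinal_terms: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "parametric_terms", tuple(self.parametric_terms))
        object.__setattr__(self, "ordinal_terms", tuple(self.ordinal_terms))
        get_family(self.family)  # raises on unsupported family
        names = list(self.parametric_terms) + [t.name for t in self.ordinal_terms]
        dups = {n for n in names if names.count(n) > 1}
        if dups:
            raise ValueError(f"duplicate predictor name(s): {sorted(dups)}")
        if self.response in names:
            raise ValueError(f"response {self.response!r} also appears as a predictor")
        for t in self.ordinal_terms:
            if not isinstance(t, OrdinalTerm):
                raise TypeError(f"ordinal_terms entries must be OrdinalTerm, got {type(t)}")

    def drop_term(self, name: str) -> "ModelSpec":
        """Spec with one ordinal term removed (used by the calibration null model)."""
        kept = tuple(t for t in self.ordinal_terms if t.name != name)
        if len(kept) == len(self.ordinal_terms):
            raise KeyError(f"no ordinal term named {name!r}")
        return ModelSpec(self.response, self.family, self.parametric_terms, kept)

    def add_term(self, term: OrdinalTerm) -> "ModelSpec":
        return ModelSpec(
            self.response, self.family, self.parametric_terms,
            self.ordinal_terms + (term,),
        )


@dataclass
class DesignBundle:
    """Assembled model matrix and aligned penalty blocks.

    ``X`` holds intercept | parametric columns | constrained ordinal blocks.
    ``penalties`` maps each ordinal term to its column slice and constrained
    penalty matrix; ``term_map`` locates every term's columns by name.
    """

    X: np.ndarray
    y: np.ndarray
    family: Family
    penalties: list  # [(name, slice, S_constrained, BasisBlock)]
    term_map: dict  # name -> slice (parametric names map to 1-col slices)
    column_names: list
    blocks: dict  # ordinal term name -> BasisBlock
    n_dropped: int = 0
    spec: "ModelSpec | None" = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_smooth_cols(self) -> int:
        return sum(s.stop - s.start for _, s, _, _ in self.penalties)

    @property
    def total_penalty_rank(self) -> int:
        return sum(b.rank for b in self.blocks.values())

    @property
    def null_space_dim(self) -> int:
        """Dimension M_p of the total penalty null space (unpenalized
        columns plus per-term penalty null spaces)."""
        return self.p - self.total_penalty_rank

    def penalty_total(self, lam: np.ndarray) -> np.ndarray:
        """Block-diagonal p x p penalty  sum_j lambda_j S_j (zero elsewhere)."""
        lam = np.asarray(lam, dtype=float)
        S = np.zeros((self.p, self.p))
        for (name, sl, Sj, _), lj in zip(self.penalties, lam):
            S[sl, sl] += lj * Sj
        return S


def build_design(spec: ModelSpec, data: pd.DataFrame) -> DesignBundle:
    """Assemble the model matrix and penalties for ``spec`` on ``data``.

    Rows with missing values in any used column are dropped with a logged
    count.  Parametric columns are taken as supplied; an all-constant
    parametric column triggers a warning (it is collinear with the
    intercept) but is kept.
    """
    used = [spec.response] + list(spec.parametric_terms) + [t.name for t in spec.ordinal_terms]
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise KeyError(f"column(s) {missing_cols} not found in the data")

    sub = data.loc[:, used]
    keep = ~sub.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing values in model columns", n_dropped)
    sub = sub.loc[keep]
    if len(sub) == 0:
        raise ValueError("no complete rows left after dropping missing values")

    family = get_family(spec.family)
    y = np.asarray(sub[spec.response], dtype=float)
    family.validate(y)

    cols = [np.ones(len(sub))]
    names = ["(Intercept)"]
    term_map: dict = {}
    for cname in spec.parametric_terms:
        v = np.asarray(sub[cname], dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"parametric column {cname!r} contains non-finite values")
        if np.ptp(v) == 0:
            logger.warning("parametric column %r is constant (collinear with intercept)", cname)
        term_map[cname] = slice(len(names), len(names) + 1)
        cols.append(v)
        names.append(cname)

    penalties = []
    blocks = {}
    offset = len(names)
    for term in spec.ordinal_terms:
        block = constrain(term, np.asarray(sub[term.name]))
        sl = slice(offset, offset + term.k - 1)
        term_map[term.name] = sl
        penalties.append((term.name, sl, block.S, block))
        blocks[term.name] = block
        cols.append(block.Z)
        names.extend(f"{term.name}.c{i}" for i in range(1, term.k))
        offset += term.k - 1

    X = np.column_stack(cols)
    return DesignBundle(
        X=X, y=y, family=family, penalties=penalties, term_map=term_map,
        column_names=names, blocks=blocks, n_dropped=n_dropped, spec=spec,
    )
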