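"""Tabular I/O, run configuration and result serialization.

Subject tables are delimited text (comma or tab, sniffed) with a header
row.  Ordinal columns may carry labels (e.g. ``">6"`` for an open-ended
top week category); a per-column level map such as ``{">6": 7}`` converts
them to integer levels ``1..k`` at load time.  Result tables are written
as TSV with 17 significant digits so that re-reading reproduces values
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import OrdinalTerm
from .model import ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["load_table", "RunConfig", "write_tsv", "fit_to_json"]

FLOAT_FORMAT = "%.17g"


def load_table(path, level_maps: "dict | None" = None) -> pd.DataFrame:
    """Read a delimited subject table, applying ordinal level-label maps.

    ``level_maps`` maps column name -> {label -> integer level}.  Values in
    a mapped column must either appear in the map or already be integers;
    anything else raises with the offending values listed.
    """
    import csv

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValueError(f"{path} is empty or not a delimited table") from None
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    logger.info("loaded %d rows x %d columns from %s", len(df), df.shape[1], path)

    for col, mapping in (level_maps or {}).items():
        if col not in df.columns:
            raise KeyError(f"level map given for absent column {col!r}")
        mapped = []
        bad = set()
        for v in df[col]:
            key = str(v).strip()
            if key in mapping:
                mapped.append(int(mapping[key]))
                continue
            try:
                fv = float(v)
                if fv == int(fv):
                    mapped.append(int(fv))
                    continue
            except (TypeError, ValueError):
                pass
            bad.add(key)
            mapped.append(-1)
        if bad:
            raise ValueError(
                f"column {col!r} has unmapped ordinal label(s): {sorted(bad)}; "
                "extend the level map"
            )
        df[col] = mapped

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%d row(s) contain missing values (dropped at design build)", n_missing)
    return df


@dataclasses.dataclass
class RunConfig:
    """Declarative run configuration (YAML).

    Example::

        input: cohort.csv
        response: bpd
        family: binomial
        parametric: [weight_g, sga, sex_male, multiples, steroid_days, antibiotic_days]
        ordinal:
          - {name: pathogenic, k: 7, order: 2, levels: {">6": 7}}
        method: REML
        seed: 1
        output: results/
    """

    input: str
    response: str
    family: str = "binomial"
    parametric: list = dataclasses.field(default_factory=list)
    ordinal: list = dataclasses.field(default_factory=list)
    method: str = "REML"
    seed: int = 0
    output: str = "."
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @property
    def level_maps(self) -> dict:
        maps = {}
        for entry in self.ordinal:
            levels = entry.get("levels")
            if levels:
                vals = sorted(int(v) for v in levels.values())
                k = int(entry["k"])
                if any(not 1 <= v <= k for v in vals):
                    raise ValueError(
                        f"level map for {entry['name']!r} must map onto 1..{k}"
                    )
                maps[entry["name"]] = levels
        return maps

    def model_spec(self) -> ModelSpec:
        terms = tuple(
            OrdinalTerm(e["name"], int(e["k"]), int(e.get("order", 2)))
            for e in self.ordinal
        )
        return ModelSpec(
            response=self.response,
            family=self.family,
            parametric_terms=tuple(self.parametric),
            ordinal_terms=terms,
        )


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with full-precision floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def fit_to_json(fit) -> dict:
    """Machine-readable record of a fitted model."""
    return {
        "family": fit.design.family.name,
        "method": fit.method,
        "converged": bool(fit.converged),
        "n": int(fit.design.n),
        "p": int(fit.design.p),
        "lambda": {name: lam for (name, _, _, _), lam in
                   zip(fit.design.penalties, fit.lambda_.tolist())},
        "edf": fit.edf,
        "edf_total": fit.edf_total,
        "deviance": fit.deviance,
        "null_deviance": fit.null_deviance,
        "scale": fit.scale,
        "criterion": None if np.isnan(fit.criterion) else fit.criterion,
        "iterations": {"criterion_evaluations": fit.iterations[0],
                       "final_pirls": fit.iterations[1]},
        "coefficients": dict(zip(fit.coef_names, fit.beta.tolist())),
    }
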