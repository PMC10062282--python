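"""CSV input, fit serialization and NDJSON monitoring logs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .expectile import ExpectileFit, GridSearchConfig
from .models import get_model

Array = np.ndarray

__all__ = [
    "read_table",
    "fit_to_dict",
    "fit_from_dict",
    "save_fit",
    "load_fit",
    "write_ndjson_record",
    "read_config",
]


def read_table(path, covariates: Sequence[str], response: str) -> tuple[Array, Array]:
    """Read a headered CSV into a design matrix and response vector.

    Columns are matched by name, so their order in the file is irrelevant.
    Missing or non-numeric cells raise with the offending row and column.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in [*covariates, response] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    sub = df[[*covariates, response]].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise ValueError(f"{path}: missing or non-numeric value at row {row}, column {col!r}")
    X = sub[list(covariates)].to_numpy(dtype=float)
    Y = sub[response].to_numpy(dtype=float)
    return X, Y


def iter_stream(path, covariates: Sequence[str], response: str):
    """Lazily yield (x, y) pairs from a CSV, for monitoring growing files."""
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader):
            try:
                x = np.array([float(row[c]) for c in covariates])
                y = float(row[response])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: bad record at data row {i}: {exc}") from exc
            yield x, y


def fit_to_dict(fit: ExpectileFit, seed: Optional[int] = None) -> dict:
    s = fit.search
    return {
        "model": fit.model.name,
        "param_box": [list(b) for b in fit.model.param_box],
        "beta_hat": fit.beta_hat.tolist(),
        "tau": fit.tau,
        "tau_estimated": fit.tau_estimated,
        "var_g": fit.var_g,
        "V_m": fit.V_m.tolist(),
        "J_m": fit.J_m.tolist(),
        "J_inv_sqrt": None if fit.J_inv_sqrt is None else fit.J_inv_sqrt.tolist(),
        "m": fit.m,
        "objective": fit.objective,
        "search": {
            "n_stages": s.n_stages,
            "n_points": s.n_points,
            "shrink": s.shrink,
            "step_tol": s.step_tol,
            "polish": s.polish,
        },
        "seed": seed,
    }


def fit_from_dict(d: dict) -> ExpectileFit:
    model = get_model(d["model"]).with_box(d["param_box"])
    search = GridSearchConfig(**d["search"])
    return ExpectileFit(
        model=model,
        beta_hat=np.asarray(d["beta_hat"], dtype=float),
        tau=float(d["tau"]),
        residuals=np.array([]),  # residuals are not serialized
        var_g=float(d["var_g"]),
        V_m=np.asarray(d["V_m"], dtype=float),
        J_m=np.asarray(d["J_m"], dtype=float),
        J_inv_sqrt=None if d["J_inv_sqrt"] is None else np.asarray(d["J_inv_sqrt"], dtype=float),
        objective=float(d["objective"]),
        m=int(d["m"]),
        tau_estimated=bool(d["tau_estimated"]),
        search=search,
    )


def save_fit(fit: ExpectileFit, path, seed: Optional[int] = None) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit, seed), indent=2))


def load_fit(path) -> ExpectileFit:
    return fit_from_dict(json.loads(Path(path).read_text()))


def write_ndjson_record(fh: IO[str], **record) -> None:
    fh.write(json.dumps(record) + "\n")


def read_config(path) -> dict:
    """Flat key=value configuration file; '#' starts a comment line."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
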