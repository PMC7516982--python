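"""Data ingestion, validation, serialization and synthetic fixture generation.

Survival tables are delimited text (comma or tab, auto-detected) with a
header row, one row per subject: a positive time column, a 0/1 status column
(1 = event, 0 = censored) and optional numeric covariate columns.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import OEPIVParams, oepiv_rvs
from .logcore import error_rvs
from .regression import CensoredSample
from .simstudy import ResidualStudyConfig, calibrate_censoring_rho, \
    generate_regression_sample

__all__ = [
    "read_survival_table",
    "write_survival_table",
    "to_censored_sample",
    "generate_fixture",
    "write_json",
]


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_survival_table(path, column_roles: dict | None = None,
                        status_flip: bool = False) -> pd.DataFrame:
    """Read and validate a survival table.

    ``column_roles`` maps roles to column names, e.g.
    ``{"time": "time", "status": "status", "covariates": ["age"]}``; unnamed
    roles default to columns named "time"/"status", with every remaining
    numeric column treated as a covariate.
    """
    roles = dict(column_roles or {})
    time_col = roles.get("time", "time")
    status_col = roles.get("status", "status")
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    covs = roles.get("covariates")
    if covs is None:
        covs = [c for c in df.columns if c not in (time_col, status_col)]
    missing = [c for c in covs if c not in df.columns]
    if missing:
        raise ValueError(f"covariate column(s) {missing} missing from {path}")

    out = df[[time_col, status_col] + list(covs)].copy()
    for col in out.columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(f"non-numeric or missing entry in column {col!r}, row {row}")
        out[col] = vals
    if (out[time_col] <= 0).any():
        row = int((out[time_col] <= 0).idxmax())
        raise ValueError(f"non-positive time at row {row}")
    if status_flip:
        out[status_col] = 1 - out[status_col]
    if not out[status_col].isin([0, 1]).all():
        row = int((~out[status_col].isin([0, 1])).idxmax())
        raise ValueError(f"status outside {{0,1}} at row {row}")
    out.attrs["roles"] = {"time": time_col, "status": status_col,
                          "covariates": list(covs)}
    return out


def write_survival_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def to_censored_sample(table: pd.DataFrame, column_roles: dict | None = None
                       ) -> CensoredSample:
    """Log the times and assemble the design matrix (intercept first)."""
    roles = dict(column_roles or table.attrs.get("roles") or {})
    time_col = roles.get("time", "time")
    status_col = roles.get("status", "status")
    covs = roles.get("covariates")
    if covs is None:
        covs = [c for c in table.columns if c not in (time_col, status_col)]
    y = np.log(table[time_col].to_numpy(dtype=float))
    tau = table[status_col].to_numpy(dtype=int)
    X = np.column_stack([np.ones(len(table))] +
                        [table[c].to_numpy(dtype=float) for c in covs])
    return CensoredSample(y, tau, X)


def generate_fixture(kind: str, config: dict | None = None, seed=None):
    """Reproducible synthetic data with known ground truth.

    Kinds:
      * ``oepiv_sample`` — uncensored positive draws; config keys ``params``
        (flat dict with lambda/a/theta/alpha) and ``n``.
      * ``regression_sample`` — the censored-regression design (single
        uniform covariate); config keys lam/alpha/sigma/beta0/beta1/
        censor_level/n.
      * ``stanford_like`` — a table mimicking a heart-transplant registry
        schema (time, status, age, surgery, transplant), with LOEPIV-generated
        times; synthetic stand-in, not the real registry data.

    Tables carry the generating parameters in ``.attrs["truth"]``.
    """
    config = dict(config or {})
    rng = np.random.default_rng(seed)
    if kind == "oepiv_sample":
        params = config.get("params", {"lambda": 0.3, "a": 0.4, "theta": 0.5,
                                       "alpha": 0.2})
        if not isinstance(params, OEPIVParams):
            params = OEPIVParams.from_dict(params)
        n = int(config.get("n", 100))
        return oepiv_rvs(n, params, seed=rng)

    if kind == "regression_sample":
        keys = ("n", "lam", "alpha", "sigma", "beta0", "beta1", "censor_level")
        rc = ResidualStudyConfig(**{k: config[k] for k in keys if k in config})
        rho = None
        if rc.censor_level > 0:
            rho = calibrate_censoring_rho(rc, rc.censor_level, seed=rng)
        sample = generate_regression_sample(rc, rho, rng)
        table = pd.DataFrame({
            "time": np.exp(sample.y),
            "status": sample.tau,
            "x1": sample.X[:, 1],
        })
        table.attrs["truth"] = dict(lam=rc.lam, alpha=rc.alpha, sigma=rc.sigma,
                                    beta0=rc.beta0, beta1=rc.beta1, rho=rho)
        table.attrs["roles"] = {"time": "time", "status": "status",
                                "covariates": ["x1"]}
        return table

    if kind == "stanford_like":
        n = int(config.get("n", 103))
        truth = dict(lam=config.get("lam", 1.4), alpha=config.get("alpha", 0.13),
                     sigma=config.get("sigma", 0.56),
                     beta=config.get("beta", [3.5, -0.054, 1.75, 2.54]),
                     censor_target=config.get("censor_target", 0.3))
        age = rng.uniform(8.0, 64.0, size=n)
        surgery = rng.binomial(1, 0.3, size=n).astype(float)
        transplant = rng.binomial(1, 0.6, size=n).astype(float)
        X = np.column_stack([np.ones(n), age, surgery, transplant])
        z = error_rvs(n, truth["lam"], truth["alpha"], seed=rng)
        t = np.exp(X @ np.asarray(truth["beta"]) + truth["sigma"] * z)
        # uniform(0, rho) censoring, rho calibrated on the realized lifetimes
        lo, hi = np.quantile(t, [0.01, 0.99])
        target = truth["censor_target"]
        for _ in range(100):
            mid = np.sqrt(lo * hi)
            lvl = np.minimum(t, mid).mean() / mid
            if abs(lvl - target) < 1e-3:
                break
            lo, hi = (mid, hi) if lvl > target else (lo, mid)
        c = rng.uniform(0.0, mid, size=n)
        table = pd.DataFrame({
            "time": np.minimum(t, c),
            "status": (t <= c).astype(int),
            "age": age,
            "surgery": surgery,
            "transplant": transplant,
        })
        table.attrs["truth"] = truth
        table.attrs["roles"] = {"time": "time", "status": "status",
                                "covariates": ["age", "surgery", "transplant"]}
        return table

    raise ValueError(f"unknown fixture kind {kind!r}")


def write_json(obj, path) -> None:
    """JSON with full double precision (repr round-trips doubles exactly)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
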