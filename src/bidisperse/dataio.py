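"""Delimited-file and configuration I/O, chain persistence, run manifests."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .exceptions import ConfigurationError, DataValidationError
from .sampler import ChainResult, MCMCConfig, PriorSpec, RegressionData

__all__ = [
    "load_config",
    "read_regression_data",
    "write_regression_data",
    "write_truth",
    "prior_from_config",
    "mcmc_config_from_dict",
    "save_chain",
    "load_chain",
    "RunManifest",
    "write_manifest",
]


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config file {path} did not parse to a mapping")
    return cfg


def read_regression_data(path, config: dict) -> RegressionData:
    """Read a CSV with a header row into a validated :class:`RegressionData`.

    ``config`` names the columns: ``response`` (required),
    ``mean_covariates`` (list; an intercept is always prepended),
    ``dispersion`` ("scalar", "individual", or a list of covariate columns),
    ``group``, ``offset`` and ``support_bound``.
    """
    df = pd.read_csv(path)
    response = config.get("response")
    if response is None:
        raise ConfigurationError("config must name the response column")
    needed = [response] + list(config.get("mean_covariates", []))
    group_col = config.get("group")
    offset_col = config.get("offset")
    dispersion = config.get("dispersion", "scalar")
    if isinstance(dispersion, list):
        needed += dispersion
    if group_col:
        needed.append(group_col)
    if offset_col:
        needed.append(offset_col)
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(f"columns missing from {path}: {missing_cols}")

    na_rows = df[needed].isna().any(axis=1)
    if na_rows.any():
        lines = (np.flatnonzero(na_rows.to_numpy()) + 2).tolist()  # 1-based + header
        raise DataValidationError(f"missing values on line(s) {lines[:10]} of {path}")
    y_raw = df[response]
    bad = (y_raw != np.floor(y_raw)) | (y_raw < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise DataValidationError(
            f"response column {response!r} must be non-negative integers; "
            f"first offending line: {row}"
        )
    y = y_raw.to_numpy().astype(np.int64)
    mean_cols = list(config.get("mean_covariates", []))
    X1 = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in mean_cols])
    x1_names = ["intercept"] + mean_cols

    group = None
    m = 0
    if group_col:
        codes, levels = pd.factorize(df[group_col], sort=True)
        group = codes.astype(np.int64)
        m = len(levels)

    if dispersion == "scalar":
        X2 = np.ones((len(df), 1))
        x2_names = ["log_nu"]
    elif dispersion == "individual":
        if group is None:
            raise ConfigurationError("dispersion='individual' requires a group column")
        X2 = np.zeros((len(df), m))
        X2[np.arange(len(df)), group] = 1.0
        x2_names = [f"alpha[{i}]" for i in range(m)]
    elif isinstance(dispersion, list):
        X2 = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(float) for c in dispersion]
        )
        x2_names = ["disp_intercept"] + dispersion
    else:
        raise ConfigurationError(f"unknown dispersion specification {dispersion!r}")

    offset = df[offset_col].to_numpy(float) if offset_col else None
    return RegressionData(
        y=y,
        X1=X1,
        X2=X2,
        group=group,
        offset=offset,
        support_bound=config.get("support_bound"),
        x1_names=x1_names,
        x2_names=x2_names,
    )


def write_regression_data(data: RegressionData, path) -> None:
    """Write data as CSV (response, named covariates, optional group)."""
    cols = {"y": data.y}
    for j, name in enumerate(data.x1_names):
        if name == "intercept":
            continue
        cols[name] = data.X1[:, j]
    if data.group is not None:
        cols["group"] = data.group
    if data.offset is not None:
        cols["offset"] = data.offset
    pd.DataFrame(cols).to_csv(path, index=False)


def data_config_for(data: RegressionData) -> dict:
    """A read-back config matching :func:`write_regression_data` output."""
    cfg = {
        "response": "y",
        "mean_covariates": [n for n in data.x1_names if n != "intercept"],
    }
    if data.group is not None:
        cfg["group"] = "group"
        cfg["dispersion"] = "individual" if data.q == data.m else "scalar"
    if data.offset is not None:
        cfg["offset"] = "offset"
    if data.support_bound is not None:
        cfg["support_bound"] = int(data.support_bound)
    return cfg


def write_truth(truth, path) -> None:
    rows = [("beta", i, v) for i, v in enumerate(truth.beta)]
    rows += [("gamma", i, v) for i, v in enumerate(np.atleast_1d(truth.gamma))]
    if truth.theta is not None:
        rows += [("theta", i, v) for i, v in enumerate(truth.theta)]
    if truth.nu is not None:
        rows += [("nu", i, v) for i, v in enumerate(np.atleast_1d(truth.nu))]
    pd.DataFrame(rows, columns=["parameter", "index", "value"]).to_csv(path, index=False)


def prior_from_config(cfg: dict, data: RegressionData) -> PriorSpec:
    """Priors from config; anything unspecified keeps the documented default."""
    pcfg = cfg.get("priors", {}) or {}
    spec = PriorSpec()
    if "beta_sd" in pcfg:
        spec.beta_cov = float(pcfg["beta_sd"]) ** 2 * np.eye(data.p)
    if "beta_var" in pcfg:
        spec.beta_cov = float(pcfg["beta_var"]) * np.eye(data.p)
    if "theta_var" in pcfg and data.m:
        spec.theta_cov = float(pcfg["theta_var"]) * np.eye(data.m)
    if "gamma_var" in pcfg:
        spec.gamma_var = np.full(data.q, float(pcfg["gamma_var"]))
    return spec.validated(data)


def mcmc_config_from_dict(cfg: dict, **overrides) -> MCMCConfig:
    mcfg = dict(cfg.get("mcmc", {}) or {})
    mcfg.update({k: v for k, v in overrides.items() if v is not None})
    allowed = MCMCConfig.__dataclass_fields__.keys()
    unknown = set(mcfg) - set(allowed)
    if unknown:
        raise ConfigurationError(f"unknown mcmc config keys: {sorted(unknown)}")
    return MCMCConfig(**mcfg)


# -- chain persistence ----------------------------------------------------


def save_chain(chain: ChainResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    draws = pd.DataFrame(chain.draws_matrix(), columns=chain.param_names)
    draws.to_csv(outdir / "draws.csv", index=False)
    pd.DataFrame(
        {"warmup": [False] * len(chain.iter_times) + [True] * len(chain.warmup_times),
         "seconds": np.concatenate([chain.iter_times, chain.warmup_times])}
    ).to_csv(outdir / "timing.csv", index=False)
    meta = {
        "config": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in chain.config.__dict__.items()},
        "accept_rates": {k: (None if v != v else float(v))
                         for k, v in chain.accept_rates.items()},
        "param_names": chain.param_names,
        "n_beta": chain.beta.shape[1],
        "n_gamma": chain.gamma.shape[1],
        "n_theta": 0 if chain.theta is None else chain.theta.shape[1],
        "table_build_time": chain.table_build_time,
        "version": __version__,
    }
    with open(outdir / "chain.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def load_chain(chain_dir, table=None) -> ChainResult:
    chain_dir = Path(chain_dir)
    with open(chain_dir / "chain.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    draws = pd.read_csv(chain_dir / "draws.csv").to_numpy(float)
    timing = pd.read_csv(chain_dir / "timing.csv")
    p, q, m = meta["n_beta"], meta["n_gamma"], meta["n_theta"]
    ccfg = meta["config"]
    if ccfg.get("beta_proposal_cov") is not None:
        ccfg["beta_proposal_cov"] = np.asarray(ccfg["beta_proposal_cov"])
    config = MCMCConfig(**ccfg)
    return ChainResult(
        beta=draws[:, :p],
        gamma=draws[:, p: p + q],
        theta=draws[:, p + q: p + q + m] if m else None,
        accept_rates=meta["accept_rates"],
        iter_times=timing.loc[~timing["warmup"], "seconds"].to_numpy(),
        warmup_times=timing.loc[timing["warmup"], "seconds"].to_numpy(),
        config=config,
        param_names=meta["param_names"],
        table=table,
        table_build_time=meta.get("table_build_time", 0.0),
    )


# -- run manifests --------------------------------------------------------


def _sha256_file(path) -> Optional[str]:
    if path is None or not Path(path).exists():
        return None
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written exactly once per output directory."""

    command: str
    config_hash: Optional[str]
    seeds: list
    solver: Optional[str]
    table_hash: Optional[str]
    version: str
    started: str
    finished: str


def write_manifest(
    outdir,
    command: str,
    seeds,
    solver=None,
    config_path=None,
    table_path=None,
    started: Optional[datetime.datetime] = None,
) -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    now = datetime.datetime.now(datetime.timezone.utc)
    manifest = RunManifest(
        command=command,
        config_hash=_sha256_file(config_path),
        seeds=list(np.atleast_1d(seeds).tolist()),
        solver=solver,
        table_hash=_sha256_file(table_path),
        version=__version__,
        started=(started or now).isoformat(),
        finished=now.isoformat(),
    )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest
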