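"""Dataset, parameter, configuration and report serialization.

Datasets live in a directory of comma-separated text files (``X.csv``,
``Y.csv``, optional ``Z.csv``; header row, '.' decimal, UTF-8) plus a
``meta.json`` sidecar carrying the dimensions, seed and generator parameters.
For static data ``Y.csv`` holds the full population with the target unit in
column 0.  Experiment reports are a pair of CSV tables (``raw_errors.csv``,
``summary.csv``) plus a configuration echo.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamic_model import DynamicDataset
from .experiments import (ConditionsReport, DynamicConditionsConfig,
                          IdentifiabilityConfig, SweepConfig, SweepReport)
from .static_model import StaticDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "load_config",
    "dump_config",
    "save_results",
    "load_results",
]

_CONFIG_KINDS = {
    "static-sweep": SweepConfig,
    "identifiability": IdentifiabilityConfig,
    "dynamic-conditions": DynamicConditionsConfig,
}


def _write_csv(path: Path, arr: np.ndarray, prefix: str) -> None:
    arr = np.atleast_2d(np.asarray(arr, float))
    if arr.shape[0] == 1 and arr.size > arr.shape[1]:
        arr = arr.T
    cols = [f"{prefix}{j}" for j in range(arr.shape[1])]
    pd.DataFrame(arr, columns=cols).to_csv(path, index=False)


def save_dataset(data, directory, meta: dict | None = None) -> None:
    """Write a static or dynamic dataset as CSV files + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    if isinstance(data, StaticDataset):
        Y = np.column_stack((data.y, data.Y_not))
        meta.update(kind="static", D=data.D, N=data.Y_not.shape[1],
                    M=data.X.shape[1])
    elif isinstance(data, DynamicDataset):
        Y = data.Y
        meta.update(kind="dynamic", T=data.T, N=data.Y.shape[1],
                    M=data.X.shape[1])
    else:
        raise TypeError(f"unsupported dataset type {type(data)!r}")
    _write_csv(directory / "X.csv", data.X, "x")
    _write_csv(directory / "Y.csv", Y, "y")
    if data.Z is not None:
        _write_csv(directory / "Z.csv", data.Z, "z")
        meta["K"] = data.Z.shape[1]
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_dataset(directory):
    """Load a dataset directory written by :func:`save_dataset`."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for name in ("X.csv", "Y.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing data file {directory / name}")
    X = pd.read_csv(directory / "X.csv").to_numpy()
    Y = pd.read_csv(directory / "Y.csv").to_numpy()
    zp = directory / "Z.csv"
    Z = pd.read_csv(zp).to_numpy() if zp.exists() else None
    if meta.get("kind") == "dynamic":
        return DynamicDataset(X=X, Y=Y, Z=Z), meta
    return StaticDataset(X=X, Y_not=Y[:, 1:], y=Y[:, 0], Z=Z), meta


def load_config(path):
    """Load and validate an experiment configuration (YAML or JSON).

    The file must carry ``kind`` (one of ``static-sweep``, ``identifiability``,
    ``dynamic-conditions``); remaining keys must be fields of the matching
    config dataclass.  Unknown keys and type mismatches are rejected with the
    offending key path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "kind" not in raw:
        raise ValueError(f"config {path} must be a mapping with a 'kind' key")
    kind = raw.pop("kind")
    if kind not in _CONFIG_KINDS:
        raise ValueError(f"unknown experiment kind {kind!r}; expected one of "
                         f"{sorted(_CONFIG_KINDS)}")
    cls = _CONFIG_KINDS[kind]
    fields = {f.name: f for f in dataclasses.fields(cls)}
    clean = {}
    for key, val in raw.items():
        if key not in fields:
            raise ValueError(f"unknown config key '{kind}.{key}'")
        if isinstance(val, list):
            val = tuple(val)
        target = fields[key].type
        if target == "int":
            if not isinstance(val, int) or isinstance(val, bool):
                raise ValueError(f"config key '{kind}.{key}' must be an integer")
        elif target == "float" and not isinstance(val, (int, float)):
            raise ValueError(f"config key '{kind}.{key}' must be numeric")
        clean[key] = val
    cfg = cls(**clean)
    if hasattr(cfg, "validate"):
        cfg.validate()
    return kind, cfg


def dump_config(kind: str, cfg, path) -> None:
    doc = {"kind": kind}
    doc.update({k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(cfg).items()})
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def save_results(report, directory) -> None:
    """Write an experiment report (raw errors, summary, config echo)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.raw.to_csv(directory / "raw_errors.csv", index=False)
    report.summary.to_csv(directory / "summary.csv", index=False)
    cfg = dict(report.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    (directory / "config_echo.yaml").write_text(
        yaml.safe_dump(cfg, sort_keys=False))


def load_results(directory):
    """Reload a report directory; numeric fields round-trip exactly via the
    full-precision CSV representation."""
    directory = Path(directory)
    for name in ("raw_errors.csv", "summary.csv", "config_echo.yaml"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing results file {directory / name}")
    raw = pd.read_csv(directory / "raw_errors.csv")
    summary = pd.read_csv(directory / "summary.csv")
    config = yaml.safe_load((directory / "config_echo.yaml").read_text())
    if {"stim_corr", "latent_corr"} <= set(raw.columns):
        return ConditionsReport(raw=raw, summary=summary, config=config)
    return SweepReport(raw=raw, summary=summary, config=config)
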