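"""Readers/writers for growth tables, parameter configs and run provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .fitting import REQUIRED_COLUMNS, FitResult, GrowthDataset
from .params import params_from_config, params_to_config

__all__ = [
    "read_growth_csv",
    "write_growth_csv",
    "load_params",
    "save_params",
    "save_fit_result",
    "provenance_record",
]

WIDE_COLUMNS = ("condition", "ratio", "time_h", "red", "green")


def read_growth_csv(path) -> GrowthDataset:
    """Read a growth table in long (canonical) or wide format.

    Long format columns: condition, ratio, time_h, channel, count,
    replicate.  The wide variant has red/green count columns instead of
    (channel, count) and is melted on input; a missing replicate column
    defaults to 1.  Malformed rows are reported with their line numbers
    (1-based, header included).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if len(frame) == 0:
        raise ValueError(f"{path}: empty dataset (no data rows)")
    cols = set(frame.columns)
    if {"channel", "count"} <= cols:
        pass
    elif {"red", "green"} <= cols:
        frame = frame.melt(
            id_vars=[c for c in frame.columns if c not in ("red", "green")],
            value_vars=["red", "green"],
            var_name="channel",
            value_name="count",
        )
    else:
        raise ValueError(
            f"{path}: need either long columns (channel, count) or wide columns "
            f"(red, green); found {sorted(cols)}"
        )
    if "replicate" not in frame.columns:
        frame["replicate"] = 1
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    bad = frame.index[pd.to_numeric(frame["count"], errors="coerce").isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric counts at lines {lines}")
    frame["count"] = frame["count"].astype(float)
    neg = frame.index[frame["count"] < 0]
    if len(neg):
        lines = [int(i) + 2 for i in neg[:10]]
        raise ValueError(f"{path}: negative counts at lines {lines}")
    return GrowthDataset(frame[list(REQUIRED_COLUMNS)].copy())


def write_growth_csv(data: GrowthDataset, path, *, float_format: str = "%.6f") -> None:
    """Write the canonical long-format CSV (stable column order/format,
    so identical datasets produce identical bytes)."""
    data.frame[list(REQUIRED_COLUMNS)].to_csv(path, index=False, float_format=float_format)


def load_params(path):
    """Load a flat parameter config (YAML or JSON by extension).

    Returns ``(PhenotypeParams, DrugParams | None, coupling, auc_mode)``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return params_from_config(cfg)


def save_params(path, p, d=None, *, coupling: str = "linear", auc_mode: str = "hold") -> None:
    cfg = params_to_config(p, d, coupling=coupling, auc_mode=auc_mode)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def save_fit_result(path, fit: FitResult) -> None:
    """Serialize a FitResult (point estimate, locked values, CIs, trace)."""
    out = {
        "condition": fit.condition,
        "seed": fit.seed,
        "objective": fit.fun,
        "estimate": fit.as_dict(),
        "fixed": fit.fixed,
        "ci95": {k: list(v) for k, v in fit.cis.items()},
        "trace": [float(x) for x in fit.trace],
    }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def provenance_record(config: dict, seed: int) -> dict:
    """Reproducibility stamp: config hash, seed and package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "psmsr_version": __version__,
    }
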