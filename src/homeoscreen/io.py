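"""Readers and writers for the pipeline's table formats and configuration.

All tables are plain CSV/TSV for auditability. The standard measurement
table has the header ``genotype,nmj_id,phtx,mepsp_mV,epsp_mV,vm_mV,rin_MOhm``
with ``phtx`` in {0, 1}; quantal content is derived on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .simulate import MEASUREMENT_COLUMNS


def read_measurements(path) -> pd.DataFrame:
    """Load and validate a measurement CSV; adds a derived ``qc`` column."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("mepsp_mV", "epsp_mV"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals <= 0)]
        if len(bad):
            # +2: 1-based line numbers plus the header line
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(
                f"{path}: non-numeric or non-positive {col} at line(s) {lines}"
            )
        df[col] = vals
    if not df["phtx"].isin([0, 1]).all():
        bad = df.index[~df["phtx"].isin([0, 1])][:5]
        raise SchemaError(
            f"{path}: phtx must be 0 or 1 at line(s) {[int(i) + 2 for i in bad]}"
        )
    df["qc"] = df["epsp_mV"] / df["mepsp_mV"]
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample TSV with first column ``gene_id``."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    arr = df.to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise SchemaError(f"{path}: counts must be non-negative integers")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "genotype", "batch"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: design needs columns {sorted(required)}")
    return df


def read_trace(path_prefix) -> tuple[pd.DataFrame, dict]:
    """Trace CSV plus its JSON sidecar (sampling rate, stimuli, truth events)."""
    trace = pd.read_csv(f"{path_prefix}.csv")
    if list(trace.columns) != ["time_s", "voltage_mV"]:
        raise SchemaError(f"{path_prefix}.csv: expected columns time_s,voltage_mV")
    with open(f"{path_prefix}.json") as fh:
        sidecar = json.load(fh)
    return trace, sidecar


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "homeoscreen_out",
    "genotypes": {},  # name -> GenotypeParams fields
    "screen": {
        "reference": "reference",
        "coverage": 0.95,
        "rule": "either",
        "n_per_genotype": 10,
        "n_deficiencies": 12,
        "n_blocked": 3,
    },
    "detection": {
        "threshold_sd": 3.5,
        "refractory_ms": 5.0,
        "evoked_window_ms": 50.0,
        "exclusion_ms": 100.0,
    },
    "classification": {"blocked_below": 15.0, "suppressed_below": 30.0},
    "deg": {"fdr_cut": 0.05, "fc_cut": 1.5, "cpm_threshold": 5.0},
}


def _merge(defaults: Mapping, overrides: Mapping, prefix="") -> dict:
    out = dict(defaults)
    for key, val in overrides.items():
        if key not in defaults:
            raise ConfigurationError(f"unknown config key: {prefix}{key}")
        if isinstance(defaults[key], dict) and key != "genotypes":
            if not isinstance(val, Mapping):
                raise ConfigurationError(f"config key {prefix}{key} must be a mapping")
            out[key] = _merge(defaults[key], val, prefix=f"{prefix}{key}.")
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Resolve a YAML/JSON config file against the defaults.

    Unknown keys are rejected so typos never silently fall back to defaults.
    """
    user: Mapping = {}
    if path is not None:
        text = Path(path).read_text()
        user = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        ) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def echo_config(cfg: Mapping, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


__all__ = [
    "read_measurements",
    "write_measurements",
    "read_counts",
    "write_counts",
    "read_design",
    "read_trace",
    "DEFAULT_CONFIG",
    "load_config",
    "echo_config",
]
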