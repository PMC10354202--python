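"""Plain-text formats and run configuration.

Traces and event tables travel as tab-separated text with unit-bearing
column names (``time_s``, ``extension_nm``, ``force_pN``) and leading ``#``
comment lines carrying provenance, so every artifact is diffable and
self-describing.  Parameter sets serialize as flat key = value text, one
scalar per key, units embedded in the key names.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import BellEvansParams, ForceSense
from .simulator import ExtensionTrace

__all__ = [
    "write_trace", "read_trace", "write_table", "read_table",
    "write_params", "read_params", "bell_evans_from_config",
    "load_run_config", "config_hash",
]

TRACE_COLUMNS = ["time_s", "extension_nm", "force_pN"]


def _provenance_header(provenance: dict) -> str:
    lines = [f"# {k}: {v}" for k, v in sorted(provenance.items())]
    return "\n".join(lines) + ("\n" if lines else "")


def write_trace(path, trace: ExtensionTrace) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "extension_nm": trace.extension_nm,
            "force_pN": trace.force_pN,
        }
    )
    prov = dict(trace.provenance)
    prov.setdefault("sampling_hz", trace.sampling_hz)
    with path.open("w") as fh:
        fh.write(_provenance_header(prov))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_trace(path) -> ExtensionTrace:
    path = Path(path)
    provenance = {}
    with path.open() as fh:
        text = fh.read()
    for ln in text.splitlines():
        if ln.startswith("#") and ":" in ln:
            key, _, val = ln[1:].partition(":")
            provenance[key.strip()] = val.strip()
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#")
    except Exception as err:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse trace: {err}") from err
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df[TRACE_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed row {int(bad.idxmax()) + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2
        raise ValueError(f"{path}: non-monotone time at data row {row}")
    fs = 1.0 / np.median(dt) if t.size > 1 else float(provenance.get("sampling_hz", 1.0))
    return ExtensionTrace(
        sampling_hz=float(fs),
        extension_nm=df["extension_nm"].to_numpy(dtype=float),
        force_pN=df["force_pN"].to_numpy(dtype=float),
        provenance=provenance,
    )


def write_table(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(_provenance_header(provenance))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", comment="#")


def write_params(path, params: dict) -> None:
    """Flat key = value parameter file (one scalar per key)."""
    with Path(path).open("w") as fh:
        for key, val in params.items():
            fh.write(f"{key} = {val}\n")


def read_params(path) -> dict:
    out: dict[str, float | str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise ValueError(f"{path}: line {i}: expected 'key = value'")
        key, _, val = ln.partition("=")
        val = val.strip()
        try:
            out[key.strip()] = float(val)
        except ValueError:
            out[key.strip()] = val
    return out


def bell_evans_from_config(cfg: dict, prefix: str = "") -> BellEvansParams:
    """Build a rate law from flat config keys ``{prefix}k0_per_s`` etc."""
    return BellEvansParams(
        k0_per_s=float(cfg[f"{prefix}k0_per_s"]),
        x_dagger_nm=float(cfg[f"{prefix}x_dagger_nm"]),
        sense=ForceSense(cfg.get(f"{prefix}sense", "force_accelerated")),
    )


def load_run_config(path) -> dict:
    """YAML run configuration for the pipeline stages."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration for output provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
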