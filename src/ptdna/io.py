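"""Delimited-text readers and writers for the pipeline's file formats.

All files are tab-separated with a named header row, '.' decimal and
'#'-prefixed comment lines.  Metadata (enantiomer, concentration_uM,
force_pN, ...) travels in ``# key = value`` comment lines.  Units are fixed
at the file boundary: extensions in um (column ``extension_um``), forces in
pN (``force_pN``), times in minutes (``time_min``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .wlc import ForceExtensionCurve
from .kinetics import ExtensionTimeSeries, RateSeries

__all__ = [
    "read_force_extension",
    "write_force_extension",
    "read_timeseries",
    "write_timeseries",
    "write_rate_series",
]

_META_TYPES = {"concentration_uM": float, "force_pN": float,
               "enantiomer": str}


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                meta[key] = _META_TYPES.get(key, str)(value)
    return meta


def _read_table(path, required: Tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=r"\s+|,|;", comment="#", engine="python")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse delimited table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    for col in required:
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r} "
                             f"near data line {bad[0] + 1}")
    return df


def read_force_extension(path) -> ForceExtensionCurve:
    """Read a force-extension file (columns ``extension_um``, ``force_pN``)."""
    df = _read_table(path, ("extension_um", "force_pN"))
    return ForceExtensionCurve(df["extension_um"].to_numpy(float),
                               df["force_pN"].to_numpy(float))


def write_force_extension(path, curve: ForceExtensionCurve,
                          metadata: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        fh.write("extension_um\tforce_pN\n")
        for e, f in zip(curve.extensions_um, curve.forces_pN):
            fh.write(f"{e:.12g}\t{f:.12g}\n")


def read_timeseries(path) -> ExtensionTimeSeries:
    """Read an extension-vs-time file (columns ``time_min``, ``extension_um``).

    '#'-comment metadata lines become the series label.
    """
    df = _read_table(path, ("time_min", "extension_um"))
    meta = _read_metadata(path)
    return ExtensionTimeSeries(df["time_min"].to_numpy(float),
                               df["extension_um"].to_numpy(float),
                               label=meta or None)


def write_timeseries(path, ts: ExtensionTimeSeries,
                     metadata: Optional[dict] = None) -> None:
    meta = dict(ts.label or {})
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        fh.write("time_min\textension_um\n")
        for t, y in zip(ts.times_min, ts.extensions_um):
            fh.write(f"{t:.12g}\t{y:.12g}\n")


def write_rate_series(path, rates: RateSeries,
                      metadata: Optional[dict] = None) -> None:
    col = ("rate_um_per_min" if rates.kind == "instantaneous"
           else "avg_rate_um_per_min")
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        fh.write(f"# kind = {rates.kind}\n")
        fh.write(f"time_min\t{col}\n")
        for t, v in zip(rates.times_min, rates.values):
            fh.write(f"{t:.12g}\t{v:.12g}\n")
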