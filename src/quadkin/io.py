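"""Delimited-text round-tripping for traces, curves, series and tables.

All data files are comma-delimited text with optional ``# key=value``
metadata comment lines before the header row:

* CD trace:        ``# wavelength_nm=265`` then ``time_min,signal``
* melting curve:   ``# wavelength_nm=295`` then ``temp_C,signal``
* HDX series:      ``# residue=G21`` then ``time_min,volume``
* peak table:      ``residue,vol_g4i,vol_g4ii``
* trajectory:      ``time_min,A_hp,B_g4i,D_u,C_g4ii``

Both LF and CRLF line endings are accepted.  Malformed rows raise
``ParseError`` carrying the 1-based line number.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Any

import numpy as np

from .kinetics import STATE_ORDER, StateTrajectory
from .nmr import HDXSeries, MeltingCurve, PeakVolumeTable
from .observables import CDTrace

__all__ = [
    "ParseError",
    "read_cd_trace", "write_cd_trace",
    "read_melting_curve", "write_melting_curve",
    "read_hdx_series", "write_hdx_series",
    "read_peak_table", "write_peak_table",
    "write_trajectory",
    "read_config",
    "write_report",
]

_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Malformed data file; carries the offending 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path, self.lineno = str(path), lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _read_table(path, n_cols: int, header: str):
    """Parse a delimited file into (metadata dict, float columns)."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header_seen = False
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = [p.strip() for p in line.split(",")]
        if not header_seen:
            if parts != header.split(","):
                raise ParseError(path, lineno, f"expected header {header!r}, got {line!r}")
            header_seen = True
            continue
        if len(parts) != n_cols:
            raise ParseError(path, lineno, f"expected {n_cols} columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric value in {line!r}") from None
    if not header_seen:
        raise ParseError(path, 1, f"missing header {header!r}")
    if not rows:
        raise ParseError(path, 1, "no data rows")
    return meta, np.array(rows, dtype=float)


def _write_table(path, meta: dict[str, Any], header: str, columns) -> None:
    lines = [f"# {k}={v}" for k, v in meta.items()]
    lines.append(header)
    for row in np.column_stack(columns):
        lines.append(",".join(_FLOAT_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cd_trace(path) -> CDTrace:
    meta, data = _read_table(path, 2, "time_min,signal")
    if np.any(np.diff(data[:, 0]) <= 0):
        raise ParseError(path, 1, "time_min column must be strictly increasing")
    return CDTrace(
        wavelength=float(meta.get("wavelength_nm", "nan")),
        times=data[:, 0],
        signal=data[:, 1],
    )


def write_cd_trace(path, trace: CDTrace) -> None:
    _write_table(
        path, {"wavelength_nm": _FLOAT_FMT % trace.wavelength},
        "time_min,signal", (trace.times, trace.signal),
    )


def read_melting_curve(path) -> MeltingCurve:
    meta, data = _read_table(path, 2, "temp_C,signal")
    return MeltingCurve(
        temperatures=data[:, 0],
        ellipticity=data[:, 1],
        wavelength=float(meta.get("wavelength_nm", 295.0)),
    )


def write_melting_curve(path, curve: MeltingCurve) -> None:
    _write_table(
        path, {"wavelength_nm": _FLOAT_FMT % curve.wavelength},
        "temp_C,signal", (curve.temperatures, curve.ellipticity),
    )


def read_hdx_series(path) -> HDXSeries:
    meta, data = _read_table(path, 2, "time_min,volume")
    return HDXSeries(
        residue=meta.get("residue", "?"), times=data[:, 0], volumes=data[:, 1]
    )


def write_hdx_series(path, series: HDXSeries) -> None:
    _write_table(
        path, {"residue": series.residue},
        "time_min,volume", (series.times, series.volumes),
    )


def read_peak_table(path) -> PeakVolumeTable:
    residues: list[str] = []
    vi: list[float] = []
    vii: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if not header_seen:
            if parts != ["residue", "vol_g4i", "vol_g4ii"]:
                raise ParseError(path, lineno, "expected header 'residue,vol_g4i,vol_g4ii'")
            header_seen = True
            continue
        if len(parts) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
        try:
            residues.append(parts[0])
            vi.append(float(parts[1]))
            vii.append(float(parts[2]))
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric volume in {line!r}") from None
    if not residues:
        raise ParseError(path, 1, "no data rows")
    return PeakVolumeTable(residues=tuple(residues), vol_g4i=np.array(vi), vol_g4ii=np.array(vii))


def write_peak_table(path, table: PeakVolumeTable) -> None:
    lines = ["residue,vol_g4i,vol_g4ii"]
    for res, a, b in zip(table.residues, table.vol_g4i, table.vol_g4ii):
        lines.append(f"{res},{_FLOAT_FMT % a},{_FLOAT_FMT % b}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(path, traj: StateTrajectory) -> None:
    _write_table(
        path, {}, "time_min," + ",".join(STATE_ORDER),
        (traj.times, *[traj.states[:, i] for i in range(4)]),
    )


def read_config(path) -> dict[str, Any]:
    """Load a TOML analysis configuration."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_report(path, report: dict[str, Any]) -> None:
    """Deterministic JSON report (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
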