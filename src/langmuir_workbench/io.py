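"""Delimited-text readers/writers for trough exports and result tables.

All tabular data travel as delimited text with a header row and '.' decimal
separator (comma, semicolon, tab and whitespace delimiters are sniffed on
read; writes are comma-separated).  Metadata that does not fit a flat table
(film label, weight fraction, oscillation frequency, trace role, ground-truth
generator parameters) lives in a YAML sidecar next to the data file, named by
swapping the extension for ``.yaml``.
"""

from __future__ import annotations

import re
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .energy import ContactAngleSet, ProbeLiquid, SurfaceEnergyResult
from .isotherm import Isotherm, IsothermError, TransitionReport
from .penetration import KineticsTrace, PenetrationResult
from .rheology import OscillationTrace, RheologyError

__all__ = [
    "ParseError",
    "sidecar_path",
    "read_sidecar",
    "write_sidecar",
    "read_isotherm",
    "write_isotherm",
    "read_oscillation_trace",
    "write_oscillation_trace",
    "read_kinetics_trace",
    "write_kinetics_trace",
    "read_contact_angles",
    "write_contact_angles",
    "read_liquids",
    "write_liquids",
    "write_transition_report",
    "write_penetration_result",
    "write_surface_energy_table",
]


class ParseError(ValueError):
    """A data file could not be parsed; the message names the offending line."""


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def read_sidecar(path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        return {}
    data = yaml.safe_load(sc.read_text())
    return data if isinstance(data, dict) else {}


def write_sidecar(path, mapping: dict) -> Path:
    sc = sidecar_path(path)
    sc.write_text(yaml.safe_dump(mapping, sort_keys=False))
    return sc


def _floatable(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_numeric_table(path) -> tuple:
    """Sniffed delimited read; returns (DataFrame, has_header)."""
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                first = line.strip()
                break
    if not first:
        raise ParseError(f"{path}: file contains no data")
    tokens = [t for t in re.split(r"[,;\t ]+", first) if t]
    has_header = not all(_floatable(t) for t in tokens)
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        comment="#",
        header=0 if has_header else None,
        skip_blank_lines=True,
    )
    return df, has_header


def _numeric_column(df: pd.DataFrame, col, path, has_header) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.nonzero(vals.isna().to_numpy())[0]
    if bad.size:
        line = int(bad[0]) + (2 if has_header else 1)
        raise ParseError(
            f"{path}: non-numeric value in column {col!r} at line {line}"
        )
    return vals.to_numpy(dtype=float)


def _pick_column(df: pd.DataFrame, patterns: Sequence[str], fallback: int):
    for col in df.columns:
        name = str(col).lower()
        if any(re.search(p, name) for p in patterns):
            return col
    return df.columns[fallback]


def read_isotherm(
    path,
    label: Optional[str] = None,
    x_w: Optional[float] = None,
    temperature: Optional[float] = None,
) -> Isotherm:
    """Read an (area, pressure) isotherm from delimited text.

    Columns are mapped by name when a header is present (``area``-like and
    ``pi``/``pressure``-like), otherwise positionally.  Rows are sorted into
    compression order (decreasing area) and duplicate areas are averaged.
    Metadata is taken from the YAML sidecar, overridden by the arguments.
    """
    df, has_header = _read_numeric_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least two columns (area, pressure)")
    a_col = _pick_column(df, [r"area", r"\ba\b"], 0) if has_header else df.columns[0]
    p_col = (
        _pick_column(df, [r"pi", r"press"], 1) if has_header else df.columns[1]
    )
    if a_col == p_col:
        p_col = df.columns[1]
    area = _numeric_column(df, a_col, path, has_header)
    pressure = _numeric_column(df, p_col, path, has_header)
    tab = (
        pd.DataFrame({"area": area, "pressure": pressure})
        .groupby("area", as_index=False)
        .mean()
        .sort_values("area", ascending=False)
    )
    meta = read_sidecar(path)
    return Isotherm(
        area=tab["area"].to_numpy(),
        pressure=tab["pressure"].to_numpy(),
        label=label if label is not None else str(meta.get("label", "")),
        x_w=x_w if x_w is not None else float(meta.get("x_w", 0.0)),
        temperature=(
            temperature
            if temperature is not None
            else float(meta.get("temperature", 20.0))
        ),
    )


def write_isotherm(iso: Isotherm, path, ground_truth=None) -> Path:
    path = Path(path)
    pd.DataFrame({"area_nm2": iso.area, "pi_mN_m": iso.pressure}).to_csv(
        path, index=False
    )
    meta = {"label": iso.label, "x_w": iso.x_w, "temperature": iso.temperature}
    if ground_truth is not None:
        meta["ground_truth"] = (
            asdict(ground_truth) if is_dataclass(ground_truth) else dict(ground_truth)
        )
    write_sidecar(path, meta)
    return path


def read_oscillation_trace(path, frequency: Optional[float] = None) -> OscillationTrace:
    """Read a forced-oscillation trace (time_s, area, pressure_mN_m).

    The barrier frequency must come from the YAML sidecar or the argument.
    """
    df, has_header = _read_numeric_table(path)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need columns time, area, pressure")
    cols = (
        (
            _pick_column(df, [r"time"], 0),
            _pick_column(df, [r"area"], 1),
            _pick_column(df, [r"pi", r"press"], 2),
        )
        if has_header
        else tuple(df.columns[:3])
    )
    t, a, p = (_numeric_column(df, c, path, has_header) for c in cols)
    meta = read_sidecar(path)
    f = frequency if frequency is not None else meta.get("frequency_hz")
    if f is None:
        raise RheologyError(
            f"{path}: oscillation frequency missing (no sidecar entry "
            "'frequency_hz' and no argument)"
        )
    return OscillationTrace(
        time=t,
        area=a,
        pressure=p,
        frequency=float(f),
        label=str(meta.get("label", "")),
        x_w=float(meta.get("x_w", 0.0)),
        baseline_pressure=meta.get("baseline_pressure"),
    )


def write_oscillation_trace(trace: OscillationTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time, "area": trace.area, "pressure_mN_m": trace.pressure}
    ).to_csv(path, index=False)
    write_sidecar(
        path,
        {
            "frequency_hz": trace.frequency,
            "label": trace.label,
            "x_w": trace.x_w,
            "baseline_pressure": trace.baseline_pressure,
        },
    )
    return path


def read_kinetics_trace(path, role: Optional[str] = None) -> KineticsTrace:
    """Read a penetration/reference trace (time_min, pressure_mN_m)."""
    df, has_header = _read_numeric_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need columns time, pressure")
    cols = (
        (_pick_column(df, [r"time"], 0), _pick_column(df, [r"pi", r"press"], 1))
        if has_header
        else tuple(df.columns[:2])
    )
    t, p = (_numeric_column(df, c, path, has_header) for c in cols)
    meta = read_sidecar(path)
    return KineticsTrace(
        time=t,
        pressure=p,
        role=role if role is not None else str(meta.get("role", "")),
        label=str(meta.get("label", "")),
        concentration=float(meta.get("concentration_ug_ml", 3.5)),
    )


def write_kinetics_trace(trace: KineticsTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_min": trace.time, "pressure_mN_m": trace.pressure}
    ).to_csv(path, index=False)
    write_sidecar(
        path,
        {
            "role": trace.role,
            "label": trace.label,
            "concentration_ug_ml": trace.concentration,
        },
    )
    return path


def read_contact_angles(path, label: Optional[str] = None) -> ContactAngleSet:
    """Read a drop-angle table (columns liquid, angle_deg)."""
    df, has_header = _read_numeric_table(path)
    if not has_header or df.shape[1] < 2:
        raise ParseError(f"{path}: need a header with columns liquid, angle_deg")
    liq_col = _pick_column(df, [r"liquid", r"solvent"], 0)
    ang_col = _pick_column(df, [r"angle", r"theta"], 1)
    angles = _numeric_column(df, ang_col, path, has_header)
    groups: dict = {}
    for name, ang in zip(df[liq_col].astype(str), angles):
        groups.setdefault(name, []).append(ang)
    meta = read_sidecar(path)
    return ContactAngleSet(
        angles={k: np.asarray(v) for k, v in groups.items()},
        label=label if label is not None else str(meta.get("label", "")),
    )


def write_contact_angles(cas: ContactAngleSet, path) -> Path:
    path = Path(path)
    rows = [
        {"liquid": name, "angle_deg": float(a)}
        for name, arr in cas.angles.items()
        for a in arr
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    write_sidecar(path, {"label": cas.label})
    return path


def read_liquids(path) -> list:
    """Read a probe-liquid table from YAML (list of name/gamma/gamma_d/gamma_p)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ParseError(f"{path}: expected a YAML list of liquids")
    return [
        ProbeLiquid(
            name=str(row["name"]),
            gamma=float(row["gamma"]),
            gamma_d=float(row["gamma_d"]),
            gamma_p=float(row["gamma_p"]),
        )
        for row in data
    ]


def write_liquids(liquids: Sequence[ProbeLiquid], path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            [
                {
                    "name": liq.name,
                    "gamma": liq.gamma,
                    "gamma_d": liq.gamma_d,
                    "gamma_p": liq.gamma_p,
                }
                for liq in liquids
            ],
            sort_keys=False,
        )
    )
    return path


def write_transition_report(report: TransitionReport, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(report.to_dict(), sort_keys=False))
    return path


def write_penetration_result(result: PenetrationResult, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(result.to_dict(), sort_keys=False))
    return path


def write_surface_energy_table(
    results: Sequence[SurfaceEnergyResult], path
) -> Path:
    """Write a flat per-surface table (label, gamma_s, gamma_d, gamma_p, sds)."""
    path = Path(path)
    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, index=False)
    return path
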