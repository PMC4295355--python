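"""Delimited-text I/O for decay curves, specimen tables and fit results.

Everything is plain CSV (UTF-8, header row, period decimal separator, ``#``
comment lines for run metadata) — the domain has no standard binary
container for PFG decay tables, and text keeps every artifact diffable.

Layouts
-------
curves
    long format: ``curve_id, b_value_si, amplitude`` (b in s/m^2).
specimens
    one row per specimen: ``specimen_id, group, tnm, stroma_class,
    p, st, at, pce, pve, v, d_fast_1e9, d_slow_1e11, p1, adc_1e9``
    (diffusivities in scaled units: 1e-9 / 1e-11 m^2/s).
fit results
    ``curve_id, d_fast_1e9, d_slow_1e11, p1, adc_1e9, method, residual_rms``.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .signal import DecayCurve

__all__ = [
    "SPECIMEN_COLUMNS",
    "write_curves",
    "read_curves",
    "write_table",
    "read_table",
    "fit_results_frame",
    "validate_specimen_table",
]

SPECIMEN_COLUMNS = [
    "specimen_id", "group", "tnm", "stroma_class",
    "p", "st", "at", "pce", "pve", "v",
    "d_fast_1e9", "d_slow_1e11", "p1", "adc_1e9",
]

_SPECIMEN_NUMERIC = SPECIMEN_COLUMNS[4:]


def _meta_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV with an optional ``#`` metadata header."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(_meta_header(meta))
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping ``#`` comments."""
    return pd.read_csv(path, comment="#")


def write_curves(curves: list[DecayCurve], path, meta: dict | None = None) -> None:
    """Write decay curves in long format (curve_id, b_value_si, amplitude)."""
    frames = [
        pd.DataFrame(
            {"curve_id": c.curve_id, "b_value_si": c.b_values, "amplitude": c.amplitudes}
        )
        for c in curves
    ]
    write_table(pd.concat(frames, ignore_index=True), path, meta=meta)


def read_curves(path) -> dict[str, DecayCurve]:
    """Read a long-format curve file into DecayCurve objects, keyed by id."""
    df = read_table(path)
    required = {"curve_id", "b_value_si", "amplitude"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"curve file missing columns: {missing}", missing=missing)
    out: dict[str, DecayCurve] = {}
    for cid, sub in df.groupby("curve_id", sort=False):
        sub = sub.sort_values("b_value_si")
        out[str(cid)] = DecayCurve(
            sub["b_value_si"].to_numpy(float),
            sub["amplitude"].to_numpy(float),
            curve_id=str(cid),
        )
    return out


def fit_results_frame(results: dict) -> pd.DataFrame:
    """Fit results (curve_id -> BiexpFitResult) as the canonical table."""
    rows = []
    for cid, r in results.items():
        rows.append(
            dict(
                curve_id=cid,
                d_fast_1e9=r.fast.d * 1e9,
                d_slow_1e11=r.slow.d * 1e11,
                p1=r.fast.population,
                adc_1e9=r.adc_initial_slope * 1e9,
                method=r.method,
                residual_rms=r.residual_rms,
            )
        )
    return pd.DataFrame(rows)


# Plausibility windows for the scaled diffusion columns; values far outside
# usually mean SI units leaked into the regression layer.
_PLAUSIBLE = {
    "d_fast_1e9": (0.1, 5.0),
    "d_slow_1e11": (0.1, 10.0),
    "p1": (0.0, 1.0),
}


def validate_specimen_table(path) -> tuple[pd.DataFrame, list[dict]]:
    """Validate a specimen CSV; returns (table, row-level error report).

    Checks, in order: header schema; numeric parsability with period
    decimals (a comma-decimal cell is reported with its row and column);
    composition invariants (each constituent in [0, 100], sum <= 100.5);
    unit-scale plausibility of the diffusion columns.  Structural problems
    (missing file / columns) raise :class:`SchemaError`; cell- and
    row-level violations are returned in the report as dicts with keys
    ``row`` (0-based data row), ``rule`` and ``message``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in SPECIMEN_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"specimen table missing columns: {missing}", missing=missing)

    errors: list[dict] = []
    df = raw.copy()
    for col in _SPECIMEN_NUMERIC:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        for idx in np.flatnonzero(bad.to_numpy()):
            errors.append(
                dict(
                    row=int(idx),
                    rule="numeric_parse",
                    message=(
                        f"column {col!r}, row {idx}: cannot parse "
                        f"{raw[col].iloc[idx]!r} as a period-decimal number"
                    ),
                )
            )
        df[col] = converted

    comp_cols = ["p", "st", "at", "pce", "pve", "v"]
    comp = df[comp_cols].to_numpy(float)
    with np.errstate(invalid="ignore"):
        out_of_range = (comp < 0) | (comp > 100)
        for i, j in zip(*np.nonzero(out_of_range)):
            errors.append(
                dict(
                    row=int(i),
                    rule="composition_range",
                    message=f"{comp_cols[j]}={comp[i, j]} outside [0, 100]",
                )
            )
        sums = np.nansum(comp, axis=1)
        for i in np.flatnonzero(sums > 100.5):
            errors.append(
                dict(
                    row=int(i),
                    rule="composition_sum",
                    message=f"constituents sum to {sums[i]:.2f} > 100.5",
                )
            )
        for col, (lo, hi) in _PLAUSIBLE.items():
            vals = df[col].to_numpy(float)
            for i in np.flatnonzero((vals < lo) | (vals > hi)):
                errors.append(
                    dict(
                        row=int(i),
                        rule=f"{col}_plausible",
                        message=f"{col}={vals[i]} outside plausible [{lo}, {hi}]",
                    )
                )
    return df, errors
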