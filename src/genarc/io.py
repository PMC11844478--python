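"""Readers and writers for the pipeline's delimited-text tables.

All tables are TSV — small (hundreds of rows), hand-inspectable, and round-
trippable: numeric cells are written with 12 significant digits. Curve
coefficients and run metadata go to small structured-text (YAML) sidecars.
"""

from __future__ import annotations

import importlib.metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .fitting import ShapeCurve, evaluate_curve
from .transform import DistanceEstimate, RgRecord
from .uncertainty import CurveEnvelope

__all__ = [
    "read_rg_table",
    "write_rg_table",
    "write_bin_table",
    "write_contrasts",
    "write_distance_table",
    "write_curve",
    "read_curve_sidecar",
    "write_envelope",
    "write_metadata",
]

RG_COLUMNS = ("case_bin", "control_bin", "x_case", "x_control", "rg", "se")
_INT_COLS = {"case_bin", "control_bin", "bin", "n"}


def _fmt(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if v is None:
        return "NA"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return "NA" if np.isnan(v) else format(float(v), ".12g")
    return str(v)


def _write_frame(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def read_rg_table(path) -> list[RgRecord]:
    """Typed rg records from a TSV with the required header columns.

    ``rg`` may be blank/NA (flagged missing, not dropped); any other
    non-numeric cell in a required column raises :class:`ParseError` with
    its row number. Extra columns ride along on each record.
    """
    frame = pd.read_csv(Path(path), sep="\t", dtype=str,
                        keep_default_na=False)
    for col in RG_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"rg table is missing required column {col!r}")
    extra_cols = [c for c in frame.columns if c not in RG_COLUMNS]
    na_ok = {"rg", "se"}
    parsed: dict[str, np.ndarray] = {}
    for col in RG_COLUMNS:
        raw = frame[col].str.strip()
        blank = (raw == "") | raw.str.upper().isin(["NA", "NAN"])
        vals = pd.to_numeric(raw.mask(blank), errors="coerce")
        bad = vals.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric value {raw.iloc[row]!r} in column {col!r}, "
                f"row {row + 1}"
            )
        if blank.any() and col not in na_ok:
            row = int(np.flatnonzero(blank)[0])
            raise ParseError(f"missing value in column {col!r}, row {row + 1}")
        parsed[col] = vals.to_numpy(dtype=float)
    records = []
    for k in range(len(frame)):
        extra = tuple(
            (c, frame[c].iloc[k]) for c in extra_cols
        )
        records.append(
            RgRecord(
                case_bin=int(parsed["case_bin"][k]),
                control_bin=int(parsed["control_bin"][k]),
                x_case=parsed["x_case"][k],
                x_control=parsed["x_control"][k],
                rg=parsed["rg"][k],
                se=parsed["se"][k],
                extra=extra,
            )
        )
    return records


def write_rg_table(records: list[RgRecord], path) -> None:
    rows = []
    for r in records:
        row = dict(case_bin=r.case_bin, control_bin=r.control_bin,
                   x_case=r.x_case, x_control=r.x_control, rg=r.rg, se=r.se)
        row.update(dict(r.extra))
        rows.append(row)
    _write_frame(pd.DataFrame(rows), path)


def write_bin_table(bin_table, path) -> None:
    _write_frame(bin_table.bins, path)


def write_contrasts(contrasts, path) -> None:
    from .binning import contrasts_frame

    _write_frame(contrasts_frame(contrasts), path)


def write_distance_table(distances: list[DistanceEstimate], path) -> None:
    rows = [
        dict(case_bin=d.case_bin, control_bin=d.control_bin,
             x_case=d.x_case, x_control=d.x_control, rg=d.rg, se=d.se,
             dx=d.dx, angle=d.angle, dy=d.dy, included=d.included,
             exclusion_reason=d.exclusion_reason or "")
        for d in distances
    ]
    _write_frame(pd.DataFrame(rows), path)


def write_curve(curve: ShapeCurve, path, grid_size: int = 200) -> None:
    """Evaluated curve TSV plus a YAML coefficient sidecar (<path>.coef.yaml)."""
    grid = np.linspace(curve.domain[0], curve.domain[1], grid_size)
    _write_frame(pd.DataFrame(dict(x=grid, y_hat=evaluate_curve(curve, grid))),
                 path)
    sidecar = Path(str(path) + ".coef.yaml")
    payload = dict(
        kind=curve.kind,
        domain=[float(curve.domain[0]), float(curve.domain[1])],
        knots=None if curve.knots is None else [float(k) for k in curve.knots],
        coefficients=[float(c) for c in curve.coefficients],
        anchor=float(curve.anchor),
        x0=float(curve.x0),
    )
    sidecar.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_curve_sidecar(path) -> ShapeCurve:
    payload = yaml.safe_load(Path(path).read_text())
    return ShapeCurve(
        kind=payload["kind"],
        coefficients=tuple(payload["coefficients"]),
        domain=tuple(payload["domain"]),
        knots=None if payload["knots"] is None else tuple(payload["knots"]),
        anchor=payload["anchor"],
        x0=payload.get("x0", 0.0),
    )


def write_envelope(env: CurveEnvelope, path, curves_path=None) -> None:
    """Band TSV (x, median, lo, hi); optionally all raw resampled curves."""
    _write_frame(
        pd.DataFrame(dict(x=env.grid, median=env.median, lo=env.lower,
                          hi=env.upper)),
        path,
    )
    if curves_path is not None:
        cols = {"x": env.grid}
        for k in range(env.n_curves):
            cols[f"curve_{k + 1:03d}"] = env.curves[k]
        _write_frame(pd.DataFrame(cols), curves_path)


def write_metadata(path, **fields) -> None:
    """Run-metadata record: config echo, seeds, package versions."""
    versions = {"genarc": _version("genarc")}
    for dep in ("numpy", "scipy", "pandas"):
        versions[dep] = _version(dep)
    payload = dict(fields)
    payload["versions"] = versions
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_plain(payload), sort_keys=False))


def _version(name: str) -> str:
    try:
        return importlib.metadata.version(name)
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, np.random.SeedSequence):
        return int(obj.entropy)
    return obj
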