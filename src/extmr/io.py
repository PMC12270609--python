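"""CSV/JSON persistence for curves, fits and reports.

Curves travel as headed CSV with '.' decimals in one of three layouts:
(strain, stress), (strain, force) with an area, or (displacement, force)
with full geometry. Fits serialize to a coefficient table mirroring the
standard report layout — one row per coefficient with name, value and unit
(N/m^2 throughout) — and to JSON with full diagnostics. All numeric output
uses 17 significant digits so every file round-trips bit-exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .constitutive import Bone, Region, StressStrainCurve
from .errors import CurveParseError
from .fitting import ExtMRFit
from .prep import LoadSample, SpecimenGeometry, curve_from_records
from .regional import _fit_from_dict, _fit_to_dict

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "write_fit",
    "read_fit_json",
]

#: default CSV column roles; override via column_map={"strain": "eps", ...}
DEFAULT_COLUMNS = {
    "strain": "strain",
    "stress": "stress",
    "force": "force",
    "displacement": "displacement",
}

_FMT = "%.17g"


def _resolve_columns(df: pd.DataFrame, column_map: Optional[dict]) -> dict:
    names = dict(DEFAULT_COLUMNS)
    names.update(column_map or {})
    return {role: col for role, col in names.items() if col in df.columns}


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    series = pd.to_numeric(df[col], errors="coerce")
    bad = series.isna() & df[col].notna()
    if bad.any():
        # +2: header line plus 1-based numbering, matching the file on disk
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise CurveParseError(
            f"{path}: non-numeric value in column {col!r} at row {row}")
    if series.isna().any():
        row = int(np.flatnonzero(series.isna().to_numpy())[0]) + 2
        raise CurveParseError(f"{path}: empty cell in column {col!r} at row {row}")
    return series.to_numpy(dtype=float)


def read_curve_csv(path: Union[str, Path],
                   column_map: Optional[dict] = None,
                   geometry: Optional[SpecimenGeometry] = None,
                   *, site_label: str = "",
                   bone: Bone = Bone.UNSPECIFIED,
                   region: Region = Region.UNSPECIFIED) -> StressStrainCurve:
    """Read a curve file, dispatching on which columns are present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise CurveParseError(f"{path}: empty file") from exc
    if df.empty:
        raise CurveParseError(f"{path}: no data rows")
    cols = _resolve_columns(df, column_map)

    if "strain" in cols and "stress" in cols:
        eps = _numeric(df, cols["strain"], path)
        sigma = _numeric(df, cols["stress"], path)
        order = np.argsort(eps)
        return StressStrainCurve(eps[order], sigma[order],
                                 site_label=site_label, bone=bone,
                                 region=region)
    if "strain" in cols and "force" in cols:
        if geometry is None:
            raise CurveParseError(
                f"{path}: (strain, force) layout needs specimen geometry")
        eps = _numeric(df, cols["strain"], path)
        force = _numeric(df, cols["force"], path)
        records = [LoadSample(force=f, strain=e) for f, e in zip(force, eps)]
        return curve_from_records(records, geometry, site_label=site_label,
                                  bone=bone, region=region)
    if "displacement" in cols and "force" in cols:
        if geometry is None or geometry.gauge_length is None:
            raise CurveParseError(
                f"{path}: (displacement, force) layout needs area and "
                "gauge_length")
        disp = _numeric(df, cols["displacement"], path)
        force = _numeric(df, cols["force"], path)
        records = [LoadSample(force=f, displacement=d)
                   for f, d in zip(force, disp)]
        return curve_from_records(records, geometry, site_label=site_label,
                                  bone=bone, region=region)
    raise CurveParseError(
        f"{path}: columns {list(df.columns)} match no supported layout "
        "(need strain+stress, strain+force, or displacement+force)")


def write_curve_csv(curve: StressStrainCurve, path: Union[str, Path]) -> None:
    """Write a curve as (strain, stress) CSV; re-readable by
    :func:`read_curve_csv`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["strain", "stress"])
        for e, s in zip(curve.eps, curve.sigma_true):
            writer.writerow([_FMT % e, _FMT % s])


def write_fit(fit: ExtMRFit, path: Union[str, Path],
              format: str = "csv") -> None:
    """Persist a fit as a coefficient table (CSV) or full-diagnostics JSON.

    The CSV has one (coefficient, value, unit) row per parameter plus R^2
    and the route taken.
    """
    path = Path(path)
    if format == "csv":
        c = fit.coefficients
        rows = [
            ("B", _FMT % c.b, "N/m^2"),
            ("C1", _FMT % c.c1, "N/m^2"),
            ("C2", _FMT % c.c2, "N/m^2"),
            ("H", _FMT % c.h, "N/m^2"),
            ("lam_c", _FMT % c.lam_c, "-"),
            ("R^2", _FMT % fit.r_squared, "-"),
            ("route", fit.route.value, "-"),
        ]
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["coefficient", "value", "unit"])
            writer.writerows(rows)
    elif format == "json":
        path.write_text(json.dumps(_fit_to_dict(fit), indent=2,
                                   sort_keys=True))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_fit_json(path: Union[str, Path]) -> ExtMRFit:
    return _fit_from_dict(json.loads(Path(path).read_text()))
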