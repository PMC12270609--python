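"""Convert raw uniaxial test records into stress-strain curves.

Raw inputs come as (force, displacement) or (load, strain) columns. True
stress is the load over the deformation-adjusted cross-section,
sigma_true = F / (A * lambda); displacement converts to engineering strain
via the gauge length, eps = d / L0. Specimen geometry has no defaults —
area and gauge length are mandatory configuration for load-based inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .constitutive import Bone, Region, StressStrainCurve
from .errors import DomainError, GeometryError, InsufficientDataError

__all__ = [
    "SpecimenGeometry",
    "LoadSample",
    "strain_from_displacement",
    "true_stress_from_load",
    "curve_from_records",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cross-sectional area A [m^2] and reference gauge length L0 [m].

    The gauge length is only needed when inputs arrive as displacements.
    """

    area: float
    gauge_length: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise GeometryError(f"area must be > 0, got {self.area}")
        if self.gauge_length is not None and not self.gauge_length > 0:
            raise GeometryError(
                f"gauge_length must be > 0, got {self.gauge_length}")


@dataclass(frozen=True)
class LoadSample:
    """One raw test record: applied load F [N] with either a displacement
    [m] or a strain (dimensionless), never both."""

    force: float
    displacement: Optional[float] = None
    strain: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.displacement is None) == (self.strain is None):
            raise ValueError(
                "exactly one of displacement/strain must be given")


def strain_from_displacement(displacement, geometry: SpecimenGeometry):
    """Engineering strain eps = d / L0."""
    if geometry.gauge_length is None:
        raise GeometryError(
            "gauge_length is required to convert displacement to strain")
    out = np.asarray(displacement, dtype=float) / geometry.gauge_length
    return out if out.ndim else float(out)


def true_stress_from_load(force, area, lam):
    """True stress sigma_true = F / (A * lambda)."""
    if np.any(np.asarray(area, dtype=float) <= 0):
        raise GeometryError("area must be > 0")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("lambda must be > 0")
    out = np.asarray(force, dtype=float) / (np.asarray(area, dtype=float) * lam)
    return out if out.ndim else float(out)


def curve_from_records(records: Iterable[LoadSample],
                       geometry: SpecimenGeometry,
                       *, site_label: str = "",
                       bone: Bone = Bone.UNSPECIFIED,
                       region: Region = Region.UNSPECIFIED) -> StressStrainCurve:
    """Assemble a StressStrainCurve from raw load records.

    Records may arrive in any order (digitized curves often do); the output
    is canonical: sorted by strain, duplicate-strain readings averaged (with
    a logged warning), true stress computed from the load, Extended Mooney
    stress cached on the curve.
    """
    records = list(records)
    if not records:
        raise InsufficientDataError("no records supplied")

    has_disp = [r.displacement is not None for r in records]
    if any(has_disp) and not all(has_disp):
        raise ValueError(
            "records mix displacement and strain columns; inputs must be "
            "homogeneous")

    force = np.array([r.force for r in records], dtype=float)
    if all(has_disp):
        disp = np.array([r.displacement for r in records], dtype=float)
        eps = strain_from_displacement(disp, geometry)
    else:
        eps = np.array([r.strain for r in records], dtype=float)

    order = np.argsort(eps, kind="stable")
    eps, force = eps[order], force[order]

    uniq, inverse, counts = np.unique(eps, return_inverse=True,
                                      return_counts=True)
    if uniq.size < eps.size:
        log.warning("averaging %d duplicate-strain record(s)",
                    eps.size - uniq.size)
        force = np.bincount(inverse, weights=force) / counts
        eps = uniq

    sigma_true = true_stress_from_load(force, geometry.area, 1.0 + eps)
    return StressStrainCurve(eps, sigma_true, site_label=site_label,
                             bone=bone, region=region)
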