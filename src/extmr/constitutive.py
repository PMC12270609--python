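"""Extended Mooney-Rivlin constitutive relations for uniaxial bone loading.

The classic Mooney (reduced) stress

    sigma_Mooney = sigma_true / (lambda - 1/lambda^2)

linearises rubber-like elasticity but is singular at lambda = 1. Multiplying
by (lambda - 1) cancels that singularity algebraically and yields the
Extended Mooney stress

    sigma_Ext = sigma_true * lambda^2 / (lambda^2 + lambda + 1),

which the four-parameter model renders as a cubic polynomial, either in the
elongation ratio lambda or in engineering strain eps = lambda - 1:

    sigma_Ext = B(lambda_C - 1) + eps (C2 + C1 + H - B)
                + eps^2 (C1 + 2H) + eps^3 H

with B the stiffness (elastic-modulus scale, strictly positive), C1 a
shear-modulus-related term, C2 an internal-friction (damping) term, H the
high-strain non-linearity term, and lambda_C the critical elongation
constant (1.4655). All stresses are in N/m^2 (Pa).

This module is pure computation: transforms between the three stress
measures and forward evaluation of the model. File I/O and fitting live
elsewhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import DomainError, SingularDeformationError

__all__ = [
    "LAMBDA_C_DEFAULT",
    "Bone",
    "Region",
    "DeformationState",
    "ExtMRCoefficients",
    "StressSample",
    "StressStrainCurve",
    "mooney_stress",
    "ext_mooney_from_true",
    "true_from_ext",
    "model_sigma_ext_lambda",
    "model_sigma_ext_strain",
    "model_true_stress",
    "strain_brackets",
]

#: Critical elongation constant of the extended model (dimensionless).
LAMBDA_C_DEFAULT = 1.4655

#: |lambda - 1| below this raises SingularDeformationError in mooney_stress.
MOONEY_SINGULARITY_TOL = 1e-9


class Bone(str, enum.Enum):
    FEMUR = "femur"
    TIBIA = "tibia"
    UNSPECIFIED = "unspecified"


class Region(str, enum.Enum):
    PROXIMAL = "proximal"
    MIDDLE = "middle"
    DISTAL = "distal"
    UNSPECIFIED = "unspecified"


def _check_lam(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("elongation ratio lambda must be > 0")
    return lam


@dataclass(frozen=True)
class DeformationState:
    """A uniaxial deformation, stored as the elongation ratio lambda.

    The engineering strain is derived (``eps = lam - 1``) so the two views
    can never disagree.
    """

    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise DomainError(f"lambda must be > 0, got {self.lam}")

    @property
    def eps(self) -> float:
        return self.lam - 1.0

    @classmethod
    def from_strain(cls, eps: float) -> "DeformationState":
        return cls(lam=1.0 + eps)


@dataclass(frozen=True)
class ExtMRCoefficients:
    """The four model parameters plus the critical elongation constant.

    Parameters
    ----------
    b : float
        Stiffness coefficient B [N/m^2]; must be strictly positive.
    c1 : float
        Shear-related coefficient C1 [N/m^2]; any sign.
    c2 : float
        Internal-friction (damping) coefficient C2 [N/m^2]; any sign.
    h : float
        High-strain non-linearity coefficient H [N/m^2]; any sign.
    lam_c : float
        Critical elongation constant lambda_C (dimensionless, > 1).
    """

    b: float
    c1: float
    c2: float
    h: float
    lam_c: float = LAMBDA_C_DEFAULT

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise DomainError(f"B must be strictly positive, got {self.b}")
        if not self.lam_c > 1:
            raise DomainError(f"lambda_C must exceed 1, got {self.lam_c}")

    def as_dict(self) -> dict:
        return {"B": self.b, "C1": self.c1, "C2": self.c2, "H": self.h,
                "lam_c": self.lam_c}

    @classmethod
    def from_dict(cls, d: dict) -> "ExtMRCoefficients":
        return cls(b=d["B"], c1=d["C1"], c2=d["C2"], h=d["H"],
                   lam_c=d.get("lam_c", LAMBDA_C_DEFAULT))


@dataclass(frozen=True)
class StressSample:
    """One (strain, true stress) reading with its cached transform."""

    eps: float
    sigma_true: float
    sigma_ext: float

    def __post_init__(self) -> None:
        if not self.eps > -1:
            raise DomainError(f"strain must exceed -1, got {self.eps}")


class StressStrainCurve:
    """Ordered uniaxial stress-strain samples for one anatomical site.

    Strains are strictly increasing and unique; true stress carries the sign
    convention of the input data (no positivity is imposed: a fitted C2 < 0
    legitimately drives sigma_Ext negative over part of the range). The
    Extended Mooney stress is computed once at construction and cached.
    """

    def __init__(self, eps, sigma_true, *, site_label: str = "",
                 bone: Bone = Bone.UNSPECIFIED,
                 region: Region = Region.UNSPECIFIED) -> None:
        eps = np.asarray(eps, dtype=float)
        sigma_true = np.asarray(sigma_true, dtype=float)
        if eps.ndim != 1 or eps.shape != sigma_true.shape:
            raise ValueError("eps and sigma_true must be 1-D and equal length")
        if eps.size < 1:
            raise ValueError("a curve needs at least one sample")
        if np.any(eps <= -1):
            raise DomainError("all strains must exceed -1 (lambda > 0)")
        if np.any(np.diff(eps) <= 0):
            raise ValueError("strains must be strictly increasing and unique")
        self.eps = eps
        self.sigma_true = sigma_true
        self.sigma_ext = ext_mooney_from_true(sigma_true, 1.0 + eps)
        self.site_label = site_label
        self.bone = Bone(bone)
        self.region = Region(region)

    @classmethod
    def from_ext_mooney(cls, eps, sigma_ext, **metadata) -> "StressStrainCurve":
        """Build a curve from Extended Mooney stress values (inverts the
        transform to recover true stress)."""
        eps = np.asarray(eps, dtype=float)
        sigma_true = true_from_ext(np.asarray(sigma_ext, dtype=float), 1.0 + eps)
        return cls(eps, sigma_true, **metadata)

    def __len__(self) -> int:
        return self.eps.size

    @property
    def lam(self) -> np.ndarray:
        return 1.0 + self.eps

    @property
    def samples(self) -> list[StressSample]:
        return [StressSample(e, st, se) for e, st, se in
                zip(self.eps, self.sigma_true, self.sigma_ext)]

    def __iter__(self) -> Iterator[StressSample]:
        return iter(self.samples)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StressStrainCurve):
            return NotImplemented
        return (np.array_equal(self.eps, other.eps)
                and np.array_equal(self.sigma_true, other.sigma_true)
                and self.site_label == other.site_label
                and self.bone == other.bone and self.region == other.region)

    def __repr__(self) -> str:
        return (f"StressStrainCurve(n={len(self)}, site={self.site_label!r}, "
                f"bone={self.bone.value}, region={self.region.value})")


def mooney_stress(sigma_true, lam, *, tol: float = MOONEY_SINGULARITY_TOL):
    """Classic Mooney (reduced) stress: sigma_true / (lambda - 1/lambda^2).

    Singular at lambda = 1; use :func:`ext_mooney_from_true` for a transform
    that is regular there.
    """
    lam = _check_lam(lam)
    if np.any(np.abs(lam - 1.0) <= tol):
        raise SingularDeformationError(
            "Mooney stress is singular at lambda = 1; use the Extended "
            "Mooney transform instead")
    out = np.asarray(sigma_true, dtype=float) / (lam - 1.0 / lam**2)
    return out if out.ndim else float(out)


def ext_mooney_from_true(sigma_true, lam):
    """Extended Mooney stress: sigma_true * lambda^2 / (lambda^2 + lambda + 1).

    Equals mooney_stress * (lambda - 1) wherever both are defined, but is
    continuous at lambda = 1 with value sigma_true / 3.
    """
    lam = _check_lam(lam)
    out = np.asarray(sigma_true, dtype=float) * lam**2 / (lam**2 + lam + 1.0)
    return out if out.ndim else float(out)


def true_from_ext(sigma_ext, lam):
    """Invert the Extended Mooney transform (exact algebraic inverse)."""
    lam = _check_lam(lam)
    out = np.asarray(sigma_ext, dtype=float) * (lam**2 + lam + 1.0) / lam**2
    return out if out.ndim else float(out)


def model_sigma_ext_lambda(coeffs: ExtMRCoefficients, lam):
    """Model Extended Mooney stress as the cubic in the elongation ratio:

    [B*lam_C - C2] + lam [C2 - C1 - B] + lam^2 [C1 - H] + lam^3 [H]
    """
    lam = _check_lam(lam)
    b, c1, c2, h = coeffs.b, coeffs.c1, coeffs.c2, coeffs.h
    out = ((b * coeffs.lam_c - c2)
           + lam * (c2 - c1 - b)
           + lam**2 * (c1 - h)
           + lam**3 * h)
    return out if out.ndim else float(out)


def strain_brackets(coeffs: ExtMRCoefficients) -> tuple[float, float, float, float]:
    """The four bracketed polynomial coefficients of the strain form,
    (a0, a1, a2, a3) with sigma_Ext = a0 + a1 eps + a2 eps^2 + a3 eps^3."""
    b, c1, c2, h = coeffs.b, coeffs.c1, coeffs.c2, coeffs.h
    return (b * (coeffs.lam_c - 1.0),
            c2 + c1 + h - b,
            c1 + 2.0 * h,
            h)


def model_sigma_ext_strain(coeffs: ExtMRCoefficients, eps):
    """Model Extended Mooney stress as the cubic in engineering strain:

    [B(lam_C - 1)] + eps [C2 + C1 + H - B] + eps^2 [C1 + 2H] + eps^3 [H]

    At eps = 0 this is exactly B(lam_C - 1): the curve originates at the
    stress-axis intercept that encodes the stiffness.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= -1):
        raise DomainError("strain must exceed -1")
    a0, a1, a2, a3 = strain_brackets(coeffs)
    out = a0 + eps * (a1 + eps * (a2 + eps * a3))
    return out if out.ndim else float(out)


def model_true_stress(coeffs: ExtMRCoefficients, eps):
    """Forward model on the true-stress scale: evaluate the strain cubic and
    invert the Extended Mooney transform. At eps = 0 this equals
    3 B (lam_C - 1) — a structural feature of the model, which does not pass
    through the origin on the true-stress scale."""
    eps = np.asarray(eps, dtype=float)
    out = true_from_ext(model_sigma_ext_strain(coeffs, eps), 1.0 + eps)
    return out if np.ndim(out) else float(out)
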