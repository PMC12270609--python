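"""Synthetic stress-strain data with the structure the analysis assumes.

The study-style inputs are uniaxial curves read off published figures, so
the generator forward-models true stress from known (B, C1, C2, H) and then
emulates what figure digitization does to a curve: sampling on a fixed
strain grid, optional rounding of the stress values, and multiplicative
Gaussian noise (digitization error scales with the magnitude of the curve,
hence relative rather than additive noise).

The six-site leg preset mirrors the qualitative regional picture a strain-
gauge survey of the femur and tibia would give — stiffness B peaking in the
midshaft (cortical) sites, damping C2 and shear-related C1 peaking in
trabecular-rich sites — with coefficient magnitudes on the scale of the
reference proximal-femur fit. The preset values themselves are synthetic
fixtures for exercising the pipeline, not measurements.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np

from .constitutive import (
    Bone,
    ExtMRCoefficients,
    Region,
    StressStrainCurve,
    model_true_stress,
)
from .errors import DuplicateLabelError, GeometryError
from .prep import LoadSample, SpecimenGeometry

__all__ = [
    "NoiseModel",
    "DigitizationEmulator",
    "SiteSpec",
    "generate_curve",
    "generate_force_displacement",
    "generate_leg_dataset",
    "default_leg_preset",
    "site_seed",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement/digitization noise: none, or multiplicative Gaussian
    sigma_true -> sigma_true * (1 + eta), eta ~ N(0, sigma_rel^2)."""

    kind: str = "none"
    sigma_rel: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.sigma_rel == 0.0:
            return values
        rng = np.random.default_rng(self.seed)
        eta = rng.normal(0.0, self.sigma_rel, size=values.shape)
        return values * (1.0 + eta)


@dataclass(frozen=True)
class DigitizationEmulator:
    """Strain grid and value rounding that stand in for reading points off
    a published figure."""

    n_points: int = 60
    eps_range: tuple[float, float] = (0.05, 3.0)
    round_decimals: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        lo, hi = self.eps_range
        if not lo > -1:
            raise ValueError("eps_lo must exceed -1")
        if not hi > lo:
            raise ValueError("eps_hi must exceed eps_lo")

    def grid(self) -> np.ndarray:
        return np.linspace(*self.eps_range, self.n_points)


@dataclass(frozen=True)
class SiteSpec:
    """Metadata and ground-truth coefficients for one strain-gauge site."""

    region: Region
    bone: Bone
    coeffs: ExtMRCoefficients


def generate_curve(coeffs: ExtMRCoefficients,
                   grid: DigitizationEmulator = DigitizationEmulator(),
                   noise: NoiseModel = NoiseModel(),
                   *, site_label: str = "",
                   bone: Bone = Bone.UNSPECIFIED,
                   region: Region = Region.UNSPECIFIED) -> StressStrainCurve:
    """Forward-model a stress-strain curve from known coefficients.

    sigma_true(eps_i) = model_true_stress(coeffs, eps_i) * (1 + eta_i),
    reproducible for a fixed noise seed.
    """
    eps = grid.grid()
    sigma_true = model_true_stress(coeffs, eps)
    sigma_true = noise.apply(np.asarray(sigma_true, dtype=float))
    if grid.round_decimals is not None:
        sigma_true = np.round(sigma_true, grid.round_decimals)
    return StressStrainCurve(eps, sigma_true, site_label=site_label,
                             bone=bone, region=region)


def generate_force_displacement(coeffs: ExtMRCoefficients,
                                geometry: SpecimenGeometry,
                                grid: DigitizationEmulator = DigitizationEmulator(),
                                noise: NoiseModel = NoiseModel()
                                ) -> list[LoadSample]:
    """Raw force-displacement records, inverting the load-to-stress map:
    F = sigma_true * A * lambda, d = eps * L0."""
    if geometry.gauge_length is None:
        raise GeometryError(
            "full geometry (area and gauge_length) is required for "
            "force-displacement generation")
    eps = grid.grid()
    lam = 1.0 + eps
    sigma_true = noise.apply(
        np.asarray(model_true_stress(coeffs, eps), dtype=float))
    if grid.round_decimals is not None:
        sigma_true = np.round(sigma_true, grid.round_decimals)
    force = sigma_true * geometry.area * lam
    disp = eps * geometry.gauge_length
    return [LoadSample(force=float(f), displacement=float(d))
            for f, d in zip(force, disp)]


def site_seed(master_seed: int, label: str) -> int:
    """Stable per-site seed: mixing the master seed with a CRC32 of the
    label means adding a site never perturbs the data of existing ones."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0])


def default_leg_preset() -> dict[str, SiteSpec]:
    """Six-site femur/tibia preset (synthetic fixture).

    Constructed so the regional trend report shows midshaft-dominant
    stiffness B, distal-dominant damping C2, a proximal-femur maximum for
    the shear-related C1, and midshaft-dominant non-linearity H. Magnitudes
    follow the reference proximal-femur fit (B, H ~ 1e4-1e5 N/m^2;
    C1 ~ 1e6; C2 negative, ~ -1e6); the exact values are invented.
    """
    def spec(region, bone, b, c1, c2, h):
        return SiteSpec(region=Region(region), bone=Bone(bone),
                        coeffs=ExtMRCoefficients(b=b, c1=c1, c2=c2, h=h))

    return {
        "SG#1": spec("proximal", "tibia", 2.4e4, 1.2e6, -1.6e6, 3.0e4),
        "SG#2": spec("middle",   "tibia", 9.5e4, 0.9e6, -2.4e6, 5.5e4),
        "SG#3": spec("distal",   "tibia", 3.5e4, 1.5e6, -0.9e6, 1.2e4),
        "SG#4": spec("distal",   "femur", 3.1e4, 1.6e6, -1.0e6, 1.5e4),
        "SG#5": spec("middle",   "femur", 1.05e5, 1.0e6, -2.3e6, 5.2e4),
        "SG#6": spec("proximal", "femur", 2.8e4, 2.4e6, -1.5e6, 2.8e4),
    }


def generate_leg_dataset(site_specs: Union[Mapping[str, SiteSpec],
                                           Iterable[tuple[str, SiteSpec]],
                                           None] = None,
                         grid: DigitizationEmulator = DigitizationEmulator(),
                         noise: NoiseModel = NoiseModel(),
                         master_seed: int = 0) -> list[StressStrainCurve]:
    """One labelled curve per site, reproducible under a single master seed.

    Each site draws its noise from a seed derived stably from (master_seed,
    label); the ``seed`` field of ``noise`` is ignored here.
    """
    if site_specs is None:
        site_specs = default_leg_preset()
    items = list(site_specs.items()) if isinstance(site_specs, Mapping) \
        else list(site_specs)
    labels = [label for label, _ in items]
    if len(set(labels)) < len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise DuplicateLabelError(f"duplicate site label(s): {dup}")
    if not items:
        raise ValueError("at least one site is required")

    curves = []
    for label, spec in items:
        site_noise = NoiseModel(kind=noise.kind, sigma_rel=noise.sigma_rel,
                                seed=site_seed(master_seed, label))
        curves.append(generate_curve(spec.coeffs, grid, site_noise,
                                     site_label=label, bone=spec.bone,
                                     region=spec.region))
    return curves
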