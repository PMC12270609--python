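import numpy as np
import pytest

from extmr import (
    DigitizationEmulator,
    ExtMRCoefficients,
    NoiseModel,
    StressStrainCurve,
    generate_curve,
)

# Published reference fit for the proximal femur (N/m^2), restated here
# independently of the package constant so tests cannot drift with it.
REFERENCE = dict(b=2.410e4, c1=1.770e6, c2=-2.120e6, h=3.829e4)
LAM_C = 1.4655


@pytest.fixture
def reference_coeffs() -> ExtMRCoefficients:
    return ExtMRCoefficients(**REFERENCE)


@pytest.fixture
def reference_curve(reference_coeffs) -> StressStrainCurve:
    """Noise-free forward-model curve from the reference coefficient set,
    60 points on [0.05, 3.0]."""
    return generate_curve(reference_coeffs, DigitizationEmulator(),
                          NoiseModel())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250929)


def random_admissible_coeffs(rng, n):
    """Random coefficient sets with B > 0 and unconstrained C1, C2, H,
    spanning the magnitudes seen in bone fits."""
    out = []
    for _ in range(n):
        out.append(ExtMRCoefficients(
            b=float(10 ** rng.uniform(3, 6)),
            c1=float(rng.uniform(-1, 1) * 10 ** rng.uniform(3, 7)),
            c2=float(rng.uniform(-1, 1) * 10 ** rng.uniform(3, 7)),
            h=float(rng.uniform(-1, 1) * 10 ** rng.uniform(3, 6)),
        ))
    return out


@pytest.fixture
def window_route_curve() -> StressStrainCurve:
    """A curve whose full-range cubic has a negative strain-free term but
    whose initial window (eps <= 0.5) has a positive one: exponential
    stiffening with a small positive intercept."""
    eps = np.linspace(0.05, 3.0, 60)
    sigma_ext = 1.0e4 + 4.0e4 * (np.exp(2.0 * eps) - 1.0)
    return StressStrainCurve.from_ext_mooney(eps, sigma_ext,
                                             site_label="window-fixture")
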