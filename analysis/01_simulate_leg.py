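#!/usr/bin/env python
"""Generate the synthetic inputs for the regional analysis.

Writes, under results/curves/: one stress-strain CSV per strain-gauge site
of the six-site femur/tibia preset (2% multiplicative noise, 60 strain
points on [0.05, 3.0]) plus a manifest mapping each site to its region and
bone, and a noise-free reference curve from the published proximal-femur
coefficient set.
"""

import json
from pathlib import Path

from extmr import (
    DigitizationEmulator,
    ExtMRCoefficients,
    NoiseModel,
    generate_curve,
    generate_leg_dataset,
)
from extmr.io import write_curve_csv

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "curves"
REFERENCE = ExtMRCoefficients(b=2.410e4, c1=1.770e6, c2=-2.120e6, h=3.829e4)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    grid = DigitizationEmulator(n_points=60, eps_range=(0.05, 3.0))

    ref_curve = generate_curve(REFERENCE, grid, NoiseModel())
    write_curve_csv(ref_curve, OUT / "reference_proximal_femur.csv")

    curves = generate_leg_dataset(
        None, grid, NoiseModel("multiplicative_gaussian", 0.02),
        master_seed=SEED)
    manifest = {}
    for curve in curves:
        fname = curve.site_label.replace("#", "") + ".csv"
        write_curve_csv(curve, OUT / fname)
        manifest[curve.site_label] = {"file": fname,
                                      "region": curve.region.value,
                                      "bone": curve.bone.value}
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    print(f"wrote reference curve + {len(curves)} site curves to {OUT}")


if __name__ == "__main__":
    main()
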