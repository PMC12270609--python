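#!/usr/bin/env python
"""Assemble the per-site fits into a regional map and the trend report.

Reads the fits written by 02_fit_sites, builds the site -> (region, bone,
fit) map, and writes results/regional_map.json plus the trend report in
text, JSON and CSV (results/trend_report.*). The text report states, for
each coefficient, which region maximises it — on the synthetic preset this
reproduces the built-in orderings: stiffness B peaks in the midshaft,
damping C2 in the distal regions.
"""

import json
from pathlib import Path

from extmr import build_map, compare_regions, render_report
from extmr.io import read_fit_json

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    manifest = json.loads((ROOT / "curves" / "manifest.json").read_text())
    fits = []
    for label, meta in sorted(manifest.items()):
        stem = meta["file"].rsplit(".", 1)[0]
        fit = read_fit_json(ROOT / "fits" / f"{stem}.json")
        fits.append((label, meta["region"], meta["bone"], fit))
    rmap = build_map(fits)
    (ROOT / "regional_map.json").write_text(rmap.to_json())

    report = compare_regions(rmap)
    for fmt, ext in (("text", "txt"), ("json", "json"), ("csv", "csv")):
        (ROOT / f"trend_report.{ext}").write_text(
            render_report(report, fmt))
    print(render_report(report, "text"))


if __name__ == "__main__":
    main()
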