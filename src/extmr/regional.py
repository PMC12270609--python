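"""Regional mapping of fitted coefficients and the trend report.

Assembles per-site fits into a site -> (region, bone, fit) map and compares
regions per coefficient: arithmetic (or median) means over the sites of a
region, the argmax/argmin regions and sites, and a magnitude-spread ratio.
Region assignments are explicit user metadata carried on each entry — they
are never inferred from site numbering. Ties are reported jointly, never
broken silently.

Because C2 (and in principle C1 or H) may be negative, the reported spread
ratio is max(|mean|) / min(|mean|) over regions, which is always >= 1;
the signed per-region means are reported alongside so no sign information
is lost.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .constitutive import Bone, ExtMRCoefficients, Region
from .errors import DuplicateLabelError, SingleRegionError
from .fitting import ExtMRFit, FitRoute

__all__ = [
    "COEFFICIENT_NAMES",
    "RegionalEntry",
    "RegionalMap",
    "CoefficientTrend",
    "TrendReport",
    "build_map",
    "compare_regions",
    "render_report",
]

COEFFICIENT_NAMES = ("B", "C1", "C2", "H")

_ATTR = {"B": "b", "C1": "c1", "C2": "c2", "H": "h"}

#: relative tolerance for declaring two regional means tied
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class RegionalEntry:
    region: Region
    bone: Bone
    fit: ExtMRFit


@dataclass(frozen=True)
class RegionalMap:
    """Validated site_label -> (region, bone, fit) mapping."""

    entries: dict[str, RegionalEntry]

    def to_json(self) -> str:
        payload = {
            label: {
                "region": e.region.value,
                "bone": e.bone.value,
                "fit": _fit_to_dict(e.fit),
            }
            for label, e in self.entries.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RegionalMap":
        payload = json.loads(text)
        entries = {
            label: RegionalEntry(region=Region(d["region"]),
                                 bone=Bone(d["bone"]),
                                 fit=_fit_from_dict(d["fit"]))
            for label, d in payload.items()
        }
        return cls(entries=entries)


def _fit_to_dict(fit: ExtMRFit) -> dict:
    return {
        "coefficients": fit.coefficients.as_dict(),
        "route": fit.route.value,
        "r_squared": fit.r_squared,
        "window_eps_max": fit.window_eps_max,
        "diagnostics": fit.diagnostics,
    }


def _fit_from_dict(d: dict) -> ExtMRFit:
    return ExtMRFit(
        coefficients=ExtMRCoefficients.from_dict(d["coefficients"]),
        route=FitRoute(d["route"]),
        r_squared=d["r_squared"],
        window_eps_max=d.get("window_eps_max"),
        diagnostics=d.get("diagnostics", {}),
    )


@dataclass(frozen=True)
class CoefficientTrend:
    """Regional summary for one coefficient."""

    region_means: dict[str, float]
    argmax_regions: list[str]
    argmin_regions: list[str]
    argmax_sites: list[str]
    spread_ratio: Optional[float]  # max(|mean|)/min(|mean|); None if a mean is 0

    def is_tie(self) -> bool:
        return len(self.argmax_regions) > 1


@dataclass(frozen=True)
class TrendReport:
    trends: dict[str, CoefficientTrend]
    aggregation: str
    narrative: list[str]

    def to_json(self) -> str:
        payload = {
            "aggregation": self.aggregation,
            "narrative": self.narrative,
            "trends": {
                name: {
                    "region_means": t.region_means,
                    "argmax_regions": t.argmax_regions,
                    "argmin_regions": t.argmin_regions,
                    "argmax_sites": t.argmax_sites,
                    "spread_ratio": t.spread_ratio,
                }
                for name, t in self.trends.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrendReport":
        payload = json.loads(text)
        trends = {
            name: CoefficientTrend(
                region_means=d["region_means"],
                argmax_regions=d["argmax_regions"],
                argmin_regions=d["argmin_regions"],
                argmax_sites=d["argmax_sites"],
                spread_ratio=d["spread_ratio"],
            )
            for name, d in payload["trends"].items()
        }
        return cls(trends=trends, aggregation=payload["aggregation"],
                   narrative=payload["narrative"])


def build_map(fits: Iterable[tuple[str, Region, Bone, ExtMRFit]]) -> RegionalMap:
    """Validate (site_label, region, bone, fit) tuples into a RegionalMap."""
    entries: dict[str, RegionalEntry] = {}
    for label, region, bone, fit in fits:
        if label in entries:
            raise DuplicateLabelError(f"duplicate site label {label!r}")
        if not fit.coefficients.b > 0:
            raise ValueError(f"fit for {label!r} has non-positive B")
        entries[label] = RegionalEntry(region=Region(region), bone=Bone(bone),
                                       fit=fit)
    if not entries:
        raise ValueError("no fits supplied")
    return RegionalMap(entries=entries)


def _aggregate(values: list[float], how: str) -> float:
    if how == "mean":
        return sum(values) / len(values)
    if how == "median":
        values = sorted(values)
        n = len(values)
        mid = n // 2
        return values[mid] if n % 2 else 0.5 * (values[mid - 1] + values[mid])
    raise ValueError(f"unknown aggregation {how!r}")


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_TIE_RTOL, abs_tol=0.0)


def compare_regions(regional_map: RegionalMap,
                    aggregation: str = "mean") -> TrendReport:
    """Per-coefficient regional comparison.

    Requires at least two distinct regions. For each coefficient: regional
    aggregate (mean by default, median optionally), joint argmax/argmin
    regions (ties reported together), argmax sites, and the magnitude
    spread ratio.
    """
    regions = sorted({e.region.value for e in regional_map.entries.values()})
    if len(regions) < 2:
        raise SingleRegionError(
            f"regional comparison needs >= 2 regions, found {regions}")

    trends: dict[str, CoefficientTrend] = {}
    narrative: list[str] = []
    for name in COEFFICIENT_NAMES:
        attr = _ATTR[name]
        by_region: dict[str, list[float]] = {r: [] for r in regions}
        site_values: dict[str, float] = {}
        for label, entry in regional_map.entries.items():
            v = getattr(entry.fit.coefficients, attr)
            by_region[entry.region.value].append(v)
            site_values[label] = v
        means = {r: _aggregate(vs, aggregation) for r, vs in by_region.items()}

        vmax = max(means.values())
        vmin = min(means.values())
        argmax = sorted(r for r, v in means.items() if _close(v, vmax))
        argmin = sorted(r for r, v in means.items() if _close(v, vmin))
        smax = max(site_values.values())
        argmax_sites = sorted(l for l, v in site_values.items()
                              if _close(v, smax))
        mags = [abs(v) for v in means.values()]
        spread = (max(mags) / min(mags)) if min(mags) > 0 else None

        trends[name] = CoefficientTrend(
            region_means=means, argmax_regions=argmax, argmin_regions=argmin,
            argmax_sites=argmax_sites, spread_ratio=spread)

        if len(argmax) == len(means):
            narrative.append(f"{name}: all regions tied "
                             f"({aggregation} = {vmax:.6g} N/m^2).")
        else:
            tie = " (tie)" if len(argmax) > 1 else ""
            line = (f"{name}: highest in {', '.join(argmax)}{tie} "
                    f"({aggregation} = {vmax:.6g} N/m^2), lowest in "
                    f"{', '.join(argmin)} ({vmin:.6g} N/m^2); "
                    f"peak site(s): {', '.join(argmax_sites)}")
            if spread is not None:
                line += f"; magnitude spread x{spread:.3g}"
            narrative.append(line + ".")
    return TrendReport(trends=trends, aggregation=aggregation,
                       narrative=narrative)


def render_report(report: TrendReport, format: str = "text") -> str:
    """Render a TrendReport as plain text, JSON (lossless round trip), or
    CSV with one row per (coefficient, region)."""
    if format == "json":
        return report.to_json()
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["coefficient", "region", f"{report.aggregation}_value",
                         "is_argmax", "is_argmin"])
        for name, t in report.trends.items():
            for region in sorted(t.region_means):
                writer.writerow([
                    name, region, f"{t.region_means[region]:.12g}",
                    int(region in t.argmax_regions),
                    int(region in t.argmin_regions),
                ])
        return buf.getvalue()
    if format == "text":
        lines = [f"Regional coefficient trends ({report.aggregation} over "
                 "sites per region)", ""]
        lines.extend(report.narrative)
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")
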