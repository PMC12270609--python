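"""Pipeline configuration: every tunable in one serializable record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

from .constitutive import LAMBDA_C_DEFAULT
from .errors import DomainError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Defaults for the whole pipeline.

    lam_c : critical elongation constant (dimensionless).
    window_eps_max : strain cap for the restricted-window B estimate.
    eps_min : strain floor for the D statistic (None = smallest strictly
        positive strain in the data).
    noise_kind / sigma_rel : synthetic-noise defaults.
    n_points / eps_range : synthetic strain grid.
    area / gauge_length : specimen geometry [m^2, m]; mandatory for
        load-based inputs, no defaults.
    column_map : CSV header -> role mapping for curve files.
    master_seed : seed for all synthetic randomness.
    region_aggregation : "mean" or "median" for the trend report.
    """

    lam_c: float = LAMBDA_C_DEFAULT
    window_eps_max: float = 0.5
    eps_min: Optional[float] = None
    noise_kind: str = "none"
    sigma_rel: float = 0.0
    n_points: int = 60
    eps_range: tuple[float, float] = (0.05, 3.0)
    round_decimals: Optional[int] = None
    area: Optional[float] = None
    gauge_length: Optional[float] = None
    column_map: dict = field(default_factory=dict)
    master_seed: int = 0
    region_aggregation: str = "mean"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.lam_c > 1:
            raise DomainError("lam_c must exceed 1")
        if not self.window_eps_max > 0:
            raise DomainError("window_eps_max must be positive")
        if self.sigma_rel < 0:
            raise DomainError("sigma_rel must be >= 0")
        if self.n_points < 4:
            raise DomainError("n_points must be >= 4")
        lo, hi = self.eps_range
        if not (lo > -1 and hi > lo):
            raise DomainError("eps_range must satisfy -1 < lo < hi")
        if self.area is not None and not self.area > 0:
            raise DomainError("area must be > 0")
        if self.gauge_length is not None and not self.gauge_length > 0:
            raise DomainError("gauge_length must be > 0")
        if self.region_aggregation not in ("mean", "median"):
            raise DomainError("region_aggregation must be 'mean' or 'median'")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["eps_range"] = list(self.eps_range)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "eps_range" in d:
            d["eps_range"] = tuple(d["eps_range"])
        return cls(**d)
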