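"""Run configuration: cost constants, analysis knobs, validation, YAML I/O."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import CostModel
from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a full pipeline run.

    Defaults are the worked relative-cost constants (A=1, B=20, n=3,
    sum(m)=0.1, N_time=12), the 0-3 m surface band, the weekly-to-six-weekly
    thinning ladder with a ±5% tolerance, and the conventional alpha=0.05 /
    beta=0.2 power setting for 5% and 10% change detection.
    """

    # cost model
    A: float = 1.0
    B: float = 20.0
    n: float = 3.0
    m: tuple[float, ...] = (0.1,)
    N_time: int = 12
    # profile reduction
    depth_band: tuple[float, float] = (0.0, 3.0)
    light_variable: str = "par"
    # frequency analysis
    keep_counts: tuple[int, ...] = (24, 12, 8, 6, 5, 4)
    tolerance_percent: float = 5.0
    # precision / power
    t_mode: str = "fixed"
    target_ci_percent: float = 20.0
    alpha: float = 0.05
    beta: float = 0.2
    delta_percents: tuple[float, ...] = (5.0, 10.0)
    # integration
    min_occasions_per_station: int = 4
    # output
    out_dir: str = "monalloc_out"

    def __post_init__(self):
        try:
            self.cost_model()  # validates cost fields
        except Exception as exc:
            raise ConfigError(f"invalid cost model: {exc}") from exc
        lo, hi = self.depth_band
        if not lo < hi:
            raise ConfigError("depth_band must satisfy min < max")
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ConfigError("alpha and beta must lie in (0, 1)")
        if self.tolerance_percent <= 0 or self.target_ci_percent <= 0:
            raise ConfigError("tolerance and target CI must be > 0")
        if self.t_mode not in ("fixed", "exact_df"):
            raise ConfigError(f"unknown t_mode {self.t_mode!r}")
        if any(d <= 0 for d in self.delta_percents):
            raise ConfigError("delta percents must be > 0")

    def cost_model(self) -> CostModel:
        return CostModel(A=self.A, B=self.B, n=self.n, m=tuple(self.m), N_time=self.N_time)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("m", "depth_band", "keep_counts", "delta_percents"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("m", "depth_band", "keep_counts", "delta_percents"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
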