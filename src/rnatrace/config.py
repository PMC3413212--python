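"""Run configuration: every tunable constant with its published default.

The defaults reproduce the printed method constants (10 Å search radius,
1-7 sigma contour ladder in 0.25 sigma steps, scoring weights 5/1/1/15 and
1/10, the r(d)/z(d) regression coefficients and C1' offset, density weight
10, 5 Å base probe).  A config round-trips through JSON unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

from .builder import BuilderWeights
from .conformers import FlagThresholds
from .geometry import RegressionCoefficients
from .tracing import ScoreWeights

__all__ = ["PeakSearchConfig", "BaseFitConfig", "CurveConfig", "Config"]


@dataclass(frozen=True)
class PeakSearchConfig:
    contour_start: float = 1.0
    contour_stop: float = 7.0
    contour_step: float = 0.25
    search_radius: float = 10.0
    dedup_factor: float = 0.75  # x min voxel spacing

    def levels(self) -> tuple[float, ...]:
        out = []
        c = self.contour_start
        while c <= self.contour_stop + 1e-9:
            out.append(round(c, 6))
            c += self.contour_step
        return tuple(out)


@dataclass(frozen=True)
class BaseFitConfig:
    probe_length: float = 5.0
    w_chi: float = 1.0
    pitch_deg: float = 5.0
    spin_step_deg: float = 5.0
    n_segment_samples: int = 10


@dataclass(frozen=True)
class CurveConfig:
    floor_frac_chi: float = 0.01
    bandwidth: float | None = None  # None -> Silverman
    ensemble_seed: int = 2024


@dataclass(frozen=True)
class Config:
    peaks: PeakSearchConfig = field(default_factory=PeakSearchConfig)
    regression: RegressionCoefficients = field(default_factory=RegressionCoefficients)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    base_fit: BaseFitConfig = field(default_factory=BaseFitConfig)
    builder: BuilderWeights = field(default_factory=BuilderWeights)
    flags: FlagThresholds = field(default_factory=FlagThresholds)
    curves: CurveConfig = field(default_factory=CurveConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        kwargs = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            typ = f.default_factory  # each field is a frozen dataclass type
            sub_fields = {sf.name for sf in fields(typ)}
            clean = {
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in d[f.name].items()
                if k in sub_fields
            }
            kwargs[f.name] = typ(**clean)
        return cls(**kwargs)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "Config":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
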