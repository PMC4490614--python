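"""Single configuration surface for all thresholds and bandwidths.

Every tunable lives here with its documented default, loadable from one
YAML file, so a run's effective parameters can be snapshotted into the
run manifest.  Validation happens at construction time: a contradictory
value (e.g. a reciprocal-overlap threshold above 1) fails before any
compute starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clustering import BandwidthConfig, ThresholdMatrix
from .concordance import ConcordanceConfig
from .model import ConfigError, Precision
from .support import SupportConfig


@dataclass
class PipelineConfig:
    thresholds: ThresholdMatrix = field(default_factory=ThresholdMatrix)
    bandwidths: BandwidthConfig = field(default_factory=BandwidthConfig)
    size_min: int = 100
    size_max: int = 1_000_000
    support: SupportConfig = field(default_factory=SupportConfig)
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    annotation_min_ro: float = 0.5

    def __post_init__(self) -> None:
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ConfigError(
                f"size range [{self.size_min}, {self.size_max}] is contradictory"
            )
        if not 0.0 < self.annotation_min_ro <= 1.0:
            raise ConfigError("annotation_min_ro must be in (0, 1]")
        if self.support.size_tolerance < 0 or self.support.window < 0:
            raise ConfigError("support tolerances must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"]["pair_ro"] = {
            ",".join(sorted(k)): v for k, v in self.thresholds.pair_ro.items()
        }
        d["bandwidths"] = {
            k.value: v for k, v in self.bandwidths.bandwidths.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        thr = data.get("thresholds", {})
        if thr or "thresholds" in data:
            pairs = {
                frozenset(str(k).split(",")): float(v)
                for k, v in (thr.get("pairs") or thr.get("pair_ro") or {}).items()
            }
            kwargs["thresholds"] = ThresholdMatrix(
                default_ro=float(thr.get("default", thr.get("default_ro", 0.5))),
                outer_boundary_ro=float(
                    thr.get("outer_boundary", thr.get("outer_boundary_ro", 0.2))
                ),
                pair_ro=pairs,
            )
        if "bandwidths" in data:
            kwargs["bandwidths"] = BandwidthConfig(
                bandwidths={
                    Precision(k): int(v) for k, v in data["bandwidths"].items()
                }
            )
        for key in ("size_min", "size_max"):
            if key in data:
                kwargs[key] = int(data[key])
        if "support" in data:
            kwargs["support"] = SupportConfig(**data["support"])
        if "concordance" in data:
            kwargs["concordance"] = ConcordanceConfig(**data["concordance"])
        if "annotation" in data:
            kwargs["annotation_min_ro"] = float(
                data["annotation"].get("min_ro", 0.5)
            )
        elif "annotation_min_ro" in data:
            kwargs["annotation_min_ro"] = float(data["annotation_min_ro"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls.from_dict(data or {})
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc
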