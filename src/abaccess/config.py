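"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .access import DistanceCategories
from .errors import ParameterError
from .synthetic import SyntheticConfig

__all__ = ["PipelineConfig", "load_config"]

_DEFAULT_LAMBDA_GRID = [10.0 ** (-2 + 8 * k / 12) for k in range(13)]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, stage by stage.

    ``exposure`` switches the whole machinery between the travel-distance
    exposure and the travel-time sensitivity exposure; the corresponding
    cut points define the categorical variable.
    """

    outdir: str = "artifacts"
    seed: int = 0
    exposure: str = "distance"  # or "time"
    distance_cuts: list = field(default_factory=lambda: [5.0, 15.0, 30.0, 60.0, 120.0])
    time_cuts: list = field(default_factory=lambda: [10.0, 30.0, 60.0, 120.0, 240.0])
    synthetic: dict = field(default_factory=dict)
    adjust_tolerance: float = 0.01
    adjacency_mode: str = "contiguity"  # or "distance"
    contiguity: str = "rook"
    snap_grid: list = field(default_factory=lambda: [None])
    lambda_grid: list = field(default_factory=lambda: list(_DEFAULT_LAMBDA_GRID))
    max_iter: int = 100
    tol: float = 1e-8
    #: None = exposure-dependent default: the two distance caps for the
    #: distance exposure, actual conditions only for the time sensitivity.
    scenario_caps: list | None = None

    def __post_init__(self):
        if self.exposure not in ("distance", "time"):
            raise ParameterError("exposure must be 'distance' or 'time'")
        cuts = self.distance_cuts if self.exposure == "distance" else self.time_cuts
        if self.scenario_caps is None:
            self.scenario_caps = [None, 30.0, 5.0] if self.exposure == "distance" else [None]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ParameterError("cut points must be strictly increasing")
        for cap in self.scenario_caps:
            if cap is not None and cap not in cuts:
                raise ParameterError(f"scenario cap {cap} must be a cut point of {cuts}")

    @property
    def categories(self) -> DistanceCategories:
        cuts = self.distance_cuts if self.exposure == "distance" else self.time_cuts
        labels = (
            [f"<{_fmt(cuts[0])}"]
            + [f"{_fmt(a)}-<{_fmt(b)}" for a, b in zip(cuts, cuts[1:])]
            + [f">={_fmt(cuts[-1])}"]
        )
        return DistanceCategories(cuts=tuple(cuts), labels=tuple(labels))

    @property
    def exposure_col(self) -> str:
        return "distance_category" if self.exposure == "distance" else "time_category"

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(seed=self.seed, **self.synthetic)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ParameterError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ParameterError(f"invalid config: {exc}") from exc
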