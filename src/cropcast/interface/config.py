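"""Control-file configuration for a full pipeline run.

The control file is YAML; every parameter has a default matching the
published winter-wheat setup (cut-off June, minimum 17 yield years, top 23
regressions retained per district, up to 4 features, 99.9% screening
confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ..features import WeatherVariable

DEFAULT_OPS = {"tas": "mean", "pr": "sum", "sund": "sum"}


@dataclass
class ControlFile:
    crop: str = "winter_wheat"
    cutoff_month: int = 6
    variables: list[dict] = field(
        default_factory=lambda: [
            {"id": "tas", "units": "degC", "op": "mean"},
            {"id": "pr", "units": "mm", "op": "sum"},
            {"id": "sund", "units": "h", "op": "sum"},
        ]
    )
    season_length: int = 12
    window_min: int = 2
    window_max: int = 6
    min_years: int = 17
    k_retain: int = 23
    d_max: int = 4
    confidence: float = 0.999
    enforce_nonoverlap: bool = True
    strict: bool = True
    min_pairs: int = 8
    selection_mode: str = "global-local"  # or "local"
    fractions: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(10, 0, -1)]
    )
    global_top: int = 5
    fallback_top_m: int = 10
    target_years: list[int] | None = None
    seed: int = 0
    n_jobs: int = 1
    delimiter: str = "\t"
    weather_path: str = "weather.tsv"
    yields_path: str = "yields.tsv"
    areas_path: str = "areas.tsv"
    regions_path: str = "regions.tsv"
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if not 1 <= self.cutoff_month <= 12:
            raise ValueError("cutoff_month outside 1..12")
        if not 1 <= self.window_min <= self.window_max <= self.season_length <= 12:
            raise ValueError("bad window bounds / season length")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence outside (0, 1)")
        if self.d_max < 0 or self.k_retain < 1 or self.min_years < self.d_max + 3:
            raise ValueError("inconsistent d_max / k_retain / min_years")
        if self.selection_mode not in ("global-local", "local"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")
        for f in self.fractions:
            if not 0 < f <= 1:
                raise ValueError(f"fraction {f} outside (0, 1]")

    def weather_variables(self) -> list[WeatherVariable]:
        return [
            WeatherVariable(
                v["id"], v.get("units", ""), v.get("op", DEFAULT_OPS.get(v["id"], "mean"))
            )
            for v in self.variables
        ]

    @classmethod
    def from_yaml(cls, path) -> "ControlFile":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown control keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
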