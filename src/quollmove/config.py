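"""Study configuration.

Collar schedules, screening thresholds and availability-design constants
live in one dataclass so every stage of the pipeline reads the same
values.  Defaults follow the field protocol the pipeline models: fixes
every 30 min between 18:00 and 06:00 local (a possible 24 per night),
HDOP screening above 10, a 4.5 m/s speed ceiling, five available steps
per observed step and five available ranges per individual.

Timestamps are stored in UTC; the nocturnal window is evaluated on local
clock time through a fixed UTC offset (the Pilbara has no daylight
saving, so a constant offset is exact).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    night_start_hour: int = 18          # local clock, inclusive
    night_end_hour: int = 6             # local clock, exclusive
    fix_interval_min: float = 30.0
    max_fixes_per_night: int = 24
    hdop_max: float = 10.0
    vmax: float = 4.5                   # m/s
    n_available_steps: int = 5
    n_available_ranges: int = 5
    isopleth_level: float = 0.95
    min_burst_locations: int = 3
    burst_tolerance_min: float = 3.0
    utc_offset_hours: float = 8.0       # AWST
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.isopleth_level < 1.0:
            raise ValueError("isopleth_level must lie in (0, 1)")
        for name in ("max_fixes_per_night", "n_available_steps",
                     "n_available_ranges", "min_burst_locations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.hdop_max < 0:
            raise ValueError("hdop_max must be >= 0")

    # fixed 30-min schedule: 18:00, 18:30, ..., 05:30 -> 24 epochs
    @property
    def fixes_per_night(self) -> int:
        night_hours = (self.night_end_hour - self.night_start_hour) % 24
        return int(night_hours * 60 / self.fix_interval_min)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
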