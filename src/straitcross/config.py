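"""Pipeline configuration: one JSON document holding every tunable constant.

Defaults reproduce the analysis conditions: a 500 m coastal exclusion
buffer, 3-min subsampling, 10-min wind matching, and the wind-drop-day
rule constants.  The flapping amplitude threshold has no published value
and must be supplied (or calibrated from a labelled burst set).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .errors import InputError

AMPLITUDE_METHODS = ("peak_to_trough", "rms", "range")


@dataclass
class PipelineConfig:
    # geofence bounding box over the strait (lon/lat degrees), configurable
    geofence_lon_min: float = -6.1
    geofence_lon_max: float = -5.2
    geofence_lat_min: float = 35.75
    geofence_lat_max: float = 36.15
    # filtering
    buffer_m: float = 500.0
    subsample_s: float = 180.0
    wind_match_max_s: float = 600.0
    max_velocity_gap_s: float = 60.0
    # flapping classification
    flap_threshold_g: float = 0.5
    amplitude_method: str = "peak_to_trough"
    burst_join_max_s: float = 90.0
    # wind-drop-day rule
    drop_high_thresh_ms: float = 9.0
    drop_frac: float = 0.5
    drop_min_high_days: int = 2
    # randomness
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.buffer_m <= 0:
            raise InputError("buffer_m must be positive")
        if self.subsample_s <= 0:
            raise InputError("subsample_s must be positive")
        if self.flap_threshold_g <= 0:
            raise InputError("flap_threshold_g must be positive")
        if self.amplitude_method not in AMPLITUDE_METHODS:
            raise InputError(f"amplitude_method must be one of {AMPLITUDE_METHODS}")
        if self.geofence_lon_min >= self.geofence_lon_max:
            raise InputError("geofence lon bounds inverted")
        if self.geofence_lat_min >= self.geofence_lat_max:
            raise InputError("geofence lat bounds inverted")
        if not (0 < self.drop_frac < 1):
            raise InputError("drop_frac must be in (0, 1)")
        if self.drop_min_high_days < 1:
            raise InputError("drop_min_high_days must be >= 1")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def geofence_polygon(self):
        from .geo import bbox_polygon

        return bbox_polygon(
            self.geofence_lon_min, self.geofence_lon_max, self.geofence_lat_min, self.geofence_lat_max
        )
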