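"""Wind vector conventions and east/west regime classification.

Station records use the meteorological "direction-from" convention (the
AEMET standard): a direction of 90° means wind blowing FROM the east,
toward the west.  The (u, v) vector is the standard oceanographic/flow
convention: u positive toward east, v positive toward north.

The regime label follows the field's Levanter terminology: an "east"
(Levanter) wind blows from the east toward the Atlantic, so its east
component as defined here is +speed when dir_met = 90°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class WindVector:
    """Horizontal wind velocity: u eastward, v northward (m s⁻¹)."""

    u: float
    v: float

    @property
    def speed(self) -> float:
        return float(np.hypot(self.u, self.v))


def met_to_vector(speed: float, dir_met: float) -> WindVector:
    """Convert (speed, meteorological direction-from) to a flow vector.

    u = −speed·sin(dir), v = −speed·cos(dir): wind FROM the east (90°)
    gives u = −speed (flow toward the west).
    """
    u, v = met_to_uv(speed, dir_met)
    return WindVector(float(u), float(v))


def met_to_uv(speed, dir_met):
    """Vectorised met_to_vector returning (u, v) arrays."""
    speed = np.asarray(speed, dtype=float)
    dir_met = np.asarray(dir_met, dtype=float)
    if np.any(speed < 0):
        raise InputError("wind speed must be non-negative")
    rad = np.radians(dir_met)
    return -speed * np.sin(rad), -speed * np.cos(rad)


def uv_to_met(u, v):
    """Inverse of met_to_uv: (speed, direction-from in [0, 360))."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    dir_met = (np.degrees(np.arctan2(-u, -v))) % 360.0
    return speed, dir_met


def east_component(w: WindVector) -> float:
    """Signed east wind component: positive for a Levanter (wind from the east)."""
    return -w.u


def classify_regime(w: WindVector) -> str:
    """"east" iff the east component is strictly positive, else "west".

    A wind with an exactly zero east component (e.g. from due north) is
    assigned to "west", the benign class; a measure-zero tie rule.
    """
    return "east" if east_component(w) > 0 else "west"


def regime_from_east_components(east_comps) -> str:
    """Whole-crossing regime by majority vote over per-fix regimes.

    Ties go to the regime of the first fix.
    """
    comps = np.asarray(east_comps, dtype=float)
    if comps.size == 0:
        raise InputError("cannot classify regime of an empty crossing")
    labels = np.where(comps > 0, "east", "west")
    n_east = int((labels == "east").sum())
    n_west = labels.size - n_east
    if n_east > n_west:
        return "east"
    if n_west > n_east:
        return "west"
    return str(labels[0])
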