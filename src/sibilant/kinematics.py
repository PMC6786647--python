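"""Tongue kinematics and quasi-steady constriction flow.

The tongue tip is modelled as a rigid plate moving linearly toward the
palate: height rises from 0 to ``h_max`` at constant speed (duration
``t1``), holds at ``h_max`` for ``t2``, and descends symmetrically.  All
schedule times are expressed in units of the mean [s] duration ``t_s``.

The constriction is a rectangular channel whose open area shrinks
affinely as the tongue rises,

    A_c(h) = area_offset + channel_span · (h_max − h)   [mm²],

and the quasi-steady bulk jet speed at the constriction is

    U̅ = Q / A_c,

with Q in cm³/s and A_c in mm² giving U̅ directly in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .units import flow_over_area_to_mps

__all__ = [
    "TongueSchedule",
    "TractGeometry",
    "tongue_height",
    "ascent_duration",
    "constriction_area",
    "mean_constriction_velocity",
    "schedule_from_table",
    "load_config",
    "TABLE_SPEEDS",
    "SCHEDULE_TABLE",
]

#: Published articulation timings: speed (mm/s) -> (t1, t2, t_int), in t/t_s.
SCHEDULE_TABLE: dict[int, tuple[float, float, float]] = {
    40: (0.429, 0.714, -0.383),
    20: (0.857, 0.514, -0.760),
    10: (1.714, 0.200, -1.457),
}

TABLE_SPEEDS: tuple[int, ...] = tuple(sorted(SCHEDULE_TABLE, reverse=True))


@dataclass(frozen=True)
class TongueSchedule:
    """Trapezoidal tongue-height schedule.

    Parameters
    ----------
    speed : float
        Ascent speed of the tongue tip, mm/s.
    t_int : float
        Start of the ascent, units of t_s (negative: the tongue starts
        rising before the acoustic [s] segment).
    t1 : float
        Ascent duration, units of t_s.
    t2 : float
        Plateau duration at maximum height, units of t_s.
    h_max : float
        Maximum tongue height, mm.
    t_s : float
        Normalization duration, ms.
    descent_speed : float or None
        Descent speed, mm/s; ``None`` means symmetric (same as ascent).
    """

    speed: float
    t_int: float
    t1: float
    t2: float
    h_max: float = 3.0
    t_s: float = 175.0
    descent_speed: float | None = None

    def __post_init__(self):
        if self.speed <= 0:
            raise ParameterError(f"tongue speed must be positive, got {self.speed}")
        if self.h_max <= 0:
            raise ParameterError(f"h_max must be positive, got {self.h_max}")
        if self.t2 < 0:
            raise ParameterError(f"plateau duration t2 must be >= 0, got {self.t2}")
        if self.t_s <= 0:
            raise ParameterError(f"t_s must be positive, got {self.t_s}")
        if self.descent_speed is not None and self.descent_speed <= 0:
            raise ParameterError("descent_speed must be positive when given")

    @property
    def t1_descent(self) -> float:
        """Descent duration in units of t_s."""
        v = self.speed if self.descent_speed is None else self.descent_speed
        return ascent_duration(v, self.h_max, self.t_s)

    @property
    def plateau_start(self) -> float:
        return self.t_int + self.t1

    @property
    def plateau_end(self) -> float:
        return self.t_int + self.t1 + self.t2

    @property
    def t_end(self) -> float:
        """Time at which the tongue returns to rest, units of t_s."""
        return self.plateau_end + self.t1_descent

    def with_(self, **kw) -> "TongueSchedule":
        return replace(self, **kw)


@dataclass(frozen=True)
class TractGeometry:
    """Constriction / teeth / lip dimensions of the simplified tract.

    ``area_offset`` (8 mm²) is the residual channel area when the tongue
    is fully raised; ``channel_span`` (25 mm) is the transverse width of
    the channel that opens as the tongue descends.  ``lip_half_height``
    (R_p = 4 mm) and ``teeth_axial_gap`` (H = 1 mm) enter the vortex-ring
    amplitude estimate.
    """

    constriction_width: float = 8.0
    constriction_height_at_hmax: float = 1.0
    channel_span: float = 25.0
    area_offset: float = 8.0
    lip_half_height: float = 4.0
    teeth_axial_gap: float = 1.0
    h_max: float = 3.0

    def __post_init__(self):
        for name in (
            "constriction_width",
            "constriction_height_at_hmax",
            "channel_span",
            "area_offset",
            "lip_half_height",
            "teeth_axial_gap",
            "h_max",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")


def ascent_duration(speed: float, h_max: float = 3.0, t_s: float = 175.0) -> float:
    """Ascent duration t1 in units of t_s: travel h_max at ``speed``.

    ``speed`` in mm/s, ``h_max`` in mm, ``t_s`` in ms.
    """
    if speed <= 0:
        raise ParameterError(f"tongue speed must be positive, got {speed}")
    return (h_max / speed) / (t_s / 1000.0)


def tongue_height(t, sched: TongueSchedule):
    """Tongue height at time ``t`` (units of t_s), mm.

    Piecewise linear and continuous: zero before ``t_int``, linear rise
    to ``h_max`` over ``t1``, plateau for ``t2``, symmetric descent
    (unless ``descent_speed`` overrides), zero afterwards.  Accepts
    scalars or arrays.
    """
    knots = np.array(
        [sched.t_int, sched.plateau_start, sched.plateau_end, sched.t_end]
    )
    vals = np.array([0.0, sched.h_max, sched.h_max, 0.0])
    h = np.interp(t, knots, vals, left=0.0, right=0.0)
    return float(h) if np.isscalar(t) else h


def constriction_area(h, geom: TractGeometry | None = None):
    """Constriction flow area, mm², for tongue height ``h`` in [0, h_max]."""
    geom = geom or TractGeometry()
    harr = np.asarray(h, dtype=float)
    if np.any(harr < 0) or np.any(harr > geom.h_max):
        raise ParameterError(
            f"tongue height must lie in [0, {geom.h_max}] mm, got {h}"
        )
    a = geom.area_offset + geom.channel_span * (geom.h_max - harr)
    return float(a) if np.isscalar(h) else a


def mean_constriction_velocity(q, h, geom: TractGeometry | None = None):
    """Quasi-steady mean jet speed U̅ = Q / A_c, m/s.

    ``q`` is the volume flow rate in cm³/s, ``h`` the tongue height in mm.
    """
    qarr = np.asarray(q, dtype=float)
    if np.any(qarr < 0):
        raise ParameterError(f"flow rate must be nonnegative, got {q}")
    area = constriction_area(h, geom)
    u = flow_over_area_to_mps(qarr, np.asarray(area, dtype=float))
    return float(u) if (np.isscalar(q) and np.isscalar(h)) else u


def schedule_from_table(speed: float, **overrides) -> TongueSchedule:
    """Published articulation schedule for one of the studied tongue speeds.

    Supported speeds are 10, 20, and 40 mm/s; other values raise a
    ``LookupError`` naming the supported set.
    """
    key = int(speed) if float(speed).is_integer() else speed
    try:
        t1, t2, t_int = SCHEDULE_TABLE[key]
    except (KeyError, TypeError):
        raise LookupError(
            f"no published schedule for tongue speed {speed} mm/s; "
            f"supported speeds: {sorted(SCHEDULE_TABLE)}"
        ) from None
    return TongueSchedule(speed=float(key), t_int=t_int, t1=t1, t2=t2, **overrides)


# -- plain-text configuration -------------------------------------------------

_SCHED_KEYS = {"speed", "t_int", "t1", "t2", "h_max", "t_s", "descent_speed"}
_GEOM_KEYS = {
    "constriction_width",
    "constriction_height_at_hmax",
    "channel_span",
    "area_offset",
    "lip_half_height",
    "teeth_axial_gap",
    "h_max",
}


def load_config(path: str | Path) -> tuple[TongueSchedule, TractGeometry]:
    """Read a ``key: value`` text config; missing keys take the defaults.

    An empty file (or one containing only comments) reproduces the
    reference setup: the 40 mm/s published schedule and the default
    geometry.  A bare ``speed`` key selects the published schedule for
    that speed; explicit timing keys override individual fields.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must be a key: value mapping")
    unknown = set(data) - _SCHED_KEYS - _GEOM_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")

    speed = data.get("speed", 40)
    sched_over = {k: data[k] for k in _SCHED_KEYS & set(data) if k != "speed"}
    if int(speed) in SCHEDULE_TABLE:
        timing = {k: sched_over.pop(k) for k in ("t_int", "t1", "t2") if k in sched_over}
        sched = schedule_from_table(speed, **sched_over)
        if timing:
            sched = sched.with_(**timing)
    else:
        missing = {"t_int", "t1", "t2"} - set(sched_over)
        if missing:
            raise ParameterError(
                f"speed {speed} has no published timing; provide {sorted(missing)}"
            )
        sched = TongueSchedule(speed=float(speed), **sched_over)

    geom_over = {k: data[k] for k in _GEOM_KEYS & set(data)}
    geom = TractGeometry(**geom_over)
    return sched, geom
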