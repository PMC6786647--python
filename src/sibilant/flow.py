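"""Inlet volume-flow profile Q(t) and flow-meter record I/O.

The reference flow schedule is pinned by three measured anchors: the
flow rises from 280 cm³/s at the start of [s] (t/t_s = 0) to a maximum
of 313 cm³/s at t/t_s = 0.314, then falls to 184 cm³/s at the end of the
segment (t/t_s = 1).  Between anchors a shape-preserving monotone cubic
(PCHIP) is used so the interpolant passes through every anchor exactly
and never overshoots the anchor range on a segment; piecewise-linear
interpolation is available for bit-exact tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import FlowRecordError, ParameterError
from .units import T_S_SECONDS

__all__ = [
    "FlowProfile",
    "DEFAULT_ANCHORS",
    "flow_rate",
    "discretize_flow",
    "read_flow_record",
    "write_flow_record",
]

#: Measured anchors (t/t_s, Q cm³/s) of the reference inlet schedule.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 280.0),
    (0.314, 313.0),
    (1.0, 184.0),
)


@dataclass(frozen=True)
class FlowProfile:
    """Time-varying inlet volume flow rate.

    Parameters
    ----------
    anchors : sequence of (t, Q)
        Interpolation anchors, t in units of t_s, Q in cm³/s, with
        strictly increasing times.
    pre_onset : {"hold", "ramp"}
        Behaviour before the first anchor: hold the first anchor value
        (default; the preceding vowel keeps the flow on) or ramp
        linearly from zero over ``pre_ramp`` units of t_s.
    post_decay : float
        After the last anchor, Q decays linearly to zero over this many
        units of t_s (tail of the utterance).
    sample_rate : float
        Rate for discretized output, Hz (flow meters here log at 100 Hz).
    interpolation : {"pchip", "linear"}
    """

    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    pre_onset: str = "hold"
    pre_ramp: float = 0.3
    post_decay: float = 0.3
    sample_rate: float = 100.0
    interpolation: str = "pchip"

    def __post_init__(self):
        t = np.array([a[0] for a in self.anchors], dtype=float)
        q = np.array([a[1] for a in self.anchors], dtype=float)
        if t.size == 0:
            raise ParameterError("flow profile needs at least one anchor")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ParameterError("anchor times must be strictly increasing")
        if np.any(q < 0):
            raise ParameterError("flow rate anchors must be nonnegative")
        if self.pre_onset not in ("hold", "ramp"):
            raise ParameterError("pre_onset must be 'hold' or 'ramp'")
        if self.interpolation not in ("pchip", "linear"):
            raise ParameterError("interpolation must be 'pchip' or 'linear'")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")

    @property
    def t_first(self) -> float:
        return self.anchors[0][0]

    @property
    def t_last(self) -> float:
        return self.anchors[-1][0]


def _interior(profile: FlowProfile, t: np.ndarray) -> np.ndarray:
    ta = np.array([a[0] for a in profile.anchors], dtype=float)
    qa = np.array([a[1] for a in profile.anchors], dtype=float)
    if ta.size == 1:
        return np.full_like(t, qa[0])
    if profile.interpolation == "linear":
        return np.interp(t, ta, qa)
    return PchipInterpolator(ta, qa)(t)


def flow_rate(t, profile: FlowProfile | None = None):
    """Volume flow rate Q(t), cm³/s, for t in units of t_s.

    Exact at every anchor; shape-preserving between anchors; before the
    first anchor the profile holds (or ramps to) the first anchor value
    and after the last it decays linearly to zero.
    """
    profile = profile or FlowProfile()
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    q = np.empty_like(tarr)

    q0 = profile.anchors[0][1]
    qn = profile.anchors[-1][1]
    pre = tarr < profile.t_first
    post = tarr > profile.t_last
    mid = ~pre & ~post

    q[mid] = _interior(profile, tarr[mid])
    if profile.pre_onset == "hold":
        q[pre] = q0
    else:
        frac = (tarr[pre] - (profile.t_first - profile.pre_ramp)) / profile.pre_ramp
        q[pre] = q0 * np.clip(frac, 0.0, 1.0)
    frac = (tarr[post] - profile.t_last) / profile.post_decay
    q[post] = qn * np.clip(1.0 - frac, 0.0, 1.0)

    return float(q[0]) if np.isscalar(t) else q


def discretize_flow(
    profile: FlowProfile,
    t_start: float,
    t_end: float,
    t_s: float = T_S_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform samples of Q over [t_start, t_end] (units of t_s).

    Returns ``(times, q)`` with times in units of t_s spaced by
    ``1/sample_rate`` seconds; the first sample is at ``t_start`` and
    samples continue while they fall within the interval, i.e.
    ``floor((t_end − t_start)·t_s·rate) + 1`` samples.
    """
    if not t_end > t_start:
        raise ParameterError(
            f"empty sampling interval: t_start={t_start}, t_end={t_end}"
        )
    dt = 1.0 / (profile.sample_rate * t_s)  # sample spacing in units of t_s
    n = int(np.floor((t_end - t_start) / dt + 1e-9)) + 1
    times = t_start + dt * np.arange(n)
    return times, flow_rate(times, profile)


# -- two-column text records --------------------------------------------------

def write_flow_record(times_s, values, path: str | Path, header: str | None = None):
    """Write a two-column text record: time (s), value (native unit).

    Values are written with 17 significant digits so a read round-trips
    to the identical float64 array.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.shape != values.shape:
        raise ParameterError("times and values must have matching shapes")
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for t, v in zip(times_s, values):
            fh.write(f"{t:.17g}\t{v:.17g}\n")


def read_flow_record(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column time/value text record.

    Whitespace- or comma-separated; lines starting with ``#`` are
    comments.  Malformed rows raise :class:`FlowRecordError` with the
    offending line number; an empty record is an error.
    """
    times, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise FlowRecordError(
                    f"expected two columns, got {len(parts)}: {line!r}", lineno
                )
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise FlowRecordError(f"non-numeric row: {line!r}", lineno) from None
            times.append(t)
            values.append(v)
    if not times:
        raise FlowRecordError(f"no data rows in {path}")
    return np.array(times), np.array(values)
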