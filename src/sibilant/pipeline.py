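"""End-to-end orchestration: simulate → synthesize → analyze → estimate.

Thin composition of the other modules, shared by the command-line
interface, the examples, and the acceptance checks.  All frame-based
outputs of one analysis share the spectrogram framing exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import ParameterError
from .flow import FlowProfile, flow_rate
from .kinematics import (
    TongueSchedule,
    TractGeometry,
    constriction_area,
    mean_constriction_velocity,
    tongue_height,
)
from .signals import (
    SampledSignal,
    Spectrogram,
    detect_onset_offset,
    duration_above,
    oaspl,
    spectrogram,
)
from .vortex import VortexSoundParams, convection_speed, estimated_level_curve

__all__ = [
    "simulate_trajectory",
    "AnalysisResult",
    "analyze_recording",
    "estimate_levels",
    "record_to_signal",
]


def simulate_trajectory(
    sched: TongueSchedule,
    geom: TractGeometry | None = None,
    profile: FlowProfile | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
    n: int = 2001,
):
    """Articulation state tables: t, h, A_c, Q, U̅ on a uniform time grid.

    Times in units of t_s; the default grid spans the articulation with
    a 0.3·t_s margin on both sides.
    """
    geom = geom or TractGeometry()
    profile = profile or FlowProfile()
    lo = sched.t_int - 0.3 if t_start is None else t_start
    hi = sched.t_end + 0.3 if t_end is None else t_end
    if not lo < hi:
        raise ParameterError(f"empty simulation span [{lo}, {hi}]")
    t = np.linspace(lo, hi, n)
    h = tongue_height(t, sched)
    area = constriction_area(h, geom)
    q = flow_rate(t, profile)
    u_bar = mean_constriction_velocity(q, h, geom)
    return {"t": t, "h": h, "area": area, "q": q, "u_bar": u_bar}


@dataclass
class AnalysisResult:
    """Everything one analysis pass produces, on shared frame times."""

    spec: Spectrogram
    oaspl_db: np.ndarray
    onset_offset: tuple[float, float] | None
    frame_times: np.ndarray
    u_c: np.ndarray | None       # None when no velocity record was given
    u_bar: np.ndarray
    h: np.ndarray
    level_pairs: tuple[np.ndarray, np.ndarray, np.ndarray]  # (U̅, OASPL, phase)


def analyze_recording(
    mic: SampledSignal,
    hotwire: SampledSignal | None,
    sched: TongueSchedule,
    geom: TractGeometry | None = None,
    profile: FlowProfile | None = None,
    band: tuple[float, float] = (4000.0, 15000.0),
    f_probe: float = 9000.0,
    threshold_db: float = 15.0,
    mean_removed: bool = True,
) -> AnalysisResult:
    """Measurement analytics of one recording bundle.

    Computes the spectrogram and band-limited OASPL of the microphone
    signal, the onset/offset of the fricative event, the per-frame
    convection speed of the hot-wire record (when given, on the same
    framing), and pairs the per-frame OASPL with the modelled
    constriction velocity U̅, tagged by articulation phase.
    """
    geom = geom or TractGeometry()
    profile = profile or FlowProfile()
    spec = spectrogram(mic)
    levels = oaspl(spec, *band)
    event = detect_onset_offset(spec, f_probe=f_probe, threshold_db=threshold_db)

    u_c = None
    if hotwire is not None:
        if abs(hotwire.rate - mic.rate) > 1e-6 * mic.rate:
            raise ParameterError(
                f"sample-rate mismatch: mic {mic.rate} Hz vs hot-wire {hotwire.rate} Hz"
            )
        uc_times, u_c = convection_speed(hotwire, mean_removed=mean_removed)
        n = min(uc_times.size, spec.frame_times.size)
        u_c = u_c[:n]

    t_frames = spec.frame_times
    h = tongue_height(t_frames, sched)
    u_bar = mean_constriction_velocity(flow_rate(t_frames, profile), h, geom)

    from .vortex import tag_phases

    pairs = (u_bar, levels, tag_phases(h))
    return AnalysisResult(
        spec=spec,
        oaspl_db=levels,
        onset_offset=event,
        frame_times=t_frames,
        u_c=u_c,
        u_bar=u_bar,
        h=h,
        level_pairs=pairs,
    )


def estimate_levels(
    hotwire: SampledSignal,
    sched: TongueSchedule,
    geom: TractGeometry | None = None,
    profile: FlowProfile | None = None,
    params: VortexSoundParams | None = None,
    mean_removed: bool = True,
):
    """Vortex-ring SPL estimate along a recording, paired with U̅.

    Returns ``(u_bar, spl_db, phase_tags, frame_times)``.
    """
    geom = geom or TractGeometry()
    profile = profile or FlowProfile()
    params = params or VortexSoundParams()
    times, u_c = convection_speed(hotwire, mean_removed=mean_removed)
    h = tongue_height(times, sched)
    u_bar = mean_constriction_velocity(flow_rate(times, profile), h, geom)
    u_bar, level, tags = estimated_level_curve(u_bar, u_c, h, params)
    return u_bar, level, tags, times


def record_to_signal(times_s, values, t_s: float = 0.175) -> SampledSignal:
    """Turn a uniformly sampled two-column record into a SampledSignal.

    Times are in seconds on the normalized clock (t = 0 at the start of
    [s]); the sample rate is inferred and must be uniform to 0.1%.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.size < 2:
        raise ParameterError("need at least two samples to infer a rate")
    dt = np.diff(times_s)
    if np.max(np.abs(dt - dt[0])) > 1e-3 * dt[0]:
        raise ParameterError("record is not uniformly sampled")
    rate = 1.0 / dt[0]
    return SampledSignal(samples=values, rate=rate, t0=times_s[0] / t_s, t_s=t_s)
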