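"""Seeded generators for microphone, hot-wire, and flow-meter records.

The generators produce signals with the statistical structure the
analysis pipeline assumes, so every stage can be exercised end-to-end
without laboratory data:

* the microphone record is Gaussian noise shaped by second-order
  resonators (default peaks at 4 and 10 kHz), amplitude-modulated so the
  per-frame RMS pressure follows the vortex-ring estimate evaluated
  along the articulation, and hard-gated to a known sound span;
* the hot-wire record is a small slowly varying mean plus a zero-mean
  broadband fluctuation whose per-frame RMS follows the convection-speed
  trajectory, gated on at a known fluctuation onset that precedes the
  sound;
* the flow-meter record is the flow profile sampled at 100 Hz with
  optional Gaussian jitter.

The convection speed is modelled as a first-order lag of the
constriction velocity, U_c(t) = gain · lag(U̅; τ): with τ > 0 the lag
makes U_c smaller during tongue ascent than during descent at equal U̅
(the observed hysteresis), and with τ = 0 the asymmetry vanishes.  The
default (gain, τ) pair is calibrated once against the two measured
operating points of the 10 mm/s articulation — U_c = 3.02 m/s on ascent
and 4.54 m/s on descent, both at U̅ = 26 m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.signal import iirpeak, lfilter

from .errors import ParameterError
from .flow import FlowProfile, discretize_flow, flow_rate
from .kinematics import (
    TongueSchedule,
    TractGeometry,
    mean_constriction_velocity,
    schedule_from_table,
    tongue_height,
)
from .signals import SampledSignal
from .units import P_REF, T_S_SECONDS
from .vortex import VortexSoundParams, r_min_from_height, vortex_pressure

__all__ = [
    "SynthesisConfig",
    "FLUCTUATION_ONSETS",
    "UC_REFERENCE",
    "calibrate_convection",
    "synth_convection_speed",
    "synth_hotwire",
    "synth_microphone",
    "synth_flowmeter",
    "first_order_lag",
]

#: Measured start of hot-wire velocity fluctuation, t/t_s, per tongue speed.
FLUCTUATION_ONSETS: dict[int, float] = {40: -0.23, 20: -0.27, 10: -0.30}

#: Measured convection-speed operating points for the 10 mm/s articulation:
#: (U̅ m/s, U_c ascent m/s, U_c descent m/s).
UC_REFERENCE = (26.0, 3.02, 4.54)


@dataclass(frozen=True)
class SynthesisConfig:
    """Everything the generators need; the seed fixes all randomness."""

    sched: TongueSchedule = field(default_factory=lambda: schedule_from_table(40))
    geom: TractGeometry = field(default_factory=TractGeometry)
    profile: FlowProfile = field(default_factory=FlowProfile)
    params: VortexSoundParams = field(default_factory=VortexSoundParams)
    uc_gain: float | None = None          # None: calibrate to UC_REFERENCE
    uc_lag: float | None = None           # lag time constant, s; None: calibrate
    resonance_freqs: tuple[float, ...] = (4000.0, 10000.0)
    resonance_q: tuple[float, ...] = (25.0, 25.0)
    broadband_frac: float = 0.05          # spectrally flat part of the mic noise
    noise_floor_db: float = 20.0          # total SPL of the mic noise floor
    fluct_onset: float | None = None      # t/t_s; None: measured value per speed
    fluct_ramp: float = 0.005             # fluctuation turn-on ramp, s
    sound_span: tuple[float, float] = (0.0, 1.0)   # t/t_s extent of the [s] event
    hotwire_mean_gain: float = 0.05       # mean hot-wire component as fraction of U̅
    flow_jitter: float = 0.0              # flow-meter noise σ, cm³/s
    rate: float = 44100.0
    t_start: float | None = None          # t/t_s; None: before every onset
    t_end: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.uc_gain is not None and self.uc_gain <= 0:
            raise ParameterError("uc_gain must be positive")
        if self.uc_lag is not None and self.uc_lag < 0:
            raise ParameterError("uc_lag must be nonnegative")
        if len(self.resonance_freqs) != len(self.resonance_q):
            raise ParameterError("resonance_freqs and resonance_q lengths differ")
        for f in self.resonance_freqs:
            if not 0 < f < self.rate / 2:
                raise ParameterError(f"resonance {f} Hz outside (0, Nyquist)")
        if not self.sound_span[0] < self.sound_span[1]:
            raise ParameterError("sound_span must be an increasing interval")

    @property
    def t_s(self) -> float:
        return self.sched.t_s / 1000.0

    def resolved_fluct_onset(self) -> float:
        if self.fluct_onset is not None:
            return self.fluct_onset
        return FLUCTUATION_ONSETS.get(int(self.sched.speed), -0.25)

    def resolved_uc(self) -> tuple[float, float]:
        """(gain, lag τ in s), calibrating defaults when unset."""
        if self.uc_gain is not None and self.uc_lag is not None:
            return self.uc_gain, self.uc_lag
        gain, tau = calibrate_convection(self.profile, self.geom)
        return (
            self.uc_gain if self.uc_gain is not None else gain,
            self.uc_lag if self.uc_lag is not None else tau,
        )

    def span(self) -> tuple[float, float]:
        lo = self.t_start
        if lo is None:
            lo = min(self.sched.t_int, self.resolved_fluct_onset(),
                     self.sound_span[0]) - 0.3
        hi = self.t_end
        if hi is None:
            hi = max(self.sched.t_end, self.sound_span[1]) + 0.3
        if not lo < hi:
            raise ParameterError(f"empty synthesis span [{lo}, {hi}]")
        return lo, hi


def first_order_lag(x: np.ndarray, tau_s: float, dt_s: float) -> np.ndarray:
    """Discrete first-order low-pass: y' = (x − y)/τ, exact exponential step."""
    if tau_s == 0:
        return np.asarray(x, dtype=float).copy()
    alpha = 1.0 - np.exp(-dt_s / tau_s)
    # y[n] = (1-a) y[n-1] + a x[n]  — an IIR filter with pole (1-a)
    y = lfilter([alpha], [1.0, alpha - 1.0], x)
    # start from the signal's initial value instead of zero state
    y += (x[0] - 0.0) * (1.0 - alpha) ** np.arange(1, len(x) + 1)
    return y


def _trajectory(cfg: SynthesisConfig):
    """Per-sample articulation state over the synthesis span.

    Returns (t in t/t_s, h mm, Q cm³/s, U̅ m/s).
    """
    lo, hi = cfg.span()
    n = int(np.floor((hi - lo) * cfg.t_s * cfg.rate)) + 1
    t = lo + np.arange(n) / (cfg.rate * cfg.t_s)
    h = tongue_height(t, cfg.sched)
    q = flow_rate(t, cfg.profile)
    u_bar = mean_constriction_velocity(q, h, cfg.geom)
    return t, h, q, u_bar


def _ubar_crossings(sched, profile, geom, u_ref, rate=44100.0):
    """Times (t/t_s) at which U̅ crosses ``u_ref`` on ascent and descent."""
    t_s = sched.t_s / 1000.0
    lo, hi = sched.t_int - 0.3, sched.t_end + 0.3
    n = int((hi - lo) * t_s * rate) + 1
    t = lo + np.arange(n) / (rate * t_s)
    u = mean_constriction_velocity(flow_rate(t, profile), tongue_height(t, sched), geom)
    asc = t <= sched.plateau_start
    dsc = t >= sched.plateau_end
    if u[asc].max() < u_ref or u[dsc].max() < u_ref:
        raise ParameterError(f"U̅ never reaches {u_ref} m/s on both phases")
    t_asc = np.interp(u_ref, u[asc], t[asc])
    t_dsc = np.interp(-u_ref, -u[dsc], t[dsc])
    return t, u, float(t_asc), float(t_dsc)


@lru_cache(maxsize=8)
def calibrate_convection(
    profile: FlowProfile | None = None,
    geom: TractGeometry | None = None,
    rate: float = 44100.0,
) -> tuple[float, float]:
    """Fit the lag model to the measured convection-speed pair.

    Solves for (gain, τ) such that gain · lag(U̅; τ) equals 3.02 m/s at
    the ascent crossing of U̅ = 26 m/s and 4.54 m/s at the descent
    crossing, for the 10 mm/s articulation with the reference flow
    profile.  The ascent/descent ratio of the lagged trajectory falls
    from 1 as τ grows from 0; the smallest τ matching the measured
    ratio is bracketed on a log grid and refined by Brent's method, and
    the gain then follows linearly.
    """
    profile = profile or FlowProfile()
    geom = geom or TractGeometry()
    sched = schedule_from_table(10)
    u_ref, uc_asc, uc_dsc = UC_REFERENCE
    t, u, t_asc, t_dsc = _ubar_crossings(sched, profile, geom, u_ref, rate)
    dt = 1.0 / rate

    def lag_pair(tau):
        ul = first_order_lag(u, tau, dt)
        return np.interp(t_asc, t, ul), np.interp(t_dsc, t, ul)

    target = uc_asc / uc_dsc

    def f(tau):
        a, d = lag_pair(tau)
        return a / d - target

    grid = np.logspace(-4, 0, 41)
    fvals = [f(g) for g in grid]
    bracket = next(
        ((grid[i], grid[i + 1]) for i in range(len(grid) - 1)
         if fvals[i] * fvals[i + 1] <= 0),
        None,
    )
    if bracket is None:
        raise ParameterError(
            "lag model cannot reproduce the measured ascent/descent ratio "
            "for this flow profile and geometry"
        )
    tau = brentq(f, *bracket, xtol=1e-6)
    _, d = lag_pair(tau)
    gain = uc_dsc / d
    return float(gain), float(tau)


def synth_convection_speed(cfg: SynthesisConfig) -> SampledSignal:
    """Per-sample convection-speed trajectory U_c(t) = gain · lag(U̅; τ)."""
    t, _, _, u_bar = _trajectory(cfg)
    gain, tau = cfg.resolved_uc()
    u_c = gain * first_order_lag(u_bar, tau, 1.0 / cfg.rate)
    return SampledSignal(samples=u_c, rate=cfg.rate, t0=t[0], t_s=cfg.t_s)


def _seeded(cfg: SynthesisConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[stream])


def synth_microphone(cfg: SynthesisConfig) -> SampledSignal:
    """Synthetic far-field microphone pressure record, Pa.

    Resonator-shaped Gaussian noise (unit RMS) is modulated by the
    vortex-ring pressure envelope p′(U_c(t), R_min(h(t))) inside the
    sound span and replaced by the noise floor outside it.
    """
    t, h, _, _ = _trajectory(cfg)
    u_c = synth_convection_speed(cfg).samples
    envelope = vortex_pressure(u_c, r_min_from_height(h), cfg.params)
    gate = ((t >= cfg.sound_span[0]) & (t <= cfg.sound_span[1])).astype(float)

    rng = _seeded(cfg, 0)
    white = rng.standard_normal(t.size)
    shaped = cfg.broadband_frac * white
    for f0, q in zip(cfg.resonance_freqs, cfg.resonance_q):
        b, a = iirpeak(f0, q, fs=cfg.rate)
        shaped = shaped + lfilter(b, a, white)
    shaped /= np.sqrt(np.mean(shaped**2))

    floor_rms = P_REF * 10.0 ** (cfg.noise_floor_db / 20.0)
    floor = _seeded(cfg, 1).standard_normal(t.size) * floor_rms

    samples = shaped * envelope * gate + floor
    return SampledSignal(samples=samples, rate=cfg.rate, t0=t[0], t_s=cfg.t_s)


def synth_hotwire(cfg: SynthesisConfig) -> SampledSignal:
    """Synthetic hot-wire velocity record at the teeth gap, m/s.

    A small mean component tracks the constriction velocity; the
    zero-mean fluctuation, whose per-frame RMS follows U_c(t), switches
    on at the fluctuation onset with a short linear ramp.
    """
    t, _, _, u_bar = _trajectory(cfg)
    u_c = synth_convection_speed(cfg).samples
    onset = cfg.resolved_fluct_onset()
    ramp = cfg.fluct_ramp / cfg.t_s  # ramp duration in units of t_s
    gate = np.clip((t - onset) / max(ramp, 1e-12), 0.0, 1.0)

    fluct = _seeded(cfg, 2).standard_normal(t.size) * u_c * gate
    mean = cfg.hotwire_mean_gain * u_bar
    return SampledSignal(samples=mean + fluct, rate=cfg.rate, t0=t[0], t_s=cfg.t_s)


def synth_flowmeter(cfg: SynthesisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Flow-meter record: times (s) and flow rate (cm³/s) at 100 Hz."""
    lo, hi = cfg.span()
    times_ts, q = discretize_flow(cfg.profile, lo, hi, t_s=cfg.t_s)
    if cfg.flow_jitter > 0:
        q = q + _seeded(cfg, 3).standard_normal(q.size) * cfg.flow_jitter
        q = np.maximum(q, 0.0)
    return times_ts * cfg.t_s, q
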