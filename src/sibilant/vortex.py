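"""Vortex-ring estimate of the radiated sound amplitude.

A small vortex ring (radius R_v, core diameter δ_v) convecting at speed
U_c through the constriction/teeth region of an axisymmetric duct
radiates with pressure amplitude

    p′ = calib · ρ∞ · (R_v δ_v / R_min²) · U_c² · (R_p − R_min) / √((R_p − R_min)² + H²)

where R_min is the constriction radius, R_p the duct radius away from
the constriction, and H the axial constriction length.  The underlying
theory gives the amplitude only up to a dimensionless proportionality
constant, introduced here as ``calib`` (default 1); curve shapes are
calib-invariant, a nonunit calib only shifts levels by a constant dB.

For the simplified tract the equivalent-duct mapping is
R_min = (4 − h)/2 mm with the tongue at height h, R_p = 4 mm (half the
lip height) and H = 1 mm (teeth gap).  The convection speed U_c is
estimated from hot-wire velocity as the windowed RMS over the same
512-point frames as the spectrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, ParameterError
from .signals import (
    FRAME_LEN,
    OVERLAP,
    LEVEL_FLOOR_DB,
    SampledSignal,
    frame_hop,
    frame_times,
    _frames,
)
from .units import P_REF

__all__ = [
    "VortexSoundParams",
    "r_min_from_height",
    "vortex_pressure",
    "spl",
    "convection_speed",
    "estimated_level_curve",
    "tag_phases",
    "calibrate_to_reference",
]


@dataclass(frozen=True)
class VortexSoundParams:
    """Constants of the vortex-ring amplitude estimate (lengths in mm)."""

    rho_inf: float = 1.2     # air density, kg/m³ (not printed; standard room air)
    r_v: float = 0.1         # vortex-ring radius, mm
    delta_v: float = 0.05    # vortex core diameter, mm
    r_p: float = 4.0         # duct radius away from the constriction, mm
    h_gap: float = 1.0       # axial constriction length (teeth gap), mm
    calib: float = 1.0       # dimensionless proportionality constant

    def __post_init__(self):
        for name in ("rho_inf", "r_v", "delta_v", "r_p", "h_gap", "calib"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.r_v >= self.r_p:
            raise GeometryError("vortex radius r_v must be smaller than duct radius r_p")
        if self.delta_v >= 2 * self.r_v:
            raise GeometryError("core diameter delta_v must be < 2·r_v")

    def with_calib(self, calib: float) -> "VortexSoundParams":
        return replace(self, calib=calib)


def r_min_from_height(h):
    """Constriction radius of the equivalent duct: R_min = (4 − h)/2 mm."""
    harr = np.asarray(h, dtype=float)
    if np.any(harr < 0) or np.any(harr >= 4.0):
        raise ParameterError(
            f"tongue height must lie in [0, 4) mm for a positive radius, got {h}"
        )
    r = (4.0 - harr) / 2.0
    return float(r) if np.isscalar(h) else r


def vortex_pressure(u_c, r_min, params: VortexSoundParams | None = None):
    """Acoustic pressure amplitude, Pa, of the convecting vortex ring.

    ``u_c`` in m/s, ``r_min`` in mm.  Quadratic in U_c; vanishes when
    U_c = 0 or when the constriction opens to the full duct
    (R_min = R_p).
    """
    params = params or VortexSoundParams()
    u = np.asarray(u_c, dtype=float)
    r = np.asarray(r_min, dtype=float)
    if np.any(u < 0):
        raise ParameterError(f"convection speed must be nonnegative, got {u_c}")
    if np.any(r <= 0):
        raise ParameterError(f"constriction radius must be positive, got {r_min}")
    if np.any(r > params.r_p):
        raise GeometryError(
            f"constriction radius {r_min} mm exceeds duct radius {params.r_p} mm"
        )
    gap = params.r_p - r
    p = (
        params.calib
        * params.rho_inf
        * (params.r_v * params.delta_v / r**2)
        * u**2
        * gap
        / np.sqrt(gap**2 + params.h_gap**2)
    )
    return float(p) if (np.isscalar(u_c) and np.isscalar(r_min)) else p


def spl(p, floor_db: float = LEVEL_FLOOR_DB):
    """Sound pressure level, dB re 20 µPa; nonpositive p maps to the floor."""
    parr = np.asarray(p, dtype=float)
    out = np.full_like(parr, floor_db)
    pos = parr > 0
    out[pos] = 20.0 * np.log10(parr[pos] / P_REF)
    out = np.maximum(out, floor_db)
    return float(out) if np.isscalar(p) else out


def convection_speed(
    series: SampledSignal,
    frame_len: int = FRAME_LEN,
    overlap: float = OVERLAP,
    mean_removed: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame convection speed from a hot-wire velocity record.

    U_c is the RMS of the velocity over the same 512-point frames (30%
    overlap) used for the spectrogram, so the two series share frame
    times exactly.  By default the per-frame mean is removed first
    (fluctuation RMS); ``mean_removed=False`` gives the raw RMS.

    Returns ``(frame_times, u_c)`` with times in units of t_s.
    """
    if len(series) < frame_len:
        raise ParameterError(
            f"velocity record too short: {len(series)} samples < {frame_len}"
        )
    hop = frame_hop(frame_len, overlap)
    frames = _frames(series.samples, frame_len, hop)
    if mean_removed:
        frames = frames - frames.mean(axis=1, keepdims=True)
    u_c = np.sqrt(np.mean(frames**2, axis=1))
    times = frame_times(len(series), series.rate, series.t0, series.t_s,
                        frame_len, overlap)
    return times, u_c


def tag_phases(h_series: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
    """Label frames 'ascent' / 'plateau' / 'descent' from a tongue-height series.

    Frames before the first attainment of the maximum height are ascent,
    frames after its last attainment are descent.
    """
    h = np.asarray(h_series, dtype=float)
    if h.size == 0:
        raise ParameterError("empty height series")
    hmax = h.max()
    at_max = h >= hmax * (1 - rtol)
    first = int(np.argmax(at_max))
    last = int(len(h) - 1 - np.argmax(at_max[::-1]))
    tags = np.empty(h.size, dtype=object)
    tags[:first] = "ascent"
    tags[first : last + 1] = "plateau"
    tags[last + 1 :] = "descent"
    return tags.astype(str)


def estimated_level_curve(
    u_bar: np.ndarray,
    u_c: np.ndarray,
    h: np.ndarray,
    params: VortexSoundParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimated SPL as a function of the constriction velocity U̅.

    Per frame, the vortex-ring pressure is evaluated at (U_c, R_min(h))
    and converted to SPL; each point is paired with the frame's U̅ and
    tagged ascent/plateau/descent from the tongue height.

    Returns ``(u_bar, spl_db, phase_tags)``.
    """
    u_bar = np.asarray(u_bar, dtype=float)
    u_c = np.asarray(u_c, dtype=float)
    h = np.asarray(h, dtype=float)
    if not (u_bar.shape == u_c.shape == h.shape):
        raise ParameterError(
            f"series must share framing: lengths {u_bar.size}, {u_c.size}, {h.size}"
        )
    params = params or VortexSoundParams()
    p = vortex_pressure(u_c, r_min_from_height(h), params)
    return u_bar, spl(p), tag_phases(h)


def calibrate_to_reference(
    params: VortexSoundParams,
    u_c_ref: float,
    r_min_ref: float,
    spl_ref_db: float,
) -> VortexSoundParams:
    """One-point calibration: choose ``calib`` so the estimate matches a
    reference SPL at one (U_c, R_min) operating point."""
    base = vortex_pressure(u_c_ref, r_min_ref, params.with_calib(1.0))
    if base <= 0:
        raise ParameterError("reference operating point radiates zero pressure")
    target_p = P_REF * 10.0 ** (spl_ref_db / 20.0)
    return params.with_calib(target_p / base)
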