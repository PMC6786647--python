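"""Spectrogram, band-limited OASPL, and event statistics.

The measurement recipe: 512-point FFT frames with a Hann window and 30%
overlap (hop = round(512 · 0.7) = 358 samples).  Per-bin amplitudes are
scaled by 2/Σw (one-sided) so a bin-centred sine reports its true SPL at
its bin; band power sums divide by the window's equivalent noise
bandwidth (N·Σw²/(Σw)², 1.5 bins for Hann) so Parseval holds for both
tones and broadband noise.  Levels are dB re 20 µPa; nonpositive powers
map to a configurable floor sentinel (−300 dB by default).

Sound onset/offset is detected where the spectrogram level at the bin
nearest a probe frequency (9 kHz) exceeds a threshold (15 dB), with a
minimum run length to reject single-frame spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal.windows import hann

from .errors import ParameterError
from .units import P_REF, T_S_SECONDS

__all__ = [
    "SampledSignal",
    "Spectrogram",
    "FRAME_LEN",
    "OVERLAP",
    "frame_hop",
    "frame_times",
    "spectrogram",
    "oaspl",
    "detect_onset_offset",
    "duration_above",
    "spectrum_slice",
    "find_spectral_peaks",
    "read_wav",
    "write_wav",
    "LEVEL_FLOOR_DB",
]

FRAME_LEN = 512
OVERLAP = 0.30
LEVEL_FLOOR_DB = -300.0


@dataclass
class SampledSignal:
    """Uniformly sampled record (pressure in Pa or velocity in m/s).

    ``t0`` is the time of the first sample in units of t_s; ``t_s`` (in
    seconds) converts sample indices to that normalized clock.
    """

    samples: np.ndarray
    rate: float = 44100.0
    t0: float = 0.0
    t_s: float = T_S_SECONDS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("signal must be mono (1-D)")
        if self.rate <= 0:
            raise ParameterError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("signal contains non-finite samples")

    def times(self) -> np.ndarray:
        """Sample times in units of t_s."""
        return self.t0 + np.arange(self.samples.size) / (self.rate * self.t_s)

    def __len__(self):
        return self.samples.size


@dataclass
class Spectrogram:
    frame_times: np.ndarray      # units of t_s (frame centres)
    freqs: np.ndarray            # Hz
    levels: np.ndarray           # (n_frames, n_bins) dB re 20 µPa
    frame_len: int = FRAME_LEN
    hop: int = 358
    overlap: float = OVERLAP
    window: str = "hann"
    enbw_bins: float = 1.5       # equivalent noise bandwidth, bins
    floor_db: float = LEVEL_FLOOR_DB

    def bin_power(self) -> np.ndarray:
        """Per-bin mean-square pressure (Pa²) recovered from levels."""
        p = P_REF**2 * 10.0 ** (self.levels / 10.0)
        p[self.levels <= self.floor_db] = 0.0
        return p

    def nearest_bin(self, freq: float) -> int:
        return int(np.argmin(np.abs(self.freqs - freq)))


def frame_hop(frame_len: int = FRAME_LEN, overlap: float = OVERLAP) -> int:
    """Hop between frame starts: round(frame_len · (1 − overlap))."""
    return int(round(frame_len * (1.0 - overlap)))


def frame_times(
    n_samples: int,
    rate: float,
    t0: float = 0.0,
    t_s: float = T_S_SECONDS,
    frame_len: int = FRAME_LEN,
    overlap: float = OVERLAP,
) -> np.ndarray:
    """Centre times (units of t_s) of the analysis frames of a signal.

    Shared by the spectrogram, OASPL, and windowed-RMS convection-speed
    estimators so their frames align exactly.
    """
    hop = frame_hop(frame_len, overlap)
    n_frames = 1 + (n_samples - frame_len) // hop
    if n_frames < 1:
        raise ParameterError(
            f"signal too short: {n_samples} samples < frame length {frame_len}"
        )
    starts = hop * np.arange(n_frames)
    centres = (starts + (frame_len - 1) / 2.0) / rate
    return t0 + centres / t_s


def _frames(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + (x.size - frame_len) // hop
    idx = hop * np.arange(n_frames)[:, None] + np.arange(frame_len)[None, :]
    return x[idx]


def _power_to_db(power: np.ndarray, floor_db: float) -> np.ndarray:
    out = np.full_like(power, floor_db, dtype=float)
    pos = power > 0
    np.log10(power, where=pos, out=out)
    out[pos] = 10.0 * out[pos] - 20.0 * np.log10(P_REF)
    return np.maximum(out, floor_db)


def spectrogram(
    sig: SampledSignal,
    frame_len: int = FRAME_LEN,
    overlap: float = OVERLAP,
    floor_db: float = LEVEL_FLOOR_DB,
) -> Spectrogram:
    """Short-time spectrum of a pressure signal as per-bin SPL.

    Each frame is Hann-windowed and Fourier transformed; the one-sided
    amplitude is scaled by 2/Σw so a bin-centred sine of amplitude A
    yields a bin mean-square of A²/2 (its true power) at its bin.
    """
    if len(sig) < frame_len:
        raise ParameterError(
            f"signal too short for spectrogram: {len(sig)} < {frame_len}"
        )
    hop = frame_hop(frame_len, overlap)
    w = hann(frame_len, sym=False)
    wsum = w.sum()
    enbw = frame_len * np.sum(w**2) / wsum**2

    frames = _frames(sig.samples, frame_len, hop) * w
    spec = np.fft.rfft(frames, axis=1)
    # one-sided mean-square per bin; DC and Nyquist carry no doubling
    scale = np.full(spec.shape[1], 2.0)
    scale[0] = 1.0
    if frame_len % 2 == 0:
        scale[-1] = 1.0
    power = scale * np.abs(spec) ** 2 / wsum**2

    freqs = np.fft.rfftfreq(frame_len, d=1.0 / sig.rate)
    times = frame_times(len(sig), sig.rate, sig.t0, sig.t_s, frame_len, overlap)
    return Spectrogram(
        frame_times=times,
        freqs=freqs,
        levels=_power_to_db(power, floor_db),
        frame_len=frame_len,
        hop=hop,
        overlap=overlap,
        enbw_bins=float(enbw),
        floor_db=floor_db,
    )


def oaspl(spec: Spectrogram, f_lo: float = 4000.0, f_hi: float = 15000.0) -> np.ndarray:
    """Per-frame overall SPL over the band [f_lo, f_hi], dB re 20 µPa.

    Bin powers in the band are summed and divided by the window ENBW so
    the full-band value satisfies Parseval against the windowed frame.
    """
    if not f_lo < f_hi:
        raise ParameterError(f"need f_lo < f_hi, got {f_lo} >= {f_hi}")
    if f_hi > spec.freqs[-1] + 1e-9:
        raise ParameterError(
            f"f_hi {f_hi} exceeds Nyquist {spec.freqs[-1]:.0f} Hz"
        )
    band = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not band.any():
        raise ParameterError(f"no FFT bins in band [{f_lo}, {f_hi}] Hz")
    power = spec.bin_power()[:, band].sum(axis=1) / spec.enbw_bins
    return _power_to_db(power, spec.floor_db)


def detect_onset_offset(
    spec: Spectrogram,
    f_probe: float = 9000.0,
    threshold_db: float = 15.0,
    min_run: int = 3,
) -> tuple[float, float] | None:
    """Event extent where the level at the probe bin exceeds a threshold.

    Returns ``(t_on, t_off)`` in units of t_s — the first frame of the
    first run and the last frame of the last run of at least ``min_run``
    consecutive frames above ``threshold_db`` at the bin nearest
    ``f_probe`` — or ``None`` when no qualifying run exists.
    """
    if not 0 <= f_probe <= spec.freqs[-1]:
        raise ParameterError(f"probe frequency {f_probe} outside [0, Nyquist]")
    above = spec.levels[:, spec.nearest_bin(f_probe)] > threshold_db
    runs = _runs(above)
    runs = [(i, j) for i, j in runs if j - i >= min_run]
    if not runs:
        return None
    return float(spec.frame_times[runs[0][0]]), float(spec.frame_times[runs[-1][1] - 1])


def duration_above(
    level_series: np.ndarray,
    times: np.ndarray,
    level_db: float = 60.0,
) -> tuple[float, float] | None:
    """Extent of the longest contiguous run of a level series above a level.

    Returns ``(t_start, t_end)`` of that run (frame times), or ``None``
    if the series never exceeds ``level_db``.
    """
    level_series = np.asarray(level_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if level_series.size == 0:
        raise ParameterError("empty level series")
    if level_series.shape != times.shape:
        raise ParameterError("level series and times must have matching shapes")
    runs = _runs(level_series > level_db)
    if not runs:
        return None
    i, j = max(runs, key=lambda r: r[1] - r[0])
    return float(times[i]), float(times[j - 1])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean mask."""
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def spectrum_slice(spec: Spectrogram, t_lo: float, t_hi: float) -> np.ndarray:
    """Time-averaged per-bin SPL over frames with centres in [t_lo, t_hi].

    Averaging is done on power, then converted back to dB.
    """
    if not t_lo < t_hi:
        raise ParameterError(f"empty time window [{t_lo}, {t_hi}]")
    sel = (spec.frame_times >= t_lo) & (spec.frame_times <= t_hi)
    if not sel.any():
        raise ParameterError(
            f"window [{t_lo}, {t_hi}] contains no frames "
            f"(spectrogram spans [{spec.frame_times[0]:.3f}, {spec.frame_times[-1]:.3f}])"
        )
    mean_power = spec.bin_power()[sel].mean(axis=0)
    return _power_to_db(mean_power, spec.floor_db)


def find_spectral_peaks(
    freqs: np.ndarray,
    spectrum_db: np.ndarray,
    min_prominence: float = 6.0,
    smooth_bins: int = 3,
) -> np.ndarray:
    """Peak frequencies of a dB spectrum, in descending prominence.

    A short moving average in the power domain (``smooth_bins`` bins,
    default 3; 0 disables) suppresses single-bin periodogram noise
    before peak picking; it is symmetric, so peak locations are not
    biased.
    """
    spectrum_db = np.asarray(spectrum_db, dtype=float)
    if smooth_bins > 1:
        power = 10.0 ** (spectrum_db / 10.0)
        kern = np.ones(smooth_bins) / smooth_bins
        spectrum_db = 10.0 * np.log10(np.convolve(power, kern, mode="same"))
    idx, props = _scipy_find_peaks(spectrum_db, prominence=min_prominence)
    order = np.argsort(props["prominences"])[::-1]
    return np.asarray(freqs)[idx[order]]


# -- WAV I/O ------------------------------------------------------------------

def read_wav(path: str | Path, t0: float = 0.0, t_s: float = T_S_SECONDS) -> SampledSignal:
    """Read a mono WAV file into a :class:`SampledSignal`.

    Integer PCM (16/24/32-bit) is rescaled to [−1, 1); float data is
    taken verbatim (the synthetic generator writes pressures in Pa as
    float32).
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ParameterError(f"{path}: expected mono WAV, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(float)
    return SampledSignal(samples=data, rate=float(rate), t0=t0, t_s=t_s)


def write_wav(sig: SampledSignal, path: str | Path, dtype: str = "float32"):
    """Write a signal as a mono WAV file (float32 by default, or pcm16)."""
    if dtype == "float32":
        wavfile.write(str(path), int(sig.rate), sig.samples.astype(np.float32))
    elif dtype == "pcm16":
        peak = np.max(np.abs(sig.samples)) or 1.0
        scaled = np.round(sig.samples / peak * 32767).astype(np.int16)
        wavfile.write(str(path), int(sig.rate), scaled)
    else:
        raise ParameterError(f"unsupported WAV dtype {dtype!r}")
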