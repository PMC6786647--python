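import numpy as np
import pytest
from scipy.signal.windows import hann

from sibilant import (
    ParameterError,
    SampledSignal,
    detect_onset_offset,
    duration_above,
    find_spectral_peaks,
    oaspl,
    read_wav,
    spectrogram,
    spectrum_slice,
    write_wav,
)
from sibilant.signals import FRAME_LEN, _frames, frame_hop, frame_times
from sibilant.units import P_REF

RATE = 44100.0
HOP = frame_hop()


def bin_freq(k: int) -> float:
    return k * RATE / FRAME_LEN


def sine(freq, amp, n=44100, rate=RATE, t0=0.0):
    t = np.arange(n) / rate
    return SampledSignal(amp * np.sin(2 * np.pi * freq * t), rate=rate, t0=t0)


def test_hop_is_30_percent_overlap():
    assert HOP == round(FRAME_LEN * 0.7) == 358


def test_bin_centred_sine_reports_true_spl_at_its_bin():
    # calibration tone at the FFT bin nearest 9 kHz
    k = round(9000 * FRAME_LEN / RATE)
    amp = 0.02
    spec = spectrogram(sine(bin_freq(k), amp))
    true_spl = 20 * np.log10(amp / np.sqrt(2) / P_REF)
    err = np.abs(spec.levels[:, k] - true_spl)
    assert err.max() < 0.5


def test_all_zero_signal_sits_at_floor():
    spec = spectrogram(SampledSignal(np.zeros(4096)))
    assert np.all(spec.levels == spec.floor_db)
    assert np.all(oaspl(spec) == spec.floor_db)


def test_white_noise_mean_spectrum_is_flat(rng):
    spec = spectrogram(SampledSignal(rng.standard_normal(176400) * 0.01))
    mean_db = spectrum_slice(spec, spec.frame_times[0], spec.frame_times[-1])
    # compare band averages across the interior (skip DC/Nyquist edges)
    interior = mean_db[5:-5]
    thirds = np.array_split(interior, 3)
    means = [t.mean() for t in thirds]
    assert max(means) - min(means) < 0.5


def test_spectrogram_rejects_short_signal():
    with pytest.raises(ParameterError):
        spectrogram(SampledSignal(np.zeros(FRAME_LEN - 1)))


def test_full_band_oaspl_satisfies_windowed_parseval(rng):
    x = rng.standard_normal(44100) * 0.01
    sig = SampledSignal(x)
    spec = spectrogram(sig)
    full = oaspl(spec, 0.0, RATE / 2)
    w = hann(FRAME_LEN, sym=False)
    frames = _frames(x, FRAME_LEN, HOP)
    td = 10 * np.log10(np.sum((frames * w) ** 2, axis=1) / np.sum(w**2) / P_REF**2)
    assert np.max(np.abs(full - td)) < 0.5
    # and the unweighted frame SPL agrees statistically
    raw = 10 * np.log10(np.mean(frames**2, axis=1) / P_REF**2)
    assert abs(np.mean(full - raw)) < 0.2


def test_single_in_band_tone_oaspl_equals_tone_spl():
    amp = 0.05
    spec = spectrogram(sine(bin_freq(104), amp))
    true_spl = 20 * np.log10(amp / np.sqrt(2) / P_REF)
    assert np.max(np.abs(oaspl(spec) - true_spl)) < 0.5
    # worst-case half-bin offset tone: band power sum is scallop-free
    spec2 = spectrogram(sine(bin_freq(104) + RATE / FRAME_LEN / 2, amp))
    assert np.max(np.abs(oaspl(spec2) - true_spl)) < 0.5


def test_out_of_band_tone_stays_at_floor():
    amp = 0.05
    spec = spectrogram(sine(2000.0, amp))
    # 2 kHz tone energy in the 4-15 kHz band is only window-sidelobe
    # leakage, at least 80 dB below the tone's own level
    tone_spl = 20 * np.log10(amp / np.sqrt(2) / P_REF)
    assert np.all(oaspl(spec) < tone_spl - 80)


def test_two_equal_tones_add_3dB():
    amp = 0.02
    one = spectrogram(sine(bin_freq(104), amp))
    t = np.arange(44100) / RATE
    two = spectrogram(
        SampledSignal(
            amp * np.sin(2 * np.pi * bin_freq(104) * t)
            + amp * np.sin(2 * np.pi * bin_freq(144) * t)
        )
    )
    assert np.mean(oaspl(two)) - np.mean(oaspl(one)) == pytest.approx(3.01, abs=0.05)


def test_oaspl_band_validation(rng):
    spec = spectrogram(SampledSignal(rng.standard_normal(2048)))
    with pytest.raises(ParameterError):
        oaspl(spec, 8000.0, 4000.0)
    with pytest.raises(ParameterError):
        oaspl(spec, 4000.0, 30000.0)


def _burst_signal(k1, k2, n_frames=40, amp=0.05, t0=0.0, seed=0):
    """Noise burst occupying analysis frames [k1, k2] exactly."""
    n = FRAME_LEN + (n_frames - 1) * HOP
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    lo = k1 * HOP
    hi = k2 * HOP + FRAME_LEN
    x[lo:hi] = rng.standard_normal(hi - lo) * amp
    return SampledSignal(x, rate=RATE, t0=t0)


def test_silence_gives_no_event():
    spec = spectrogram(SampledSignal(np.zeros(8192)))
    assert detect_onset_offset(spec) is None


def test_burst_onset_offset_recovered_within_one_hop():
    k1, k2 = 12, 30
    sig = _burst_signal(k1, k2)
    spec = spectrogram(sig)
    event = detect_onset_offset(spec)
    assert event is not None
    t_on, t_off = event
    hop_ts = HOP / RATE / sig.t_s + 1e-12
    assert abs(t_on - spec.frame_times[k1]) <= hop_ts
    assert abs(t_off - spec.frame_times[k2]) <= hop_ts


def test_min_run_rejects_short_spike():
    # a 50-sample impulse touches at most two overlapping frames
    n = FRAME_LEN + 39 * HOP
    x = np.zeros(n)
    x[10 * HOP + 200 : 10 * HOP + 250] = np.random.default_rng(0).standard_normal(50)
    spec = spectrogram(SampledSignal(x))
    assert detect_onset_offset(spec, min_run=3) is None
    assert detect_onset_offset(spec, min_run=1) is not None


def test_event_detection_invariant_to_time_shift():
    a = _burst_signal(12, 30, t0=0.0)
    b = _burst_signal(12, 30, t0=-0.4)
    ev_a = detect_onset_offset(spectrogram(a))
    ev_b = detect_onset_offset(spectrogram(b))
    assert ev_a[0] - ev_b[0] == pytest.approx(0.4, abs=1e-9)
    assert ev_a[1] - ev_b[1] == pytest.approx(0.4, abs=1e-9)


def test_duration_above_constant_series():
    t = np.linspace(0, 1, 50)
    full = duration_above(np.full(50, 70.0), t, 60.0)
    assert full == (t[0], t[-1])
    assert duration_above(np.full(50, 50.0), t, 60.0) is None
    with pytest.raises(ParameterError):
        duration_above(np.array([]), np.array([]))


def test_duration_above_longest_run_of_a_hump():
    t = np.linspace(0, 1, 101)
    series = 70 - 80 * (t - 0.5) ** 2  # above 60 dB for |t-0.5| < 0.354
    lo, hi = duration_above(series, t, 60.0)
    assert lo == pytest.approx(0.5 - np.sqrt(10 / 80), abs=0.011)
    assert hi == pytest.approx(0.5 + np.sqrt(10 / 80), abs=0.011)


def test_spectrum_slice_and_peaks_pure_tone():
    spec = spectrogram(sine(bin_freq(104), 0.02))
    mean_db = spectrum_slice(spec, spec.frame_times[0], spec.frame_times[-1])
    peaks = find_spectral_peaks(spec.freqs, mean_db, min_prominence=20.0)
    assert peaks.size >= 1
    assert abs(peaks[0] - bin_freq(104)) <= RATE / FRAME_LEN


def test_white_noise_has_no_prominent_peaks(rng):
    spec = spectrogram(SampledSignal(rng.standard_normal(88200) * 0.01))
    mean_db = spectrum_slice(spec, spec.frame_times[0], spec.frame_times[-1])
    assert find_spectral_peaks(spec.freqs, mean_db, min_prominence=10.0).size == 0


def test_spectrum_slice_empty_window_rejected(rng):
    spec = spectrogram(SampledSignal(rng.standard_normal(4096)))
    with pytest.raises(ParameterError):
        spectrum_slice(spec, 10.0, 11.0)
    with pytest.raises(ParameterError):
        spectrum_slice(spec, 0.5, 0.1)


def test_frame_times_are_shared_and_shift_with_t0(rng):
    x = rng.standard_normal(5000)
    a = SampledSignal(x, t0=0.0)
    b = SampledSignal(x, t0=-1.0)
    ta = frame_times(len(a), a.rate, a.t0, a.t_s)
    tb = frame_times(len(b), b.rate, b.t0, b.t_s)
    assert np.allclose(ta - tb, 1.0)
    assert np.array_equal(spectrogram(a).frame_times, ta)


def test_wav_roundtrip_float32(tmp_path, rng):
    sig = SampledSignal(rng.standard_normal(3000).astype(np.float32).astype(float))
    path = tmp_path / "x.wav"
    write_wav(sig, path)
    back = read_wav(path)
    assert back.rate == sig.rate
    assert np.allclose(back.samples, sig.samples, atol=1e-7)


def test_wav_pcm16_read_scales_to_unit_range(tmp_path, rng):
    sig = SampledSignal(np.sin(np.linspace(0, 20, 3000)))
    path = tmp_path / "x16.wav"
    write_wav(sig, path, dtype="pcm16")
    back = read_wav(path)
    assert np.max(np.abs(back.samples)) <= 1.0
    assert np.corrcoef(back.samples, sig.samples)[0, 1] > 0.9999
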