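# Methods

## Articulation model

The tongue-height trajectory is a trapezoid in normalized time t/t_s
(t_s = 175 ms): zero before `t_int`, a linear ascent of duration
`t1 = h_max / (speed · t_s)`, a plateau of duration `t2` at
h_max = 3 mm, and a linear descent. The three studied schedules
(10/20/40 mm/s) carry tabulated `(t1, t2, t_int)`; `t1` recomputed from
the speed agrees with the tabulated value to three decimals, and the
plateau instants `t_int + t1` and `t_int + t1 + t2` round to the
published intervals (0.05–0.76, 0.10–0.61, 0.26–0.46).

Only ascent speeds are tabulated; the descent is taken at the same
magnitude (the recorded trajectories look symmetric), with
`descent_speed` exposed for asymmetric experiments.

Heights outside [0, h_max] passed to the area formula raise an error
rather than clamping — a schedule that produces them is a bug worth
surfacing. Units are fixed per quantity (mm, mm², cm³/s, m/s) with the
single conversion — cm³/s over mm² is already m/s — written out in
`units.py` so the cancellation is deliberate.

## Flow profile

Q(t) is pinned by three anchors (280 cm³/s at 0, 313 at 0.314, 184
at 1, in units of t_s) and interpolated with a shape-preserving
monotone cubic (PCHIP), which passes through the anchors exactly and
cannot overshoot the anchor range on a segment; piecewise-linear
interpolation is available for bit-exact tests. Before the first
anchor the profile holds the first value (the preceding vowel keeps the
flow on; a linear ramp is available), and after the last anchor it
decays linearly to zero over 0.3 t_s — both are plumbing for synthetic
tails, not measured behaviour, and only the anchor-pinned interior is
used in any quantitative claim.

## Vortex-ring amplitude estimate

The estimate is implemented exactly as stated under the model section
of the README, with one addition: the underlying theory fixes the
amplitude only up to proportionality, so a dimensionless `calib`
(default 1) multiplies the pressure. All curve *shapes* and level
*differences* are calib-invariant (ΔSPL = 40·log₁₀ of the U_c ratio);
`calibrate_to_reference` performs an optional one-point match when
absolute overlay on measured levels is wanted. ρ∞ defaults to
1.2 kg/m³ (room air; not a measured value here) and is configurable.

U_c is the per-frame RMS of hot-wire velocity on the same 512-point,
30 %-overlap framing as the spectrogram, so convection-speed and level
series share timestamps exactly. The RMS is computed on the
mean-removed frame by default — the tabulated U_c values (3–4.5 m/s)
are far below plausible jet mean speeds, so they must be fluctuation
levels — with `mean_removed=False` available since the convention is
not stated.

## Spectrogram and OASPL conventions

Frames are 512 samples, Hann-windowed, hopped by
round(512 · 0.7) = 358 samples. Per-bin one-sided amplitudes are
scaled by 2/Σw, so a bin-centred sine reports its true SPL at its bin;
band power sums divide by the window's equivalent noise bandwidth
(1.5 bins for Hann), which makes the full-band sum satisfy Parseval
against the windowed frame to machine precision and — a convenient
Hann property — makes a tone's band-summed power scallop-free to
~1e-10 dB at any bin offset. Nonpositive powers map to a −300 dB
sentinel instead of failing, so whole-trajectory curves stay plottable.

Single-bin tone levels do scallop (up to ~1.4 dB at a half-bin offset
for Hann); single-bin calibration statements therefore refer to a tone
at the bin centre nearest the nominal frequency (8958.98 Hz for the
"9 kHz" bin).

Event detection thresholds the level at the bin nearest 9 kHz at 15 dB
and requires a minimum run of 3 frames to reject isolated spikes. The
absolute meaning of the 15 dB threshold depends on the rendering of the
original spectrograms, which is not fully specified; both the probe
frequency and threshold are configurable. Onset/offset precision is
bounded by one window half-length (< one hop), since only frames
overlapping a signal edge can cross the threshold.

## Convection-speed lag model (synthetic data)

The mapping from U̅ to U_c is known only at two measured operating
points (ascent 3.02 m/s, descent 4.54 m/s, both at U̅ = 26 m/s for the
10 mm/s schedule). The generator models it as a first-order lag,
`U_c = gain · lag(U̅; τ)` — the simplest mechanism that produces the
observed descent-over-ascent hysteresis and collapses to
proportionality at τ = 0. The default `(gain, τ)` pair is calibrated
once against both points: the ascent/descent ratio of the lagged
trajectory is matched by bracketing the smallest crossing on a log grid
in τ and refining with Brent's method (the ratio is not globally
monotone in τ), giving gain ≈ 0.141 and τ ≈ 10.3 ms. The model is a
stand-in for unknown physics; its parameters are exposed, not asserted.

## Synthetic generator

The microphone record is Gaussian white noise passed through
second-order peaking resonators at 4 and 10 kHz (matching the spectral
peaks of the physical model), normalized to unit RMS, multiplied by the
vortex-ring pressure envelope p′(U_c(t), R_min(h(t))) with calib = 1,
hard-gated to the known sound span (default t/t_s ∈ [0, 1]), and summed
with a white noise floor (20 dB SPL total). The resonator quality
factor defaults to Q = 25 per peak: narrow enough that the peak
frequencies are statistically localizable to one FFT bin from records
of this length, which is the recovery contract the tests check. The
hot-wire record is a small mean component (5 % of U̅ — deliberately
small so its within-frame slope does not leak into mean-removed frame
RMS) plus a zero-mean fluctuation scaled per-sample by U_c(t) and gated
on at the measured fluctuation onset (−0.23/−0.27/−0.30 t/t_s by
speed) with a 5 ms ramp. The flow-meter record samples Q(t) at 100 Hz
with optional Gaussian jitter (default σ = 0). All randomness derives
from one seed through independent spawned streams, so every output is
bit-reproducible per configuration.

What the generator does *not* emulate: physically faithful turbulence
spectra and intermittency, room and baffle acoustics, tract resonant
filtering beyond two fixed peaks, sensor noise floors other than white,
or the absolute 60–65 dB OASPL levels of the laboratory recordings
(synthetic absolute levels are internally consistent with calib = 1 but
not claimed to match a real microphone at 30 cm). Passing end-to-end
tests therefore demonstrates that the analysis recovers what the
generator injects under realistic statistical structure — not that it
would produce identical numbers on laboratory data.

## Problem sizes and numerical choices

Synthetic records are generated at the full 44.1 kHz over the natural
span of each articulation (roughly 0.4–0.9 s), which keeps every test
and the reproduction script to seconds of runtime. The flow-profile
scan behind the maximum-U̅ figure uses 20 001 points over the anchored
interval. Dense-grid monotonicity checks use 100–200 points.
Interpolation onto level curves at U̅ = 26 m/s uses the monotone ascent
(descent) branches only. Ties in event runs resolve to the first run
(onset) and last run (offset) of qualifying length.

## Known limitations

* The amplitude estimate is quasi-steady and amplitude-only: no
  frequency content is predicted, no far-field propagation or distance
  dependence is modelled, and the bent pharynx and 3-D duct geometry
  are reduced to an equivalent axisymmetric channel.
* The lag model for U_c is constrained by two measured points; its
  extrapolation to other speeds and flow schedules is a modelling
  choice.
* The 15 dB onset threshold is an absolute per-bin SPL here; comparing
  against detectors defined on differently normalized spectrograms
  requires adjusting the threshold.
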