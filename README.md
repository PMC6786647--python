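# sibilant

Articulation-driven aeroacoustics of the fricative [s]: a quasi-steady
tongue-kinematics/flow model, a vortex-ring estimate of the radiated
sound amplitude, the signal statistics that connect microphone and
hot-wire recordings back to the articulation, and a seeded synthetic
generator so the whole pipeline is testable end to end.

It is written for speech-production and bioacoustics researchers who
work with simplified physical models of the vocal tract: people who
drive a mechanical tongue through a constriction, blow controlled air
through it, and ask how the timing of tongue movement shapes the
turbulent hiss of [s].

## The model

**Articulation.** The tongue tip moves linearly: height rises from 0 to
h_max = 3 mm at a constant speed (10–40 mm/s), holds for a plateau, and
descends symmetrically. Times are normalized by the mean [s] duration
t_s = 175 ms. The constriction area shrinks affinely with tongue height,

    A_c(h) = 8 + 25 · (3 − h)   [mm²],

and the quasi-steady jet speed at the constriction is **U̅ = Q / A_c**,
with the inlet volume flow Q following its measured schedule
(280 cm³/s at t/t_s = 0, peak 313 cm³/s at t/t_s = 0.314, 184 cm³/s at
t/t_s = 1).

**Sound amplitude.** The radiated pressure is estimated from a vortex
ring (radius R_v = 0.1 mm, core δ_v = 0.05 mm) convecting at speed U_c
through an equivalent axisymmetric duct (constriction radius
R_min = (4 − h)/2 mm, duct radius R_p = 4 mm, axial length H = 1 mm):

    p′ = calib · ρ∞ · (R_v δ_v / R_min²) · U_c² · (R_p − R_min) / √((R_p − R_min)² + H²)

U_c is measured as the windowed RMS of hot-wire velocity over the same
512-point frames as the spectrogram. Because p′ ∝ U_c², level
differences are 40·log₁₀ of the U_c ratio — doubling U_c adds 12.04 dB.

**Signal statistics.** Spectrograms use 512-point Hann-windowed FFT
frames with 30 % overlap; levels are dB re 20 µPa. The overall SPL
(OASPL) is power-summed over 4–15 kHz per frame. The onset/offset of
the fricative event is where the spectrogram level at the 9 kHz bin
exceeds 15 dB.

## Worked example

```
$ python examples/03_vortex_sound_estimate.py
U_c = 3.02 m/s: p' = 0.2105 Pa, SPL = 80.4 dB
U_c = 4.54 m/s: p' = 0.4756 Pa, SPL = 87.5 dB
U_c = 9.08 m/s: p' = 1.9026 Pa, SPL = 99.6 dB
descent-over-ascent difference: 7.08 dB (= 40·log10(4.54/3.02) = 7.08)
doubling U_c adds 12.04 dB
```

3.02 and 4.54 m/s are the measured convection speeds during tongue
ascent and descent at the *same* jet speed U̅ = 26 m/s: the lag between
tongue motion and the build-up of vorticity at the teeth makes the
descent ~7 dB louder, which is why [s] keeps sounding while the tongue
is already falling away.

Running the full pipeline on a synthetic bundle:

```
$ python examples/05_analyze_and_recover.py
detected event: -0.008 <= t/ts <= 0.967 (injected (0.0, 1.0))
spectral peaks: [3962.0, 10078.0] Hz (injected (4000.0, 10000.0))
OASPL at U̅=26 m/s: ascent 77.1 dB, descent 83.2 dB (descent louder by 6.0 dB — the convection-lag hysteresis)
```

The analysis recovers the injected event boundaries within one frame
hop (~8 ms), the injected 4/10 kHz resonances within one FFT bin
(~86 Hz), and the sign and rough size of the ascent/descent asymmetry.

A thin CLI wraps the same functions: `sibilant simulate`, `synth`,
`analyze`, `estimate`, `check` (each writes a `manifest.json` recording
all parameters and seeds).

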