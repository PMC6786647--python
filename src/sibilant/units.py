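"""Centralized unit conventions and conversions.

Conventions used throughout the package:

* geometry in mm and mm²,
* volume flow rate in cm³/s,
* velocities in m/s,
* schedule times dimensionless (t / t_s, with t_s in seconds at signal
  boundaries only),
* acoustic pressure in Pa, levels in dB re 20 µPa.

1 cm³/s = 1e-6 m³/s and 1 mm² = 1e-6 m², so a flow rate in cm³/s divided
by an area in mm² is already a velocity in m/s; the conversion factor is
exactly 1 and is written out here so the cancellation is deliberate, not
accidental.
"""

#: Reference sound pressure, Pa (dB re 20 µPa).
P_REF = 2.0e-5

#: Mean duration of the [s] segment used to normalize schedule times, seconds.
T_S_SECONDS = 0.175

#: (cm³/s) / mm² → m/s.  1e-6 m³/s per cm³/s over 1e-6 m² per mm².
CM3PS_PER_MM2_TO_MPS = 1.0


def flow_over_area_to_mps(q_cm3ps: float, area_mm2: float) -> float:
    """Mean velocity in m/s from a flow rate in cm³/s and an area in mm²."""
    return CM3PS_PER_MM2_TO_MPS * q_cm3ps / area_mm2
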