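"""Tongue schedules, constriction area, and the jet speed U̅.

The tongue rises linearly to 3 mm, holds, and descends; the constriction
area shrinks from 83 to 8 mm² as it rises.  With the measured inlet flow
this gives the quasi-steady jet speed U̅ = Q/A_c at the constriction.
"""

from sibilant import (
    constriction_area,
    mean_constriction_velocity,
    schedule_from_table,
    tongue_height,
)

for speed in (40, 20, 10):
    s = schedule_from_table(speed)
    print(
        f"{speed:>2} mm/s: ascent starts t/ts={s.t_int:+.3f}, "
        f"plateau {s.plateau_start:.2f} .. {s.plateau_end:.2f}, "
        f"rest again at {s.t_end:.2f}"
    )
# the plateau interval is when the constriction is tightest and the jet fastest

s = schedule_from_table(40)
for t in (-0.5, 0.0, 0.4, 1.0, 1.3):
    h = tongue_height(t, s)
    print(f"t/ts={t:+.1f}: h={h:.2f} mm, A_c={constriction_area(h):5.1f} mm^2")

print(f"U̅ at peak flow (313 cm³/s, tongue raised): "
      f"{mean_constriction_velocity(313.0, 3.0):.1f} m/s")
print(f"U̅ at the start of [s] (280 cm³/s): "
      f"{mean_constriction_velocity(280.0, 3.0):.1f} m/s")
# ~39 and 35 m/s: the jet accelerates five-fold as the constriction closes
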