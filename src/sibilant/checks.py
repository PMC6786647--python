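"""Recomputation of the published reference quantities.

Each check recomputes a published number from scratch through the
package — articulation timings, plateau instants, constriction-velocity
endpoints, and the vortex-ring amplitude scaling — and compares it with
the printed value.  Used by ``sibilant check`` and the reproduction
script.
"""

from __future__ import annotations

import numpy as np

from .flow import FlowProfile, flow_rate
from .kinematics import (
    SCHEDULE_TABLE,
    TractGeometry,
    ascent_duration,
    mean_constriction_velocity,
    schedule_from_table,
)
from .vortex import VortexSoundParams, r_min_from_height, spl, vortex_pressure

__all__ = ["max_constriction_velocity", "run_checks"]

#: Published plateau intervals (t/t_s, rounded to 2 decimals) per speed.
PLATEAU_INTERVALS = {40: (0.05, 0.76), 20: (0.10, 0.61), 10: (0.26, 0.46)}


def max_constriction_velocity(
    profile: FlowProfile | None = None,
    geom: TractGeometry | None = None,
    n: int = 20001,
) -> tuple[float, int]:
    """Maximum U̅ with the tongue fully raised, scanning the flow profile.

    Returns ``(u_max m/s, n samples scanned)``.  The maximum occurs at
    the flow-rate peak because the constriction area is fixed at its
    minimum while the tongue holds h_max.
    """
    profile = profile or FlowProfile()
    geom = geom or TractGeometry()
    t = np.linspace(profile.t_first, profile.t_last, n)
    q = flow_rate(t, profile)
    u = mean_constriction_velocity(q, np.full(n, geom.h_max), geom)
    return float(u.max()), n


def run_checks(seed: int = 1):
    """Yield (name, value, expected, tolerance, ok) for each reference check."""
    results = []

    def add(name, value, expected, tol):
        results.append((name, float(value), expected, tol, abs(value - expected) <= tol))

    for speed, (t1, _, _) in SCHEDULE_TABLE.items():
        add(f"ascent duration t1/ts at {speed} mm/s",
            round(ascent_duration(speed), 3), t1, 5e-4)

    for speed, (lo, hi) in PLATEAU_INTERVALS.items():
        s = schedule_from_table(speed)
        add(f"plateau start t/ts at {speed} mm/s", round(s.plateau_start, 2), lo, 5e-3)
        add(f"plateau end t/ts at {speed} mm/s", round(s.plateau_end, 2), hi, 5e-3)

    geom = TractGeometry()
    u_max, _ = max_constriction_velocity(geom=geom)
    add("max U̅ (m/s, nearest integer)", round(u_max), 39, 0)
    add("U̅ at the start of [s], tongue raised (m/s)",
        mean_constriction_velocity(flow_rate(0.0, FlowProfile()), geom.h_max, geom),
        35.0, 1e-9)

    params = VortexSoundParams()
    p_ref_point = vortex_pressure(4.54, r_min_from_height(3.0), params)
    add("vortex-ring pressure at U_c=4.54 m/s, h=3 mm (Pa)", p_ref_point, 0.476, 5e-4)
    add("SPL doubling of U_c (dB)",
        spl(vortex_pressure(2 * 4.54, 0.5, params)) - spl(p_ref_point),
        12.04, 0.01)
    add("pressure with constriction fully open (Pa)",
        vortex_pressure(10.0, params.r_p, params), 0.0, 0.0)

    return results
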