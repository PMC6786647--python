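"""The inlet flow schedule Q(t) and 100 Hz flow-meter records.

The measured flow rises from 280 cm³/s at the start of [s] to 313 cm³/s
at t/t_s = 0.314 and falls to 184 cm³/s at the end of the segment; a
shape-preserving cubic joins the anchors.
"""

import tempfile
from pathlib import Path

from sibilant import FlowProfile, discretize_flow, flow_rate, read_flow_record, write_flow_record

profile = FlowProfile()
for t in (0.0, 0.157, 0.314, 0.657, 1.0):
    print(f"t/ts={t:.3f}: Q = {flow_rate(t, profile):6.1f} cm³/s")

times, q = discretize_flow(profile, 0.0, 1.0)  # 100 Hz, one t_s = 175 ms
print(f"{times.size} flow-meter samples over one t_s; peak {q.max():.1f} cm³/s")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "flow.txt"
    write_flow_record(times * 0.175, q, path, header="inlet flow rate, cm3/s")
    t2, q2 = read_flow_record(path)
    print(f"record round-trip: {q2.size} rows, identical = {(q2 == q).all()}")
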