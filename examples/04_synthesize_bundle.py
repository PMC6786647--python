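"""Generate a synthetic recording bundle (microphone, hot-wire, flow meter).

Everything is deterministic per seed: the microphone is resonator-shaped
noise whose envelope follows the vortex-ring estimate along the
articulation, the hot-wire fluctuation switches on before the sound, and
the flow meter logs the inlet schedule at 100 Hz.
"""

import numpy as np

from sibilant import SynthesisConfig, schedule_from_table, synth_flowmeter, synth_hotwire, synth_microphone

cfg = SynthesisConfig(sched=schedule_from_table(20), seed=42)
gain, tau = cfg.resolved_uc()
print(f"convection model: U_c = {gain:.3f} · lag(U̅; τ={1000*tau:.1f} ms)")
print(f"velocity fluctuation onset: t/ts = {cfg.resolved_fluct_onset():+.2f} "
      f"(precedes the sound span {cfg.sound_span})")

mic = synth_microphone(cfg)
hw = synth_hotwire(cfg)
t_q, q = synth_flowmeter(cfg)
print(f"microphone: {len(mic)} samples at {mic.rate:.0f} Hz, "
      f"RMS {np.sqrt(np.mean(mic.samples**2)):.3f} Pa")
print(f"hot-wire:   {len(hw)} samples, peak {hw.samples.max():.1f} m/s")
print(f"flow meter: {q.size} samples at 100 Hz, peak {q.max():.1f} cm³/s")
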