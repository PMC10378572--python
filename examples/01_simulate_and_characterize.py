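"""Simulate the fold oscillator at the four regime points and characterize
the steady orbits.

For each (alpha, Delta) point of the pathology regions (beta = 0.32) the
script integrates 2000 model-time units, counts Poincare-section crossing
clusters (the period count), and reports the right:left entrainment ratio
and torus flag.  A single crossing cluster with 1:1 entrainment is the
normal-voice signature; many clusters signal a quasi-periodic (toroidal)
orbit.
"""

from vfokit import (PoincareConfig, VFOParams, summarize_dynamics,
                    simulate_vfo)
from vfokit.synth import PRESETS

for name, (alpha, beta, delta) in PRESETS.items():
    traj = simulate_vfo(VFOParams(alpha, beta, delta), duration=2000.0,
                        dt=0.02)
    s = summarize_dynamics(traj, PoincareConfig(),
                           params=VFOParams(alpha, beta, delta))
    ent = str(s.entrainment) if s.entrainment else "undefined"
    print(f"{name:12s} alpha={alpha:.2f} delta={delta:.2f} -> "
          f"period r/l = {s.period_count_r}/{s.period_count_l}, "
          f"entrainment {ent}, torus={s.torus}, label={s.label.value}")
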