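"""Recover fold parameters from a synthetic lip signal with ADLES-VFT.

The lip trace is generated by propagating the glottal flow of a known
oscillator through the vocal-tract wave model with a smooth source profile.
The joint estimator sees only the lip signal; it recovers alpha and Delta
(the parameters that shape the oscillation) and reconstructs the glottal
flow.  The normalized mean absolute error compares the reconstructed and
true flows after zero-mean unit-variance scaling.
"""

import numpy as np

from vfokit import OptimizerConfig, TimeScale, VFOParams, fit_adles_vft
from vfokit.synth import synth_speech_case

truth = VFOParams(0.5, 0.32, 0.2)
case = synth_speech_case(truth, duration_s=0.02)

res = fit_adles_vft(case.um, case.geom, case.ics, case.vt_cfg,
                    OptimizerConfig(max_iter=800), TimeScale(case.f0),
                    f_iters=0, normalize=False)


def nz(v):
    return (v - v.mean()) / v.std()


mae = np.mean(np.abs(nz(res.final_u0) - nz(case.ug.u0)))
print(f"truth:     alpha=0.500 delta=0.200")
print(f"recovered: alpha={res.params.alpha:.3f} delta={res.params.delta:.3f}")
print(f"normalized glottal-flow MAE vs truth: {mae:.4f}")
print(f"lip-plane loss: {res.loss_history[0]:.3e} -> "
      f"{res.loss_history.min():.3e}")
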