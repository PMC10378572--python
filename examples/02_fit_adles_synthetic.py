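"""Recover fold parameters from a synthetic glottal flow with ADLES.

A noiseless reference flow is generated at (alpha, beta, Delta) =
(0.5, 0.32, 0.2); the estimator starts from the default initialization
(0.8, 0.32, 1.0) and descends the adjoint gradient.  The printed relative
errors show per-parameter recovery accuracy; the loss trace shows the
squared-residual decrease over iterations.
"""

import numpy as np

from vfokit import OptimizerConfig, VFOParams, fit_adles
from vfokit.synth import synth_glottal_case

truth = VFOParams(0.5, 0.32, 0.2)
case = synth_glottal_case(truth, duration=30.0, dt=0.02)

res = fit_adles(case.ug, case.geom, case.ics,
                OptimizerConfig(max_iter=500), normalize=False)
rel = np.abs(res.params.as_array() - truth.as_array()) / truth.as_array()
print(f"truth:     alpha=0.500 beta=0.320 delta=0.200")
print(f"recovered: alpha={res.params.alpha:.3f} beta={res.params.beta:.3f} "
      f"delta={res.params.delta:.3f}")
print(f"relative error per parameter: {np.round(rel * 100, 2)} %")
print(f"loss: {res.loss_history[0]:.3e} -> {res.loss_history.min():.3e} "
      f"in {res.n_iter} iterations")
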