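"""Recover programmed theta-gamma coupling with the phase-locking value.

Sweeps the programmed coupling strength kappa and shows that the estimated
PLV (mean vector length of theta-phase / gamma-envelope-phase differences)
increases monotonically with it, and that the preferred coupling phase psi0
is recovered.
"""

import numpy as np

from neurocarousel import HIGH_GAMMA, THETA, LfpSimParams, generate_coupled_lfp, plv_pac

print("kappa   mean PLV  (3 seeds, 30 s epochs, theta phase vs high-gamma amplitude)")
for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
    vals = [plv_pac(generate_coupled_lfp(
        LfpSimParams(duration=30.0, kappa=kappa, seed=s)), HIGH_GAMMA, THETA).plv
        for s in range(3)]
    print(f"{kappa:5.2f}   {np.mean(vals):8.3f}")

res = plv_pac(generate_coupled_lfp(LfpSimParams(
    duration=20.0, kappa=1.0, psi0=1.2, pink_sigma=0.0, line_amp=())),
    HIGH_GAMMA, THETA)
print(f"\nnoise-free kappa=1 fixture: PLV={res.plv:.4f}, "
      f"preferred phase {res.mean_phase:.4f} rad (programmed psi0=1.2)")
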