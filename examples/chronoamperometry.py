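"""Potential-step transient: surface depletion at -0.9 V.

Steps the potential to -0.9 V and follows the analyte concentration at the
outer face of the porous layer: a rapid initial drop while electrochemical
consumption outruns diffusive replenishment, then a gradual approach to a
quasi-steady balance.  The step current follows the classical
diffusion-limited decay once the mediator has switched on.
"""

import numpy as np

import p2dvolt as pv

params = pv.default_parameters()
program = pv.PotentialProgram.step(E_step=-0.9, duration=80.0)
vgram, history = pv.run_chronoamperometry(params, program, nx=400, nr=80)

times, trace, plateau, t_plateau = pv.surface_concentration_transient(history)
print("t (s)    C_surface/C_bulk")
for t_q in (0.1, 1.0, 5.0, 20.0, 80.0):
    i = np.argmin(np.abs(times - t_q))
    print(f"{times[i]:7.2f} {trace[i]/params.C_bulk:12.4f}")
print(f"plateau: {plateau/params.C_bulk:.4f} C_bulk, "
      f"reached (within 5%) at t = {t_plateau:.1f} s")
print(f"monotone non-increasing: {bool(np.all(np.diff(trace) <= 1e-9))}")
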