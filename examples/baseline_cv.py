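"""Baseline cyclic voltammogram of the porous-oxide-modified electrode.

Sweeps 0.2 -> -1.2 -> 0.2 V vs Ag/AgCl at 50 mV/s in 1.0 mM analyte and
locates the cathodic peak.  The peak potential (~-0.70 V) and peak current
density (~-0.60 A/m2, cathodic = negative) are the sensor's primary
observables; the reverse sweep shows no anodic feature because the
reduction is irreversible.
"""

import p2dvolt as pv

params = pv.default_parameters()
vgram, history = pv.run_cv(params, nx=400, nr=80)

E_pk, j_pk = pv.find_cathodic_peak(vgram)
print(f"cathodic peak: E = {E_pk:.4f} V vs Ag/AgCl, j = {j_pk:.4f} A/m2")
print(f"max reverse-sweep current: {vgram.j_total.max():.2e} A/m2 "
      "(no anodic feature)")

pv.dump_parameters(params, "baseline_params.json")
from p2dvolt.io import write_voltammogram_csv  # noqa: E402

write_voltammogram_csv(vgram, "baseline_cv.csv")
print("wrote baseline_cv.csv and baseline_params.json")
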