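"""Untreated baseline: immune-cell dynamics during tumor growth.

Assembles the full model at the default (median) parameters, grows the
tumor from a single seed cell, and prints when intratumoral M1-macrophage
and CD8 T-cell densities first reach 1e5 cell/mL, plus the tumor-
microenvironment composition when the tumor reaches a 3 cm diameter.
"""

import numpy as np

import tnbcqsp as q
from tnbcqsp.trial import characteristics

system = q.assemble_model()
print(f"model: {system.n_odes} ODE states, {system.n_rules} rules, "
      f"{system.n_parameters} parameters")

traj = q.simulate(system, (0, 1500), record_grid=1.0,
                  stop_when=("D_T", 3.0, +1))
v_t = traj.value("V_T")
for label, series in (("M1 macrophages", traj.value("Mac_M1") / v_t),
                      ("CD8 T cells", traj.value("Teff_T") / v_t)):
    k = int(np.argmax(series >= 1e5))
    f = (1e5 - series[k - 1]) / (series[k] - series[k - 1])
    day = traj.t[k - 1] + f * (traj.t[k] - traj.t[k - 1])
    print(f"{label} reach 1e5 cell/mL on day {day:.1f}")

print(f"tumor reaches 3 cm on day {traj.stopped_at:.0f}")
ch = characteristics(system, traj.states.iloc[-1].to_numpy())
for name in ("CD8_density", "Treg_density", "Mac_density", "M1_M2_ratio",
             "MDSC_density", "IL10", "IFNg", "CCL2"):
    print(f"  {name}: {ch[name]:.3g}")
# densities are cell/mL, cytokines pg/mL; M1/M2 is the macrophage
# polarization balance the macrophage module was calibrated to.
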