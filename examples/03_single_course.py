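"""One treated course: combination atezolizumab + nab-paclitaxel.

Initializes a median virtual patient at a 3 cm tumor, then simulates
400 days of the combination regimen (800 mg atezolizumab Q2W plus
100 mg/m^2 nab-paclitaxel on days 1/8/15 of 28-day cycles) and prints
the tumor diameter at the 8-week response assessments.
"""

import numpy as np

import tnbcqsp as q
from tnbcqsp.pharmacology import regimen_doses
from tnbcqsp.trial import classify_response

params = q.default_parameters()
system = q.assemble_model(params)
growth = q.simulate(system, (0, 1500), record_grid=10.0, stop_when=("D_T", 3.0, +1))
baseline = growth.states.iloc[-1].to_numpy()

doses = regimen_doses("combination", params, 400.0)
visits = np.arange(0.0, 400.1, 56.0)
course = q.simulate(system, (0, 400), doses=doses, record_grid=visits, y0=baseline)
diameters = np.interp(visits, course.t, course.value("D_T"))
for day, d in zip(visits, diameters):
    print(f"day {day:3.0f}: {d:.2f} cm ({(d - diameters[0]) / diameters[0] * 100:+.0f}%)")
assessment = classify_response(diameters, "RECIST1_1", visits)
print(f"best overall response: {assessment.best_overall}")
# RECIST 1.1: partial response at <= -30% vs baseline; progression at
# >= +20% over the nadir (with a 5 mm absolute guard).
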