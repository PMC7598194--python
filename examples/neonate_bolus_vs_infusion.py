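"""Bolus versus short infusion in neonates: peak arterial concentrations.

Simulates a virtual population of 100 term neonates (fixed demographics,
variability on enzyme/transporter expression and the unspecific clearance)
under a 1 ug/kg bolus, 2- and 4-min infusions, and a 3 ug/kg 4-min infusion,
and prints the geometric-mean arterial peak concentration of each scheme.
High bolus peaks are the suspected driver of rare chest-wall-rigidity events.
"""

import numpy as np

import fenpbpk as f
from fenpbpk.population import PopulationSpec, build_population_models, \
    simulate_population

neonate = f.build_individual("male", 0.0, 40.0)      # term, 3.5 kg
spec = PopulationSpec(n=100, seed=2024, fixed_individual=neonate)
models = build_population_models(spec)

grid = np.concatenate([np.linspace(0.0, 0.5, 400),
                       np.linspace(0.5, 4.0, 120)[1:]])
schemes = [("1 ug/kg bolus", 1.0, 0.0), ("1 ug/kg over 2 min", 1.0, 2.0),
           ("1 ug/kg over 4 min", 1.0, 4.0), ("3 ug/kg over 4 min", 3.0, 4.0)]

peaks = {}
for label, dose, minutes in schemes:
    regimen = [f.DoseEvent("fentanyl", 0.0, minutes / 60.0, dose, per_kg=True)]
    res = simulate_population(models, regimen, t_end=4.0, t_eval_h=grid)
    peaks[label] = float(np.nanmax(res.geo_mean[("arterial_plasma", "fentanyl")]))
    print(f"{label:22s} geometric-mean arterial Cmax {peaks[label]:5.1f} ng/mL")

ratio = peaks["1 ug/kg bolus"] / peaks["1 ug/kg over 4 min"]
print(f"\nbolus : 4-min infusion peak ratio = {ratio:.1f}")
print("Stretching the same dose over a few minutes cuts the arterial peak")
print("several-fold; even a tripled dose infused over 4 min stays below the")
print("bolus peak.")
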