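"""Bi-phasic endocytic tuning curve across burst lengths.

Fits the post-burst decay for 5-100 AP trains (10 Hz) on a small
population of cells, then reports the population-mean acceleration
(5 -> 25 AP) and slowing (25 -> 100 AP) of the fitted time constant.
"""

import numpy as np

from phendo import (
    PopulationSpec,
    calibrate_defaults,
    cell_from_config,
    fit_config_for,
    percent_change,
    population_tuning_study,
)

cfg = calibrate_defaults()["37C"]
base = cell_from_config(cfg)
spec = PopulationSpec(
    n_cells=9,
    tau1_mean=base.tau1,
    tau1_cv=cfg["population"]["tau1_cv"],
    slope_mean=base.slope_m,
    slope_cv=cfg["population"]["slope_cv"],
    base=base,
)
stimuli = [(n, 10.0) for n in (5, 10, 15, 25, 50, 100)]
curves = population_tuning_study(spec, stimuli, seed=0, cfg=fit_config_for("37C"))

print("n_AP   mean tau (s)")
for stim in stimuli:
    taus = [c.tau(stim) for c in curves]
    print(f"{stim[0]:>4d}   {np.mean(taus):6.2f} +- {np.std(taus, ddof=1)/len(taus)**0.5:.2f}")

accel = [percent_change(c.tau(stimuli[0]), c.tau(stimuli[3]), "accel") for c in curves]
slow = [percent_change(c.tau(stimuli[3]), c.tau(stimuli[5]), "slow") for c in curves]
print(f"\nacceleration 5 -> 25 AP : {np.mean(accel):.1f} %")
print(f"slowing 25 -> 100 AP    : {np.mean(slow):.1f} %")
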