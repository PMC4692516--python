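"""Rank the nested models with AICc on noisy replicates.

Fits steady-state, Patlak and modified Tofts models to simulated NAWM-like
curves at CNR 8 and reports how often each attains the highest Akaike
weight.
"""

import numpy as np

from dceleak import (
    FitConfig,
    SimulationConfig,
    add_noise_to_cnr,
    compare_models,
    fit_model,
    simulate_clean_pair,
)

N = 50
cfg = SimulationConfig(seed=4)
cp, ct = simulate_clean_pair(cfg)
wins = {"steady_state": 0, "patlak": 0, "mtofts": 0}
for seed in range(N):
    noisy = add_noise_to_cnr(ct, cfg.target_cnr, seed=seed)
    fits = [fit_model(noisy, cp, m, FitConfig(seed=seed))
            for m in ("steady_state", "patlak", "mtofts")]
    comp = compare_models(fits)
    wins[comp.best_model] += 1

for model, n in wins.items():
    print(f"{model:>12}: best in {n}/{N} replicates")
last = compare_models(fits)
print("last replicate Akaike weights:",
      {m: round(float(w), 3) for m, w in zip(last.models, last.akaike_weights)})
print(
    "The two-parameter Patlak model usually wins: the steady-state model "
    "misses the slow leakage entirely, while the extra backflux parameter "
    "of the modified Tofts model over-fits noise at this permeability."
)
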