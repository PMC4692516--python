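"""Evaluate the population vascular input function.

Prints the first-pass peak and late-washout plasma concentrations of the
extended Parker input function used throughout the simulations.
"""

import numpy as np

from dceleak import default_vif_params, extended_parker_vif

params = default_vif_params()
t_min = np.arange(0.0, 25.0, 0.01)
cp = extended_parker_vif(t_min, params)

peak_t = t_min[np.argmax(cp)]
print(f"first-pass peak: {np.max(cp):.2f} mM plasma at t = {peak_t:.2f} min")
for t in (2.0, 5.0, 10.0, 20.0):
    print(f"  C_p({t:4.0f} min) = {extended_parker_vif(t, params):.3f} mM")
print(
    "The bolus peaks within the first minute; the slowly decaying tail "
    "(~1 mM at 15-20 min) is what drives the leakage signal in "
    "low-permeability tissue."
)
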