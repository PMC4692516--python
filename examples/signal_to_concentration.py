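"""Signal-side building blocks: VFA T1 mapping and concentration conversion.

Generates two pre-contrast SPGR signals at 2/12 degrees, recovers T10 with
the variable-flip-angle formula, then round-trips a concentration through
the enhancement equation.
"""

from dceleak import (
    AcquisitionParams,
    concentration_from_enhancement,
    concentration_to_enhancement,
    spgr_signal,
    vfa_t1,
)

acq = AcquisitionParams()   # TR/TE = 8.24/3.1 ms, 2/12 deg, 1.5 T relaxivities
t10_true = 0.969            # NAWM-like pre-contrast T1 (s)

s_low = spgr_signal(0.0, t10_true, 500.0, acq.alpha_low, acq)
s_high = spgr_signal(0.0, t10_true, 500.0, acq.alpha_high, acq)
t10 = vfa_t1(s_low, s_high, acq)
print(f"VFA T1 estimate: {t10 * 1000:.1f} ms (truth {t10_true * 1000:.0f} ms)")

c_true = 0.5  # mM
e = concentration_to_enhancement(c_true, t10, acq)
c_back = concentration_from_enhancement(e, t10, acq)
print(f"C = {c_true} mM -> enhancement {e:.4f} -> C = {c_back:.9f} mM")
print(
    "A 0.5 mM gadolinium concentration raises the SPGR signal by "
    f"{100 * e:.0f}%; the numerical inversion recovers the concentration "
    "to solver precision."
)
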