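# dceleak

ROI-level quantification of **subtle blood–brain-barrier (BBB) leakage** from
low-temporal-resolution dynamic contrast-enhanced MRI (DCE-MRI), with the
simulation machinery needed to judge when such measurements can be trusted.

In diseases such as cerebral small vessel disease and some dementias the BBB
leaks *slightly*: extravascular contrast uptake is slow and the induced signal
change over a ~24-minute scan is a few percent. Protocols built for tumours
(fast sampling, large enhancement) do not transfer, and reported permeability
values for normal-appearing brain span orders of magnitude. `dceleak`
implements the analysis chain appropriate for this regime and quantifies its
two dominant failure modes — model misspecification and scanner signal drift —
by Monte-Carlo simulation. It is aimed at researchers analysing ROI-averaged
DCE-MRI curves in low-permeability tissue and at protocol designers deciding
whether a given drift level invalidates their measurements.

## The models

Signal is converted to gadolinium concentration through the spoiled
gradient-echo (SPGR) steady-state equation, with pre-contrast T1 from the
variable-flip-angle method (2°/12°) and relaxivities r1/r2 = 4.2/6.7
s⁻¹mM⁻¹. Tissue concentration curves C_t(t) are then fitted against the
plasma input C_p(t) with a nested family:

| model          | parameters            | form |
|----------------|-----------------------|------|
| steady-state   | v_p                   | C_t = v_p·C_p(t) |
| Patlak         | v_p, K^Trans          | C_t = v_p·C_p + K^Trans·∫₀ᵗ C_p dτ |
| modified Tofts | v_p, K^Trans, v_e     | C_t = v_p·C_p + K^Trans·∫₀ᵗ C_p·e^(−K^Trans(t−τ)/v_e) dτ |

Fits are non-negative, constrained to v_p + v_e ≤ 1, exclude the first three
post-contrast frames (the unresolved bolus first pass), and the nonlinear fit
restarts from 25 random initial values. Models are ranked by the
small-sample-corrected Akaike information criterion AICc = N·ln(SS/N) +
2(K+1) + 2K(K+1)/(N−K−1), summarised as Akaike weights.

For simulation, ground truth comes from the two-compartment exchange model
(2CXM; finite plasma flow F_p, permeability–surface area product PS), driven
by an extended Parker population input function with a sigmoid-modulated
bi-exponential washout, sampled at Δt = 0.1 s, down-sampled to the 20 × 73 s
acquisition grid, with Gaussian noise scaled to a concentration
contrast-to-noise ratio (CNR = peak/σ) of 8 and an optional linear scanner
drift injected in the signal-enhancement domain.

## Worked example

```bash
python examples/drift_bias.py
```

```
200 replicates, CNR 8, PS truth 3.0e-04 /min, vp truth 0.006
no drift : KTrans bias -1.62e-06 /min, vp bias +5.90e-04
with drift: KTrans bias +2.55e-04 /min, vp bias +2.18e-04
```

Without drift the fitted K^Trans is essentially unbiased (−1.6×10⁻⁶ min⁻¹ on
a truth of 3×10⁻⁴). Adding a 0.08 %/min signal drift — the magnitude observed
in contrast-free volunteer scans — inflates K^Trans by +2.6×10⁻⁴ min⁻¹,
i.e. by roughly the size of the true normal-appearing-white-matter
permeability itself. The other examples cover the input function
(`evaluate_vif.py`), T1 mapping and concentration conversion
(`signal_to_concentration.py`), simulation + fitting (`simulate_and_fit.py`),
AICc model ranking (`model_selection.py`) and the file-based ROI pipeline
(`roi_pipeline.py`). A thin CLI wraps the same functions
(`dceleak simulate|fit|compare|semiquant|drift-experiment|vif-eval|pipeline`).

## Layout

- `src/dceleak/` — library: `signal_model`, `vif`, `kinetic_models`,
  `fitting`, `model_selection`, `semiquant`, `synthetic_data`, `io`, `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model assumptions, numerical choices, limitations
- `tests/` — pytest suite including the acceptance checks
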