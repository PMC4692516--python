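# Methods

This note records the models implemented in `dceleak`, the assumptions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations. Parameter defaults are the
package's study conditions; everything quantitative stated here is computed
by the test suite or `scripts/acceptance.py`.

## Signal model

The dynamic acquisition is a spoiled gradient-echo (SPGR) sequence. With
R1(C) = 1/T10 + r1·C, the steady-state signal at flip angle α is

    S(C) = M0 · sin α · (1 − e^{−TR·R1}) / (1 − cos α · e^{−TR·R1}) · e^{−TE·r2·C}.

The final factor models T2* shortening by the contrast agent; the
pre-contrast T2* decay is absorbed into M0. Fractional enhancement is
E = S/S(0) − 1 at the dynamic flip angle, so M0 cancels and concentration can
be recovered from E alone given T10.

*Defaults*: TR = 8.24 ms, TE = 3.1 ms, α = 2°/12°, r1/r2 = 4.2/6.7 s⁻¹mM⁻¹
(1.5 T gadoterate), Δt = 73 s, 20 post-contrast frames, injection at t = 0
with the first frame at t = 73 s. Units are seconds and mM internally,
degrees at the interface.

**Inversion.** E(C) is inverted per frame by bracketed Brent root-finding.
Two structural features are handled explicitly:

- the SPGR denominator has a pole on the negative-concentration axis at
  C = (ln cos α / TR − 1/T10)/r1 (≈ −0.89 mM at defaults); the bracket's
  lower edge is clipped just above it, within the nominal [−1, 20] mM box;
- because of the T2* factor, E(C) attains a maximum near 4.4–5.1 mM
  (depending on T10) and decreases beyond it. The inversion is restricted to
  the monotonically increasing branch; the branch maximum is located by a
  bounded scalar optimisation, and an enhancement beyond it raises a
  no-solution error carrying the offending value.

Negative enhancements map to (small) negative concentrations on the extended
branch — deliberately unclipped, because the drift analysis needs signed
errors and clipping would bias v_p.

**T1 estimation.** Pre-contrast T1 comes from the two-point variable flip
angle formula (exact inversion of the SPGR ratio; non-physical signal ratios,
e.g. the T1 → ∞ limit, raise a typed error so callers choose the fallback).
An inversion-recovery fit SI = A + B·exp(−TI/T1) (trust-region least squares,
four T1 starting values) backs the reference T1 measurements; flat data are
rejected as unidentifiable.

## Vascular input function

The plasma input is the Parker population function extended with a second
exponential washout term:

    C_p(t) = 1/(1−Hct) · [ Σₙ Aₙ/(σₙ√2π)·e^{−(t−Tₙ)²/2σₙ²}
                           + (α₁e^{−β₁t} + α₂e^{−β₂t}) · sigmoid(s(t−τ)) ].

First-pass parameters (A_n, T_n, σ_n, s, τ) are the published Parker
population values. The washout defaults use half-lives of 2 min
(redistribution) and 40 min (elimination), with amplitudes partitioning the
Parker recirculation amplitude (α₁ + α₂ = 1.05 mM blood) and the slow
fraction α₂ = 0.70 chosen so that late plasma concentration is ≈ 0.9–1.0 mM
at 15–20 min after a 0.1 mmol/kg dose, consistent with published gadolinium
plasma pharmacokinetics. All of this lives in `parker_defaults.json` and is
configuration, not constants. Time is minutes inside this module (the
function's natural parameterisation); the haematocrit default is 0.45.

For measured data, the vessel curve is converted blood → plasma by
C_p = C_b/(1−Hct). When two observers nominate different VIF voxels, the
higher-peak-enhancement candidate is kept unless its noise score — the sum of
squared differences from a fitted bi-exponential — exceeds the alternative's
by a factor of 2 (configurable; scores at numerical-noise level count as
equal, and a failed bi-exponential fit falls back to the peak rule).

## Kinetic models

Nested fitting family (all assuming infinitely fast plasma transit):
steady-state (v_p), Patlak (v_p, K^Trans; no backflux), modified Tofts
(v_p, K^Trans, v_e). Ground truth for simulations is the two-compartment
exchange model

    v_p·dC_cap/dt = F_p(C_a − C_cap) + PS(C_e − C_cap)
    v_e·dC_e/dt   = PS(C_cap − C_e),      C_t = v_p·C_cap + v_e·C_e,

solved through its bi-exponential impulse response (eigendecomposition of
the 2×2 rate matrix) and verified in the tests against direct stiff ODE
integration (rtol 10⁻⁸) to < 10⁻³ relative error on random parameter draws.
F_p in ml/100 g/min is converted to min⁻¹ assuming 1 g/ml tissue density.

**Quadrature.** All integrals and convolutions treat the input as zero
before injection and piecewise linear between samples; when a grid starts at
t = 73 s a virtual (0, 0) sample is prepended so the first-pass area is not
silently dropped. Exponential kernels are integrated *exactly* against the
piecewise-linear input (a one-pole recursion, implemented as an IIR filter on
uniform grids), which reduces identically to the cumulative trapezoid rule
as the kernel rate → 0 — so the Patlak model is the exact K^Trans/v_e → 0
limit of the modified Tofts implementation, and the constant-input closed
forms are reproduced to machine precision.

## Fitting protocol

Residuals exclude the first three post-contrast frames (by index): the bolus
passage is neither resolved at Δt = 73 s nor described by any high-flow
model. Parameters are box-constrained non-negative with v_p + v_e ≤ 1
(soft penalty on the joint constraint; it is inactive under the study
conditions).

The steady-state and Patlak models are linear in their parameters, so the
constrained problem is convex and solved to its global optimum with bounded
linear least squares — restarts are redundant there. The modified Tofts fit
is genuinely nonlinear in K^Trans/v_e and uses 25 restarts with initial
values drawn log-uniformly (v_p ∈ [10⁻⁴, 0.1], K^Trans ∈ [10⁻⁶, 10⁻²] min⁻¹,
v_e ∈ [0.01, 0.5]), trust-region reflective minimisation with an analytic
Jacobian, and seed-deterministic behaviour. Model comparison uses
AICc = N ln(SS/N) + 2(K+1) + 2K(K+1)/(N−K−1) with N = 17 included frames and
K = 1/2/3; a literal "2K+1" penalty variant is available via
`aic_convention` (the two differ by a constant 1 per model and rarely change
the ranking). Ties break toward fewer parameters.

The concentration contrast-to-noise ratio is CNR = max C_t / std(Patlak
residuals). Two small-sample effects are documented in the tests: the
residual std is shrunk below the true σ by the fitted degrees of freedom,
and the *measured* peak is max-biased upward at CNR 8, so the estimator sits
some tens of percent above the generator's target; the generator's σ
calibration itself (σ = clean peak/CNR) is exact.

## Synthetic-data generator

`simulate_clean_pair` evaluates the VIF on a 0.1-s grid, convolves it with
the 2CXM impulse response, and point-samples both curves at the frame times.
`add_noise_to_cnr` adds i.i.d. Gaussian noise with σ = peak/CNR to the
coarse tissue curve (noise after down-sampling; for point sampling the order
is immaterial, and placing it after keeps σ defined on the fitted grid). The
VIF is noise-free by default (`vif_noise` flag). `add_drift` injects scanner
drift in the *signal-enhancement* domain — the measured quantity — by
converting concentration → enhancement through the forward SPGR model,
adding rate·t (fraction of baseline per minute), and inverting back; it is
applied to tissue and VIF alike, using the tissue T10 for both unless a
vessel T10 is configured. `run_drift_experiment` chains
simulate → drift → noise → Patlak fit over n_reps replicates with seeds
spawned from one root seed, and reports mean/std/bias of K^Trans (against
the generating PS) and v_p.

*Reference conditions* (the defaults): F_p = 10 ml/100 g/min,
PS = 3×10⁻⁴ min⁻¹, v_p = 0.006, v_e = 0.2, T10 = 969 ms (normal-appearing
white matter), CNR = 8, drift 0 or 8×10⁻⁴ /min (0.08 %/min), 1000
replicates.

What the generator does **not** emulate: image-domain effects (motion, Gibbs
ringing, B1 inhomogeneity, slice profiles), partial-volume and inflow
artefacts in the vessel, water-exchange effects, tissue-dependent
relaxivity, or physiological drift structure beyond a linear trend. Passing
tests therefore demonstrate correctness of the analysis chain and its noise/
drift response under these idealised conditions, not robustness to real
image artefacts.

## Design choices made where the design was open

- **First-frame integral.** The bolus mass between injection and the first
  frame is unobservable at Δt = 73 s: the true ∫C_p over [0, 73 s] is
  ≈ 3.3 mM·min while the prepended-origin trapezoid sees ≈ 1.0. The deficit
  is absorbed by the fit as a v_p offset of order K^Trans·ΔI/mean(C_p)
  (≈ +9 % at PS = 3×10⁻⁴ min⁻¹) — an information limit of the sampling, not
  of the estimator; K^Trans recovery is much less affected (≈ 1 %). The
  origin-prepend convention was chosen over ignoring the interval entirely
  (which roughly doubles both errors).
- **Drift domain.** Drift is modelled on enhancement (equivalently signal
  relative to baseline) rather than concentration, matching how scanner
  instability enters real data and the %/min volunteer metric.
- **Washout tail.** The bi-exponential tail parameters are set from general
  gadolinium pharmacokinetics (above); simulation outcomes that depend on
  the late-VIF level (notably the drift-induced v_p bias) are sensitive to
  this choice — see Limitations.
- **CNR targeting** is one-shot (σ = peak/CNR), not iterative.

## Limitations

- Analyses are ROI-level by design; no voxel-wise maps, registration, or
  segmentation.
- The drift experiments reproduce a K^Trans drift bias of ≈ +2.6×10⁻⁴ min⁻¹
  at 0.08 %/min drift under the reference conditions. The accompanying v_p
  drift bias is small and slightly positive here; its sign and magnitude
  trade off against the K^Trans bias through the (not independently
  measurable) late-washout shape of the input function, so v_p drift bias
  should be treated as VIF-model-dependent rather than a robust prediction.
- K^Trans underestimates PS increasingly at higher permeability (backflux
  neglected by Patlak), and v_p is correspondingly overestimated; both
  trends are asserted in the tests.
- Flows are assumed high (F_p ≫ PS); the uptake model for flow-limited
  regimes is out of scope.
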