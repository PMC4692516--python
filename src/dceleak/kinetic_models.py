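"""Forward tissue concentration models.

Nested family used for fitting low-permeability DCE-MRI data:

* steady-state model  C_t = vp Cp(t)                      (1 parameter)
* Patlak model        C_t = vp Cp + KTrans int_0^t Cp     (2 parameters)
* modified Tofts      C_t = vp Cp + KTrans Cp (x) exp(-KTrans t / ve)  (3)

plus the two-compartment exchange model (2CXM) with finite plasma flow,
used as the ground-truth generator for simulations. The 2CXM is defined by
the mass balance

    vp dC_cap/dt = Fp (Ca - C_cap) + PS (C_e - C_cap)
    ve dC_e/dt   = PS (C_cap - C_e)
    C_t          = vp C_cap + ve C_e

and solved here via its bi-exponential impulse response (eigendecomposition
of the 2x2 rate matrix) convolved with the input.

Convolutions and integrals assume the input is zero before injection
(t < 0) and piecewise linear between samples; when a grid starts after
injection (first frame at t = dt), a virtual origin (0, 0) is prepended so
the first-pass area is not silently dropped. Kernels are integrated exactly
against the piecewise-linear input, which reduces to the cumulative
trapezoid rule as the kernel rate goes to zero -- so the Patlak model is the
exact KTrans/ve -> 0 limit of the modified Tofts implementation.

Times on curve containers are seconds; rate constants are per minute
(KTrans, PS, Fp/100 with unit tissue density); conversion happens inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import InvalidParameterError
from .signal_model import ConcentrationCurve

__all__ = [
    "TissueParams",
    "KineticParams",
    "exp_conv",
    "steady_state_ct",
    "patlak_ct",
    "mtofts_ct",
    "twocxm_ct",
    "twocxm_irf_modes",
]

MODEL_NAMES = ("steady_state", "patlak", "mtofts")


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth tissue physiology for the 2CXM simulation.

    ``fp`` is plasma flow in ml/100 g/min (converted internally to min^-1
    assuming 1 g/ml tissue density, so 10 ml/100 g/min = 0.1 min^-1);
    ``ps`` the permeability-surface area product (min^-1); ``vp``/``ve`` the
    fractional plasma/interstitial volumes; ``t10`` the pre-contrast T1 (s).
    """

    fp: float = 10.0
    ps: float = 3e-4
    vp: float = 0.006
    ve: float = 0.2
    t10: float = 0.969

    def __post_init__(self) -> None:
        if self.fp <= 0:
            raise InvalidParameterError(f"Fp must be > 0, got {self.fp}")
        if self.ps < 0:
            raise InvalidParameterError(f"PS must be >= 0, got {self.ps}")
        if not (0 <= self.vp <= 1) or not (0 <= self.ve <= 1):
            raise InvalidParameterError("vp and ve must lie in [0, 1]")
        if self.vp + self.ve > 1:
            raise InvalidParameterError("vp + ve must be <= 1")
        if self.t10 <= 0:
            raise InvalidParameterError(f"T10 must be > 0, got {self.t10}")

    @property
    def fp_per_min(self) -> float:
        """Plasma flow in min^-1 (unit tissue density)."""
        return self.fp / 100.0


@dataclass(frozen=True)
class KineticParams:
    """Fitted parameters of one nested model."""

    model: str
    vp: float
    ktrans: float = 0.0   # min^-1
    ve: float = 0.0       # mtofts only

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.vp < 0 or self.ktrans < 0 or self.ve < 0:
            raise InvalidParameterError("kinetic parameters must be >= 0")
        if self.vp + self.ve > 1 + 1e-9:
            raise InvalidParameterError("vp + ve must be <= 1")

    @property
    def k(self) -> int:
        """Number of free parameters of the model."""
        return {"steady_state": 1, "patlak": 2, "mtofts": 3}[self.model]


def _with_origin(t_min: np.ndarray, u: np.ndarray):
    """Prepend a virtual (t=0, u=0) sample when the grid starts post-injection."""
    if t_min[0] > 0:
        return np.concatenate(([0.0], t_min)), np.concatenate(([0.0], u)), 1
    return t_min, u, 0


def exp_conv(t: np.ndarray, u: np.ndarray, rate: float) -> np.ndarray:
    """y(t_i) = int_{t_0}^{t_i} u(tau) exp(-rate (t_i - tau)) dtau.

    Exact for piecewise-linear ``u``; reduces to the cumulative trapezoid
    integral for ``rate`` = 0. ``t`` may be non-uniform.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    n = t.size
    if n < 2:
        return np.zeros(n)
    dt = np.diff(t)
    if rate == 0.0:
        out = np.empty(n)
        out[0] = 0.0
        np.cumsum(0.5 * dt * (u[1:] + u[:-1]), out=out[1:])
        return out

    a = rate * dt
    e = np.exp(-a)
    if a.min() < 1e-5:
        small = a < 1e-5
        c_prev = np.where(small,
                          dt * (0.5 - a / 3.0 + a * a / 8.0),
                          (1.0 - e * (1.0 + a)) / (rate * rate * dt))
        c_next = np.where(small,
                          dt * (0.5 - a / 6.0 + a * a / 24.0),
                          (1.0 - e) / rate - (1.0 - e * (1.0 + a)) / (rate * rate * dt))
    else:
        c_prev = (1.0 - e * (1.0 + a)) / (rate * rate * dt)
        c_next = (1.0 - e) / rate - c_prev
    g = c_prev * u[:-1] + c_next * u[1:]

    dt0 = dt[0]
    if np.ptp(dt) <= 1e-9 * dt0:
        # uniform grid: y_{i+1} = e y_i + g_i is an order-1 IIR filter
        z = lfilter([1.0], [1.0, -float(e[0])], g)
    else:
        z = np.empty_like(g)
        acc = 0.0
        for i in range(g.size):
            acc = e[i] * acc + g[i]
            z[i] = acc
    return np.concatenate(([0.0], z))


def steady_state_ct(cp: ConcentrationCurve, vp: float) -> ConcentrationCurve:
    """Steady-state (intravascular-only) model: C_t = vp Cp."""
    return ConcentrationCurve(cp.times, vp * cp.values)


def patlak_ct(cp: ConcentrationCurve, vp: float, ktrans: float) -> ConcentrationCurve:
    """Patlak model: C_t = vp Cp(t) + KTrans int_0^t Cp dtau (no backflux)."""
    t_min, u, off = _with_origin(cp.times_min, cp.values)
    integral = exp_conv(t_min, u, 0.0)[off:]
    return ConcentrationCurve(cp.times, vp * cp.values + ktrans * integral)


def mtofts_ct(cp: ConcentrationCurve, vp: float, ktrans: float, ve: float) -> ConcentrationCurve:
    """Modified Tofts model: adds backflux with rate KTrans/ve."""
    if ktrans > 0 and ve <= 0:
        raise InvalidParameterError("ve must be > 0 when KTrans > 0")
    if ktrans == 0:
        return steady_state_ct(cp, vp)
    t_min, u, off = _with_origin(cp.times_min, cp.values)
    leak = exp_conv(t_min, u, ktrans / ve)[off:]
    return ConcentrationCurve(cp.times, vp * cp.values + ktrans * leak)


def twocxm_irf_modes(p: TissueParams) -> tuple[np.ndarray, np.ndarray]:
    """Bi-exponential impulse-response decomposition of the 2CXM.

    Returns (weights, rates) such that the tissue impulse response is
    h(t) = sum_j w_j exp(-rates_j t) (t in minutes) and
    C_t = h (x) Ca.
    """
    fp = p.fp_per_min
    if p.vp <= 0:
        if p.ps == 0 and p.vp == 0:
            # vanishing tissue: C_t -> 0 in the vp -> 0 limit
            return np.array([]), np.array([])
        raise InvalidParameterError("2CXM requires vp > 0 when PS > 0")
    if p.ps > 0 and p.ve <= 0:
        raise InvalidParameterError("2CXM requires ve > 0 when PS > 0")
    if p.ps == 0:
        # single well-mixed plasma compartment
        return np.array([fp]), np.array([fp / p.vp])

    a = np.array([
        [-(fp + p.ps) / p.vp, p.ps / p.vp],
        [p.ps / p.ve, -p.ps / p.ve],
    ])
    lam, vec = np.linalg.eig(a)
    b = np.array([fp / p.vp, 0.0])
    v_out = np.array([p.vp, p.ve])
    coeff = np.linalg.solve(vec, b)
    w = (v_out @ vec) * coeff
    return w.real, (-lam).real


def twocxm_ct(ca: ConcentrationCurve, p: TissueParams) -> ConcentrationCurve:
    """Two-compartment exchange model tissue curve by modal convolution.

    Intended for a fine input grid (e.g. 0.1 s) so the fast capillary mode
    (time constant vp/Fp, well under a minute) is resolved.
    """
    w, rates = twocxm_irf_modes(p)
    t_min, u, off = _with_origin(ca.times_min, ca.values)
    ct = np.zeros_like(u)
    for wj, rj in zip(w, rates):
        ct += wj * exp_conv(t_min, u, rj)
    return ConcentrationCurve(ca.times, ct[off:])
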