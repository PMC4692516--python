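"""Spoiled-gradient-echo signal model and T1 estimation.

Links contrast-agent concentration, pre-contrast T1 and the SPGR acquisition
parameters to the measured signal, and provides the inverse mappings used by
the analysis pipeline:

* forward SPGR signal (including T2* attenuation by the agent),
* variable-flip-angle (VFA) T1 estimation from two pre-contrast acquisitions,
* fractional signal enhancement E = (S - S0)/S0,
* numerical inversion enhancement -> concentration, and
* three-parameter inversion-recovery T1 fitting.

Units: seconds and mM internally; flip angles in degrees at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit, minimize_scalar

from .errors import (
    FitFailureError,
    InvalidParameterError,
    NonPhysicalSignalRatioError,
    NoSolutionError,
)

__all__ = [
    "AcquisitionParams",
    "SignalCurve",
    "ConcentrationCurve",
    "spgr_signal",
    "vfa_t1",
    "enhancement",
    "concentration_to_enhancement",
    "concentration_from_enhancement",
    "ir_t1_fit",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """SPGR acquisition parameters of the dynamic protocol.

    Defaults describe a 1.5 T protocol with TR/TE = 8.24/3.1 ms, pre-contrast
    flip angles 2 deg / 12 deg, gadolinium relaxivities r1/r2 = 4.2/6.7
    s^-1 mM^-1 and 20 dynamic frames at 73 s temporal resolution.
    """

    tr: float = 8.24e-3          # repetition time (s)
    te: float = 3.1e-3           # echo time (s)
    alpha_low: float = 2.0       # low flip angle (degrees)
    alpha_high: float = 12.0     # high / dynamic flip angle (degrees)
    r1: float = 4.2              # longitudinal relaxivity (s^-1 mM^-1)
    r2: float = 6.7              # transverse relaxivity (s^-1 mM^-1)
    dt: float = 73.0             # temporal resolution (s)
    n_frames: int = 20           # number of post-contrast frames

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise InvalidParameterError(f"TR must be > 0, got {self.tr}")
        if self.te < 0:
            raise InvalidParameterError(f"TE must be >= 0, got {self.te}")
        if not (0 < self.alpha_low < self.alpha_high <= 90):
            raise InvalidParameterError(
                f"flip angles must satisfy 0 < alpha_low < alpha_high <= 90, "
                f"got {self.alpha_low}, {self.alpha_high}"
            )
        if self.r1 <= 0 or self.r2 <= 0:
            raise InvalidParameterError("relaxivities must be > 0")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.n_frames < 4:
            raise InvalidParameterError("n_frames must be >= 4")

    @property
    def frame_times(self) -> np.ndarray:
        """Post-contrast frame times t_i = i*dt (s), injection at t = 0."""
        return self.dt * np.arange(1, self.n_frames + 1)


def _validate_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidParameterError("times must be a non-empty 1-D array")
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("times must be finite and strictly increasing")
    return t


@dataclass
class SignalCurve:
    """ROI or vessel-voxel signal-time curve in scanner units.

    ``baseline`` is the pre-contrast signal S0 acquired at the dynamic
    (high) flip angle.
    """

    times: np.ndarray
    values: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        self.times = _validate_times(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.times.shape:
            raise InvalidParameterError("times and values must have equal length")
        if np.any(~np.isfinite(self.values)):
            raise InvalidParameterError("signal values must be finite")
        if not np.isfinite(self.baseline) or self.baseline <= 0:
            raise InvalidParameterError(f"baseline must be > 0, got {self.baseline}")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ConcentrationCurve:
    """Contrast-agent concentration-time curve (mM).

    Negative values are permitted: noise and scanner drift can push the
    *apparent* concentration below zero and clipping would bias parameter
    estimates.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = _validate_times(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.times.shape:
            raise InvalidParameterError("times and values must have equal length")
        if np.any(~np.isfinite(self.values)):
            raise InvalidParameterError("concentration values must be finite")

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0

    def __len__(self) -> int:
        return self.times.size


def _spgr_ratio_terms(c, t10: float, alpha: float, acq: AcquisitionParams):
    """Return (t1_factor, t2_factor) of the SPGR signal at concentration c."""
    c = np.asarray(c, dtype=float)
    r1_tot = 1.0 / t10 + acq.r1 * c
    e = np.exp(-acq.tr * r1_tot)
    cos_a = np.cos(np.deg2rad(alpha))
    t1_factor = (1.0 - e) / (1.0 - cos_a * e)
    t2_factor = np.exp(-acq.te * acq.r2 * c)
    return t1_factor, t2_factor


def spgr_signal(c, t10: float, m0: float, alpha: float, acq: AcquisitionParams):
    """Steady-state SPGR signal at concentration ``c`` (mM).

    S = M0 sin(a) (1 - e)/(1 - cos(a) e) * exp(-TE r2 C), with
    e = exp(-TR (1/T10 + r1 C)). The exp(-TE r2 C) factor models T2*
    shortening by the agent; the pre-contrast T2* decay is absorbed in M0.
    """
    if t10 <= 0:
        raise InvalidParameterError(f"T10 must be > 0, got {t10}")
    if m0 <= 0:
        raise InvalidParameterError(f"M0 must be > 0, got {m0}")
    t1f, t2f = _spgr_ratio_terms(c, t10, alpha, acq)
    return m0 * np.sin(np.deg2rad(alpha)) * t1f * t2f


def vfa_t1(s_a: float, s_b: float, acq: AcquisitionParams) -> float:
    """Variable-flip-angle T1 from two pre-contrast SPGR signals.

    ``s_a``/``s_b`` are the signals at ``alpha_low``/``alpha_high``. Solving
    the SPGR signal ratio S_R = S_a/S_b for exp(-TR/T1) gives

        1/T10 = (1/TR) ln[(S_R sin(ab) cos(aa) - sin(aa) cos(ab)) /
                          (S_R sin(ab) - sin(aa))].

    Raises :class:`NonPhysicalSignalRatioError` when the ratio lies outside
    the interval mapping to a positive finite T1 (e.g. the T1 -> infinity
    limit S_R -> sin(aa)/sin(ab)).
    """
    if s_a <= 0 or s_b <= 0:
        raise NonPhysicalSignalRatioError("signals must be > 0")
    aa, ab = np.deg2rad(acq.alpha_low), np.deg2rad(acq.alpha_high)
    s_r = s_a / s_b
    num = s_r * np.sin(ab) * np.cos(aa) - np.sin(aa) * np.cos(ab)
    den = s_r * np.sin(ab) - np.sin(aa)
    if den == 0 or num / den <= 0:
        raise NonPhysicalSignalRatioError(
            f"signal ratio {s_r:.6g} outside the physically valid interval"
        )
    log_arg = num / den
    if log_arg <= 1.0:
        # exp(-TR/T1) >= 1  <=>  T1 <= 0 or infinite
        raise NonPhysicalSignalRatioError(
            f"signal ratio {s_r:.6g} implies non-positive 1/T1"
        )
    return acq.tr / np.log(log_arg)


def enhancement(curve: SignalCurve) -> np.ndarray:
    """Fractional signal enhancement E_i = (S_i - S0)/S0 (dimensionless)."""
    return (curve.values - curve.baseline) / curve.baseline


def concentration_to_enhancement(c, t10: float, acq: AcquisitionParams,
                                 alpha: float | None = None):
    """Forward map concentration (mM) -> fractional enhancement.

    E(C) = S(C)/S(0) - 1 at the dynamic flip angle; M0 cancels in the ratio.
    """
    if t10 <= 0:
        raise InvalidParameterError(f"T10 must be > 0, got {t10}")
    alpha = acq.alpha_high if alpha is None else alpha
    t1f, t2f = _spgr_ratio_terms(c, t10, alpha, acq)
    t1f0, _ = _spgr_ratio_terms(0.0, t10, alpha, acq)
    return t1f * t2f / t1f0 - 1.0


def _bracket_low(t10: float, acq: AcquisitionParams, alpha: float) -> float:
    """Lowest usable concentration: just above the SPGR pole on the negative axis."""
    cos_a = np.cos(np.deg2rad(alpha))
    c_pole = (np.log(cos_a) / acq.tr - 1.0 / t10) / acq.r1
    return max(-1.0, c_pole * (1.0 - 1e-9) + 1e-6)


def concentration_from_enhancement(
    e,
    t10: float,
    acq: AcquisitionParams,
    alpha: float | None = None,
    bracket: tuple[float, float] = (-1.0, 20.0),
    xtol: float = 1e-12,
) -> np.ndarray | float:
    """Invert the enhancement equation for concentration by root-finding.

    Solves E(C) = e on the monotonic branch of the forward map using
    bracketed Brent iteration. The lower bracket edge is clipped above the
    analytic pole of the SPGR expression; the upper edge is shrunk to the
    maximum of E(C) if T2* attenuation makes the map turn over within the
    bracket. Negative enhancements map to (small) negative concentrations.

    Raises :class:`NoSolutionError` if the requested enhancement lies outside
    the attainable range, carrying the offending value.
    """
    if t10 <= 0:
        raise InvalidParameterError(f"T10 must be > 0, got {t10}")
    alpha = acq.alpha_high if alpha is None else alpha
    lo = max(bracket[0], _bracket_low(t10, acq, alpha))
    hi = bracket[1]

    # Restrict to the monotonically increasing branch (T2* decay eventually
    # dominates the saturating T1 term).
    grid = np.linspace(lo, hi, 256)
    e_grid = concentration_to_enhancement(grid, t10, acq, alpha)
    i_max = int(np.argmax(e_grid))
    if i_max < grid.size - 1:
        res = minimize_scalar(
            lambda c: -concentration_to_enhancement(c, t10, acq, alpha),
            bounds=(grid[max(i_max - 1, 0)], grid[i_max + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        hi = float(res.x)
        e_hi = float(-res.fun)
    else:
        e_hi = e_grid[-1]
    e_lo = concentration_to_enhancement(lo, t10, acq, alpha)

    def solve_one(target: float) -> float:
        if not np.isfinite(target):
            raise NoSolutionError("non-finite enhancement", enhancement=target)
        if target == 0.0:
            return 0.0
        if not (e_lo < target < e_hi):
            raise NoSolutionError(
                f"enhancement {target:.6g} outside attainable range "
                f"[{e_lo:.6g}, {e_hi:.6g}]",
                enhancement=target,
            )
        f = lambda c: concentration_to_enhancement(c, t10, acq, alpha) - target
        return brentq(f, lo, hi, xtol=xtol, rtol=8.9e-16)

    e_arr = np.asarray(e, dtype=float)
    if e_arr.ndim == 0:
        return solve_one(float(e_arr))
    return np.array([solve_one(float(x)) for x in e_arr])


def ir_t1_fit(ti, si) -> tuple[float, float, float]:
    """Three-parameter inversion-recovery T1 fit.

    Least-squares fit of SI = A + B exp(-TI/T1) to signed signal intensities
    at inversion times ``ti`` (s). Returns (A, B, T1) with T1 > 0.

    Raises :class:`FitFailureError` on degenerate (flat) data or solver
    failure.
    """
    ti = np.asarray(ti, dtype=float)
    si = np.asarray(si, dtype=float)
    if np.unique(ti).size < 4:
        raise InvalidParameterError("at least 4 distinct inversion times required")
    if np.ptp(si) < 1e-12 * max(1.0, np.max(np.abs(si))):
        raise FitFailureError("flat signal: T1 is unidentifiable")

    def model(t, a, b, t1):
        return a + b * np.exp(-t / t1)

    a0 = si[np.argmax(ti)]
    b0 = si[np.argmin(ti)] - a0
    messages: list[str] = []
    best = None
    for t1_init in (0.3, 0.9, 1.5, 3.0):
        try:
            popt, _ = curve_fit(
                model, ti, si, p0=(a0, b0, t1_init),
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 50.0]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            messages.append(f"T1 init {t1_init}: {exc}")
            continue
        ss = float(np.sum((model(ti, *popt) - si) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt)
    if best is None:
        raise FitFailureError("inversion-recovery fit failed", diagnostics=messages)
    a, b, t1 = best[1]
    return float(a), float(b), float(t1)
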