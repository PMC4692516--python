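"""Vascular input function (VIF).

Provides the extended Parker population input function -- two Gaussians for
the first and second bolus pass plus a sigmoid-modulated bi-exponential
washout -- the blood-to-plasma haematocrit conversion, and the tie-break rule
used to choose a VIF voxel between candidate vessel curves.

The first-pass parameters (Gaussian amplitudes/centres/widths, sigmoid) are
the Parker et al. population values; the bi-exponential washout defaults use
half-lives of 2 min (redistribution) and 40 min (elimination) with the slow
fraction chosen so the late plasma concentration is ~1 mM at 15-20 min after
a standard 0.1 mmol/kg dose. All are configuration (``parker_defaults.json``),
not constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from importlib import resources

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .errors import InvalidParameterError
from .signal_model import SignalCurve, enhancement

__all__ = [
    "VifParams",
    "default_vif_params",
    "extended_parker_vif",
    "blood_to_plasma",
    "select_vif_candidate",
    "biexponential_noise_score",
]


@dataclass(frozen=True)
class VifParams:
    """Parameters of the extended Parker input function.

    Gaussian terms are parameterised in minutes (centres T1g/T2g, widths
    sigma1/sigma2, scales A1/A2 in mmol min); the washout is
    alpha1 exp(-beta1 t) + alpha2 exp(-beta2 t) (mM, min^-1) modulated by a
    sigmoid of width ``s`` (min^-1) centred at ``tau`` (min). ``hct`` is the
    haematocrit used for the blood -> plasma conversion.
    """

    A1: float
    A2: float
    T1g: float
    T2g: float
    sigma1: float
    sigma2: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    s: float
    tau: float
    hct: float = 0.45

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise InvalidParameterError("Gaussian widths must be > 0")
        if self.beta1 < 0 or self.beta2 < 0:
            raise InvalidParameterError("exponential decay rates must be >= 0")
        if not (0 < self.hct < 1):
            raise InvalidParameterError(f"haematocrit must be in (0, 1), got {self.hct}")

    @classmethod
    def from_dict(cls, d: dict) -> "VifParams":
        d = dict(d)
        if "Hct" in d:
            d["hct"] = d.pop("Hct")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_hct(self, hct: float) -> "VifParams":
        return replace(self, hct=hct)


def default_vif_params() -> VifParams:
    """Load the packaged population VIF parameters."""
    text = resources.files("dceleak.data").joinpath("parker_defaults.json").read_text()
    return VifParams.from_dict(json.loads(text))


def extended_parker_vif(t_min, p: VifParams) -> np.ndarray:
    """Plasma concentration C_p (mM) of the extended Parker VIF at ``t_min`` (minutes).

    C_p(t) = 1/(1-Hct) * [ sum_n A_n/(sigma_n sqrt(2 pi)) exp(-(t-T_n)^2/(2 sigma_n^2))
                           + (sum_n alpha_n exp(-beta_n t)) / (1 + exp(-s (t - tau))) ]
    """
    t = np.asarray(t_min, dtype=float)
    gauss = (
        p.A1 / (p.sigma1 * np.sqrt(2 * np.pi)) * np.exp(-((t - p.T1g) ** 2) / (2 * p.sigma1**2))
        + p.A2 / (p.sigma2 * np.sqrt(2 * np.pi)) * np.exp(-((t - p.T2g) ** 2) / (2 * p.sigma2**2))
    )
    washout = p.alpha1 * np.exp(-p.beta1 * t) + p.alpha2 * np.exp(-p.beta2 * t)
    sigmoid = expit(p.s * (t - p.tau))
    return (gauss + washout * sigmoid) / (1.0 - p.hct)


def blood_to_plasma(c_b, hct: float = 0.45):
    """Convert whole-blood concentration to plasma: C_p = C_b / (1 - Hct)."""
    if not (0 <= hct < 1):
        raise InvalidParameterError(f"haematocrit must be in [0, 1), got {hct}")
    return np.asarray(c_b, dtype=float) / (1.0 - hct)


def biexponential_noise_score(curve: SignalCurve) -> float:
    """Noise score of a vessel signal curve.

    Sum of squared differences between the curve and the best-fitting
    bi-exponential c1 exp(-k1 t) + c2 exp(-k2 t) (t in minutes). A smoother
    curve yields a lower score.
    """
    t = curve.times / 60.0
    y = curve.values

    def model(tt, c1, k1, c2, k2):
        return c1 * np.exp(-k1 * tt) + c2 * np.exp(-k2 * tt)

    scale = max(np.max(np.abs(y)), 1e-12)
    best = None
    for k1_init, k2_init in ((1.0, 0.02), (0.3, 0.01), (3.0, 0.1)):
        try:
            popt, _ = curve_fit(
                model, t, y,
                p0=(0.5 * scale, k1_init, 0.5 * scale, k2_init),
                bounds=([-np.inf, 0, -np.inf, 0], [np.inf, 50, np.inf, 50]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or ss < best:
            best = ss
    if best is None:
        raise RuntimeError("bi-exponential fit failed for all starts")
    return best


def select_vif_candidate(
    candidates: list[SignalCurve],
    noise_ratio_threshold: float = 2.0,
) -> int:
    """Choose the VIF voxel among candidate vessel signal curves.

    The candidate with the highest peak enhancement is chosen, unless its
    bi-exponential noise score exceeds that of the best alternative by more
    than ``noise_ratio_threshold``, in which case the alternative (applied
    recursively over remaining candidates) is preferred. If the noise fit
    fails, the rule falls back to peak enhancement alone.
    """
    if len(candidates) == 0:
        raise InvalidParameterError("at least one candidate is required")
    if len(candidates) == 1:
        return 0

    peaks = [float(np.max(enhancement(c))) for c in candidates]
    order = sorted(range(len(candidates)), key=lambda i: -peaks[i])
    try:
        scores = [biexponential_noise_score(c) for c in candidates]
    except RuntimeError:
        return order[0]

    # scores at numerical-noise level (near-perfect fits) count as equal
    floor = max((1e-8 * max(np.max(np.abs(c.values)), 1.0)) ** 2 * len(c)
                for c in candidates)
    scores = [max(s, floor) for s in scores]

    chosen = order[0]
    for alt in order[1:]:
        # keep the higher-peak voxel unless it is "significantly noisier"
        if scores[chosen] > noise_ratio_threshold * scores[alt]:
            chosen = alt
    return chosen
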