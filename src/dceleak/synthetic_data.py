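"""Simulation engine: synthetic low-permeability DCE-MRI experiments.

Generates what the study's acquisition would measure for known ground truth:

1. a high-resolution (0.1 s) extended Parker VIF,
2. a tissue curve by 2CXM convolution,
3. point-sampling of both onto the acquisition grid (20 frames at 73 s,
   injection at t = 0, first frame at t = 73 s),
4. optional linear scanner drift, injected in the signal-enhancement domain
   (the measured quantity) via the forward SPGR model and mapped back to
   apparent concentration,
5. Gaussian noise scaled to a target concentration contrast-to-noise ratio
   (sigma = peak / CNR), added to the coarse tissue curve,

plus the replicate driver that fits the Patlak model to each realisation
and summarises bias in KTrans (against the generating PS) and vp.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import linregress

from .errors import InvalidParameterError
from .fitting import FitConfig, FitResult, fit_model
from .kinetic_models import TissueParams, twocxm_ct
from .signal_model import (
    AcquisitionParams,
    ConcentrationCurve,
    SignalCurve,
    concentration_from_enhancement,
    concentration_to_enhancement,
)
from .vif import VifParams, default_vif_params, extended_parker_vif

__all__ = [
    "SimulationConfig",
    "BiasSummary",
    "simulate_clean_pair",
    "add_noise_to_cnr",
    "add_drift",
    "run_drift_experiment",
    "volunteer_drift_rate",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults are the NAWM-like reference conditions: Fp = 10 ml/100 g/min,
    PS = 3e-4 min^-1, vp = 0.006, ve = 0.2, T10 = 969 ms, CNR = 8,
    20 frames at 73 s, fine grid 0.1 s, 1000 replicates. ``drift_rate`` is
    the fractional signal change per minute (0.08 %/min = 8e-4).
    """

    vif: VifParams = field(default_factory=default_vif_params)
    tissue: TissueParams = field(default_factory=TissueParams)
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    fine_dt: float = 0.1          # s
    target_cnr: float = 8.0
    drift_rate: float = 0.0       # fraction of baseline signal per minute
    n_reps: int = 1000
    seed: int = 0
    vif_noise: bool = False
    vif_t10: float | None = None  # T10 used for VIF drift conversion; tissue T10 if None
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.fine_dt <= 0 or self.fine_dt >= self.acq.dt:
            raise InvalidParameterError("fine_dt must satisfy 0 < fine_dt < coarse dt")
        if self.target_cnr <= 0:
            raise InvalidParameterError("target_cnr must be > 0")
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")


@dataclass
class BiasSummary:
    """Replicate statistics of fitted Patlak parameters against ground truth."""

    n_reps: int
    truth_ps: float
    truth_vp: float
    ktrans_mean: float
    ktrans_std: float
    ktrans_bias: float    # mean fitted KTrans - PS
    vp_mean: float
    vp_std: float
    vp_bias: float        # mean fitted vp - vp
    drift_rate: float
    seed: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def simulate_clean_pair(cfg: SimulationConfig) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """Noise- and drift-free (VIF, tissue) concentration pair on the frame grid.

    The VIF and the 2CXM tissue response are generated on the fine grid and
    point-sampled at the frame times t_i = i * dt, i = 1..n_frames.
    """
    t_end = cfg.acq.n_frames * cfg.acq.dt
    n_fine = int(round(t_end / cfg.fine_dt))
    t_fine = np.linspace(0.0, t_end, n_fine + 1)
    cp_fine = ConcentrationCurve(t_fine, extended_parker_vif(t_fine / 60.0, cfg.vif))
    ct_fine = twocxm_ct(cp_fine, cfg.tissue)

    t_frames = cfg.acq.frame_times
    idx = np.searchsorted(t_fine, t_frames)
    # frame times must lie on the fine grid (73 s is a multiple of 0.1 s)
    if not np.allclose(t_fine[idx], t_frames, atol=cfg.fine_dt / 2):
        raise InvalidParameterError("frame times do not align with the fine grid")
    cp = ConcentrationCurve(t_frames, cp_fine.values[idx])
    ct = ConcentrationCurve(t_frames, ct_fine.values[idx])
    return cp, ct


def add_noise_to_cnr(ct: ConcentrationCurve, target_cnr: float, seed) -> ConcentrationCurve:
    """Add i.i.d. Gaussian noise with sigma = peak(Ct)/CNR to a tissue curve.

    ``seed`` may be an int or a numpy Generator/SeedSequence.
    """
    peak = float(np.max(ct.values))
    if peak <= 0:
        raise InvalidParameterError("add_noise_to_cnr requires a positive peak")
    if target_cnr <= 0:
        raise InvalidParameterError("target_cnr must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = peak / target_cnr
    return ConcentrationCurve(ct.times, ct.values + rng.normal(0.0, sigma, ct.values.shape))


def add_drift(
    curve: ConcentrationCurve,
    drift_rate: float,
    t10: float,
    acq: AcquisitionParams,
) -> ConcentrationCurve:
    """Inject a linear scanner drift into a concentration curve.

    The curve is converted to signal enhancement through the forward SPGR
    model (T10 of the pre-contrast tissue/blood), the drift
    ``drift_rate * t`` (t in minutes, rate as a fraction of baseline signal
    per minute) is added, and the result is converted back to apparent
    concentration. With ``drift_rate`` = 0 this is an identity round trip.
    """
    e = concentration_to_enhancement(curve.values, t10, acq)
    e = e + drift_rate * curve.times / 60.0
    c = concentration_from_enhancement(e, t10, acq)
    return ConcentrationCurve(curve.times, c)


def run_drift_experiment(cfg: SimulationConfig) -> BiasSummary:
    """Replicate experiment: simulate -> (drift) -> noise -> Patlak fit.

    Per replicate, Gaussian noise at the target CNR is added to the
    (possibly drifted) tissue curve and the Patlak model is fitted; the VIF
    is shared across replicates (optionally noisy when ``vif_noise``).
    Returns mean/std/bias of fitted KTrans (against the generating PS) and
    vp. Fully deterministic given (cfg, cfg.seed).
    """
    cp, ct = simulate_clean_pair(cfg)
    if cfg.drift_rate != 0.0:
        t10_vif = cfg.vif_t10 if cfg.vif_t10 is not None else cfg.tissue.t10
        ct = add_drift(ct, cfg.drift_rate, cfg.tissue.t10, cfg.acq)
        cp = add_drift(cp, cfg.drift_rate, t10_vif, cfg.acq)

    root = np.random.SeedSequence(cfg.seed)
    noise_seeds = root.spawn(cfg.n_reps)
    ktrans = np.empty(cfg.n_reps)
    vp = np.empty(cfg.n_reps)
    for i in range(cfg.n_reps):
        rng = np.random.default_rng(noise_seeds[i])
        ct_i = add_noise_to_cnr(ct, cfg.target_cnr, rng)
        cp_i = add_noise_to_cnr(cp, cfg.target_cnr, rng) if cfg.vif_noise else cp
        fit_cfg = replace(cfg.fit, seed=int(rng.integers(2**31)))
        res = fit_model(ct_i, cp_i, "patlak", fit_cfg)
        ktrans[i] = res.params.ktrans
        vp[i] = res.params.vp

    return BiasSummary(
        n_reps=cfg.n_reps,
        truth_ps=cfg.tissue.ps,
        truth_vp=cfg.tissue.vp,
        ktrans_mean=float(np.mean(ktrans)),
        ktrans_std=float(np.std(ktrans)),
        ktrans_bias=float(np.mean(ktrans) - cfg.tissue.ps),
        vp_mean=float(np.mean(vp)),
        vp_std=float(np.std(vp)),
        vp_bias=float(np.mean(vp) - cfg.tissue.vp),
        drift_rate=cfg.drift_rate,
        seed=cfg.seed,
    )


def volunteer_drift_rate(curve: SignalCurve) -> float:
    """Scanner drift of a contrast-free signal curve, in % per minute.

    OLS slope of signal versus time (minutes), normalised by the
    time-averaged signal and expressed as a percentage.
    """
    if len(curve) < 2:
        raise InvalidParameterError("need at least 2 frames")
    slope = linregress(curve.times / 60.0, curve.values).slope
    return float(100.0 * slope / np.mean(curve.values))
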