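"""Curve/config file handling and the end-to-end ROI pipeline.

Curve files are two-column delimited text with a ``time_s,<value>`` header,
where ``<value>`` is ``signal`` (scanner units), ``conc_mM`` or ``enh``; an
optional ``# baseline=<S0>`` comment line carries the pre-contrast signal of
a signal curve. The pipeline stitches the analysis together: enhancement ->
concentration -> nested-model fits -> AICc comparison -> semi-quantitative
metrics, and returns a JSON-serialisable report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CurveFormatError, InvalidParameterError
from .fitting import FitConfig, FitResult, estimate_cnr, fit_model
from .kinetic_models import MODEL_NAMES
from .model_selection import compare_models
from .semiquant import auc_norm, late_slope
from .signal_model import (
    AcquisitionParams,
    ConcentrationCurve,
    SignalCurve,
    concentration_from_enhancement,
    enhancement,
)
from .vif import blood_to_plasma

__all__ = [
    "PipelineConfig",
    "read_curve",
    "write_curve",
    "fit_result_to_dict",
    "run_pipeline",
]

_VALUE_HEADERS = ("signal", "conc_mM", "enh", "value")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the ROI analysis pipeline."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    fit: FitConfig = field(default_factory=FitConfig)
    hct: float = 0.45
    models: tuple[str, ...] = MODEL_NAMES
    t10_tissue: float = 0.969   # s
    t10_blood: float = 1.48     # s

    def __post_init__(self) -> None:
        if not self.models:
            raise InvalidParameterError("models must be non-empty")
        for m in self.models:
            if m not in MODEL_NAMES:
                raise InvalidParameterError(f"unknown model {m!r}")
        if not (0 < self.hct < 1):
            raise InvalidParameterError("hct must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionParams(**d["acquisition"])
        if "fit" in d:
            d["fit"] = FitConfig(**d["fit"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def read_curve(path) -> SignalCurve | ConcentrationCurve:
    """Read a curve file; the value header decides the returned type.

    ``signal`` (requires a ``# baseline=`` line) -> :class:`SignalCurve`;
    ``conc_mM`` -> :class:`ConcentrationCurve`; ``enh``/``value`` ->
    :class:`ConcentrationCurve` semantics are not assumed -- the raw numbers
    are returned in a :class:`ConcentrationCurve` container.
    """
    path = Path(path)
    baseline = None
    header_line = None
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "baseline=" in line:
                    baseline = float(line.split("baseline=")[1])
                continue
            if header_line is None:
                header_line = line
                cols = [c.strip() for c in line.split(",")]
                if len(cols) != 2 or cols[0] != "time_s" or cols[1] not in _VALUE_HEADERS:
                    raise CurveFormatError(
                        f"{path}:{lineno}: expected header 'time_s,<signal|conc_mM|enh|value>', "
                        f"got {line!r}"
                    )
                value_kind = cols[1]
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise CurveFormatError(f"{path}:{lineno}: expected 2 columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{lineno}: {exc}") from None
    if header_line is None or not rows:
        raise CurveFormatError(f"{path}: empty curve file")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    t, v = arr[order, 0], arr[order, 1]
    if np.any(np.diff(t) <= 0):
        raise CurveFormatError(f"{path}: duplicated or non-increasing timestamps")
    if value_kind == "signal":
        if baseline is None:
            raise CurveFormatError(f"{path}: signal curve requires a '# baseline=' line")
        return SignalCurve(t, v, baseline)
    return ConcentrationCurve(t, v)


def write_curve(path, curve: SignalCurve | ConcentrationCurve) -> None:
    """Write a curve file; lossless round trip to 12+ significant digits."""
    path = Path(path)
    is_signal = isinstance(curve, SignalCurve)
    with path.open("w") as fh:
        if is_signal:
            fh.write(f"# baseline={float(curve.baseline)!r}\n")
            fh.write("time_s,signal\n")
        else:
            fh.write("time_s,conc_mM\n")
        for t, v in zip(curve.times, curve.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def fit_result_to_dict(res: FitResult) -> dict:
    return {
        "model": res.model,
        "params": dataclasses.asdict(res.params),
        "ss": res.ss,
        "n_included": res.n_included,
        "converged": res.converged,
        "cnr": res.cnr,
    }


def run_pipeline(cfg: PipelineConfig, tissue_path, vif_path) -> dict:
    """Full ROI analysis from raw signal curves to a report dictionary.

    Inputs are signal-curve files (with baselines). Stages: enhancement;
    signal -> concentration conversion with the configured tissue/blood
    T10; haematocrit correction of the VIF; fitting of each configured
    nested model; AICc comparison; semi-quantitative metrics.
    Deterministic for a given ``cfg.fit.seed``.
    """
    tissue_path, vif_path = Path(tissue_path), Path(vif_path)
    for p in (tissue_path, vif_path):
        if not p.exists():
            raise FileNotFoundError(f"input curve file not found: {p}")

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    tissue = stage("read", read_curve, tissue_path)
    vif = stage("read", read_curve, vif_path)
    if not isinstance(tissue, SignalCurve) or not isinstance(vif, SignalCurve):
        raise CurveFormatError("pipeline inputs must be signal curves with baselines")

    acq = cfg.acquisition
    e_tissue = stage("enhancement", enhancement, tissue)
    e_vif = stage("enhancement", enhancement, vif)
    ct = ConcentrationCurve(
        tissue.times,
        stage("concentration", concentration_from_enhancement, e_tissue, cfg.t10_tissue, acq),
    )
    cb = ConcentrationCurve(
        vif.times,
        stage("concentration", concentration_from_enhancement, e_vif, cfg.t10_blood, acq),
    )
    cp = ConcentrationCurve(cb.times, blood_to_plasma(cb.values, cfg.hct))

    fits = [stage(f"fit:{m}", fit_model, ct, cp, m, cfg.fit) for m in cfg.models]
    for f in fits:
        if f.model == "patlak":
            f.cnr = estimate_cnr(ct, f)

    report: dict = {
        "acquisition": dataclasses.asdict(acq),
        "t10_tissue": cfg.t10_tissue,
        "t10_blood": cfg.t10_blood,
        "hct": cfg.hct,
        "seed": cfg.fit.seed,
        "enhancement_tissue": e_tissue.tolist(),
        "enhancement_vif": e_vif.tolist(),
        "concentration_tissue_mM": ct.values.tolist(),
        "concentration_plasma_mM": cp.values.tolist(),
        "times_s": ct.times.tolist(),
        "fits": [fit_result_to_dict(f) for f in fits],
        "semiquant": {
            "auc_norm": stage("semiquant", auc_norm, tissue.times, e_tissue, e_vif,
                              cfg.fit.exclude_first),
            "late_slope_per_min": stage("semiquant", late_slope, tissue.times, e_tissue,
                                        cfg.fit.exclude_first),
        },
    }
    if len(fits) > 1:
        comparison = stage("compare", compare_models, fits)
        report["model_comparison"] = comparison.as_dict()
    return report


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
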