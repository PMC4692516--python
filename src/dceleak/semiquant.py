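"""Semi-quantitative enhancement-curve metrics.

Model-free comparison arm: the normalised area under the enhancement curve
(tissue over vascular) and the late slope of the tissue enhancement curve.
As for model fitting, the first post-contrast frames covering the bolus
first pass are excluded.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import linregress

from .errors import InvalidParameterError

__all__ = ["auc_norm", "late_slope"]


def auc_norm(times, e_tissue, e_vif, exclude_first: int = 3) -> float:
    """Area under the tissue enhancement curve normalised by the vascular one.

    Trapezoidal areas over the included frames (times in seconds). Raises
    :class:`InvalidParameterError` when the vascular area is not positive.
    """
    t = np.asarray(times, dtype=float)[exclude_first:]
    et = np.asarray(e_tissue, dtype=float)[exclude_first:]
    ev = np.asarray(e_vif, dtype=float)[exclude_first:]
    if t.size < 2:
        raise InvalidParameterError("need at least 2 included frames")
    area_v = np.trapezoid(ev, t)
    if area_v <= 0:
        raise InvalidParameterError(f"vascular enhancement area must be > 0, got {area_v:.6g}")
    return float(np.trapezoid(et, t) / area_v)


def late_slope(times, e, exclude_first: int = 3) -> float:
    """OLS slope of the enhancement curve over included frames (per minute)."""
    t_min = np.asarray(times, dtype=float)[exclude_first:] / 60.0
    y = np.asarray(e, dtype=float)[exclude_first:]
    if t_min.size < 2:
        raise InvalidParameterError("need at least 2 included frames")
    return float(linregress(t_min, y).slope)
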