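"""AICc-based ranking of the nested tracer-kinetic models.

For least-squares fits the Akaike information criterion is
AIC = N ln(SS/N) + 2(K+1), where K is the number of kinetic parameters and
the +1 counts the fitted noise variance; the small-sample (N/K < 40)
correction adds 2K(K+1)/(N-K-1). Akaike weights convert AICc differences
into per-model selection probabilities.

Two conventions for the AIC penalty constant are offered (``2(K+1)``,
the default, or a literal ``2K+1``); they differ only in how strongly each
extra parameter is penalised and are selected with ``aic_convention``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .fitting import FitResult

__all__ = ["ModelComparison", "aicc", "akaike_weights", "compare_models"]

_CONVENTIONS = ("2(k+1)", "2k+1")


@dataclass
class ModelComparison:
    """Ranked comparison of fitted models sharing the same data."""

    models: list[str]
    aicc_values: np.ndarray
    delta: np.ndarray
    akaike_weights: np.ndarray
    best_model: str

    def as_dict(self) -> dict:
        return {
            "models": list(self.models),
            "aicc": [float(v) for v in self.aicc_values],
            "delta": [float(v) for v in self.delta],
            "akaike_weights": [float(v) for v in self.akaike_weights],
            "best_model": self.best_model,
        }


def aicc(ss: float, n: int, k: int, convention: str = "2(k+1)") -> float:
    """Corrected Akaike information criterion for a least-squares fit.

    ``ss``: residual sum of squares; ``n``: number of residual points;
    ``k``: number of free model parameters.
    """
    if convention not in _CONVENTIONS:
        raise InvalidParameterError(f"unknown AIC convention {convention!r}")
    if ss <= 0:
        raise InvalidParameterError("ss must be > 0 (use -inf AICc for exact fits)")
    if n <= k + 1:
        raise InvalidParameterError(
            f"AICc correction undefined for n={n}, k={k} (need n > k+1)"
        )
    penalty = 2.0 * (k + 1) if convention == "2(k+1)" else 2.0 * k + 1.0
    aic = n * np.log(ss / n) + penalty
    return float(aic + 2.0 * k * (k + 1) / (n - k - 1))


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: per-model probability of being the best model."""
    v = np.asarray(aicc_values, dtype=float)
    if v.size < 1 or np.any(~np.isfinite(v)):
        raise InvalidParameterError("AICc values must be finite")
    delta = v - np.min(v)
    w = np.exp(-delta / 2.0)
    return w / np.sum(w)


def compare_models(fits: list[FitResult], convention: str = "2(k+1)") -> ModelComparison:
    """Rank fitted models by AICc and Akaike weight.

    All fits must share the same data (equal included-point count). Ties in
    AICc are broken toward the model with fewer parameters.
    """
    if not fits:
        raise InvalidParameterError("at least one fit is required")
    ns = {f.n_included for f in fits}
    if len(ns) != 1:
        raise InvalidParameterError("fits must share the same number of data points")
    n = ns.pop()
    models = [f.model for f in fits]
    ks = [f.params.k for f in fits]
    values = np.array([aicc(f.ss, n, k, convention) for f, k in zip(fits, ks)])
    weights = akaike_weights(values)
    delta = values - np.min(values)
    order = sorted(range(len(fits)), key=lambda i: (values[i], ks[i]))
    return ModelComparison(
        models=models,
        aicc_values=values,
        delta=delta,
        akaike_weights=weights,
        best_model=models[order[0]],
    )
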