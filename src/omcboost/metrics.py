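"""Performance metrics and response-scale conversion.

The response throughout the package is the log10 IC50 (drug concentration
halving cell viability). Public pharmacogenomics tables often report natural-log
IC50s, hence the explicit conversion helper; it is never applied implicitly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedCorrelationError",
    "spearman_rs",
    "r_squared",
    "natural_log_to_log10",
]

LOG10_E = float(np.log10(np.e))


class UndefinedCorrelationError(ValueError):
    """Raised when a rank correlation is undefined (a constant input vector)."""


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def spearman_rs(pred, obs) -> float:
    """Spearman rank correlation between predicted and observed responses.

    Equals the Pearson correlation of the two vectors' mid-ranks (ties receive
    their average rank). Raises :class:`UndefinedCorrelationError` when either
    vector is constant, so callers can distinguish "no correlation information"
    from a numeric correlation of zero.
    """
    p = _as_vector(pred, "pred")
    o = _as_vector(obs, "obs")
    if p.size != o.size:
        raise ValueError(f"length mismatch: pred has {p.size}, obs has {o.size}")
    if p.size < 3:
        raise ValueError("spearman_rs requires at least 3 paired values")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.spearmanr(p, o).statistic)


def r_squared(pred, obs) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot is centered on mean(obs); the value may be negative when the model
    predicts worse than the observed mean.
    """
    p = _as_vector(pred, "pred")
    o = _as_vector(obs, "obs")
    if p.size != o.size:
        raise ValueError(f"length mismatch: pred has {p.size}, obs has {o.size}")
    if p.size < 2:
        raise ValueError("r_squared requires at least 2 paired values")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared undefined: observed responses are constant")
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot


def natural_log_to_log10(values) -> np.ndarray:
    """Convert natural-log IC50 values to log10 IC50 (elementwise x * log10(e))."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("natural_log_to_log10 requires finite inputs")
    return arr * LOG10_E
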