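"""Small numeric helpers used across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "logit", "clip_rf"]


def sigmoid(x):
    """Numerically stable logistic function sigma(x) = 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def logit(p):
    """Inverse of :func:`sigmoid`; p must lie strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    if out.ndim == 0:
        return float(out)
    return out


def clip_rf(rf, lo: float = 0.01, hi: float = 0.99):
    """Clip retardation factors away from {0, 1} so the logit is finite."""
    return np.clip(np.asarray(rf, dtype=float), lo, hi)
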