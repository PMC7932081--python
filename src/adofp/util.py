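"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit
from scipy.special import logit as _logit

__all__ = ["logit", "invlogit", "clip_proportion", "norm_logpdf"]

# keep transformed values finite; proportions are clipped into the open interval
_EPS = 1e-12


def logit(p):
    """Log-odds transform, vectorised; inputs clipped into (0, 1)."""
    out = _logit(np.minimum(np.maximum(p, _EPS), 1.0 - _EPS))
    if np.ndim(out) == 0:
        return float(out)
    return out


def invlogit(x):
    """Inverse log-odds (expit), numerically stable for large |x|."""
    out = _expit(x)
    if np.ndim(out) == 0:
        return float(out)
    return out


def clip_proportion(p, eps: float = 1e-9):
    return np.clip(p, eps, 1.0 - eps)


def norm_logpdf(x, mean, var):
    """Normal log-density with variance parameterisation (no scipy overhead)."""
    var = np.asarray(var, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * var) + (np.asarray(x) - mean) ** 2 / var)
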