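"""Probability/hazard conversions under an exponential survival assumption.

Annual transition probabilities are interconverted with constant hazards via
``p = 1 - exp(-r t)``, and treatment effects expressed as odds/hazard ratios
act multiplicatively on the hazard scale: ``r_adj = r * OR``, which is then
mapped back to a cycle probability.  All functions accept scalars or numpy
arrays and are exact inverses of each other on their shared domain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rate_to_prob", "prob_to_rate", "apply_odds_ratio"]


def rate_to_prob(rate, t: float = 1.0):
    """Convert an instantaneous event rate to a probability over ``t`` years.

    Parameters
    ----------
    rate : float or array_like
        Non-negative event rate per year.
    t : float
        Exposure time in years, strictly positive.

    Returns
    -------
    float or ndarray
        ``1 - exp(-rate * t)``, in ``[0, 1)``.
    """
    rate = np.asarray(rate, dtype=float)
    if t <= 0:
        raise ValueError(f"exposure time must be positive, got t={t}")
    if np.any(rate < 0):
        raise ValueError("event rate must be non-negative")
    out = -np.expm1(-rate * t)
    return out.item() if out.ndim == 0 else out


def prob_to_rate(p, t: float = 1.0):
    """Invert :func:`rate_to_prob`: the constant hazard giving probability ``p``.

    ``p`` must lie in ``[0, 1)``; a probability of 1 would imply an infinite
    hazard under the exponential model.
    """
    p = np.asarray(p, dtype=float)
    if t <= 0:
        raise ValueError(f"exposure time must be positive, got t={t}")
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("probability must lie in [0, 1)")
    out = -np.log1p(-p) / t
    return out.item() if out.ndim == 0 else out


def apply_odds_ratio(p, or_, t: float = 1.0):
    """Adjust an annual probability by a risk-reduction ratio on the hazard scale.

    The probability is converted to a hazard, multiplied by ``or_`` and
    converted back.  The result is smaller than ``p`` exactly when ``or_ < 1``.
    """
    or_ = np.asarray(or_, dtype=float)
    if np.any(or_ <= 0):
        raise ValueError("odds ratio must be positive")
    rate = prob_to_rate(p, t)
    return rate_to_prob(rate * or_, t)
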