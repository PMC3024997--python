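"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np

# Probabilities are kept this far from {0, 1} so log-likelihoods stay finite.
PROB_EPS = 1e-12

# Wald critical value for 95% two-sided intervals.
Z_95 = 1.959964


def logistic(eta: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable inverse-logit."""
    out = np.empty_like(eta, dtype=float) if isinstance(eta, np.ndarray) else None
    if out is None:
        return 1.0 / (1.0 + np.exp(-eta)) if eta >= 0 else np.exp(eta) / (1.0 + np.exp(eta))
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def clip_prob(p: np.ndarray | float) -> np.ndarray | float:
    """Clip probabilities away from the boundary (finite log contract)."""
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed tables do.

    numpy/python round() use banker's rounding; descriptive tables in this
    package follow the half-up convention instead.
    """
    factor = 10.0**ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x != 0 else 0.0
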