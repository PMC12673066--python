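"""Small shared helpers (circular statistics, Pearson wrappers)."""

from __future__ import annotations

import numpy as np

__all__ = ["circular_corr", "circular_dist", "pearson"]


def circular_dist(a_deg: np.ndarray, b_deg: np.ndarray) -> np.ndarray:
    """Signed circular difference a - b in (-180, 180] degrees."""
    return (np.asarray(a_deg, float) - np.asarray(b_deg, float) + 180.0) % 360.0 - 180.0


def circular_corr(a_deg: np.ndarray, b_deg: np.ndarray) -> float:
    """Fisher-Lee T-linear circular correlation between two angle samples.

    rho = sum_{i,j} sin(a_i - a_j) sin(b_i - b_j) /
          sqrt(sum sin^2(a_i - a_j) * sum sin^2(b_i - b_j)),
    evaluated in O(n) via product-to-sum identities.  Well defined even for
    marginally uniform angles (where the circular mean is degenerate).
    """
    a = np.deg2rad(np.asarray(a_deg, float))
    b = np.deg2rad(np.asarray(b_deg, float))
    sa, ca, sb, cb = np.sin(a), np.cos(a), np.sin(b), np.cos(b)
    num = (sa @ sb) * (ca @ cb) - (sa @ cb) * (ca @ sb)
    n = a.size

    def _ss(x):
        return (n**2 - np.sum(np.cos(2 * x)) ** 2 - np.sum(np.sin(2 * x)) ** 2) / 2.0

    denom = np.sqrt(_ss(a) * _ss(b)) / 2.0
    if denom == 0:
        return 0.0
    return float(num / denom)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r on flattened arrays, NaN-safe only for constant input (-> 0)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
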