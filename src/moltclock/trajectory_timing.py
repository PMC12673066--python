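"""Bulk developmental pseudo-time from phase-binned oscillating gene sets.

Thousands of genes oscillate once per larval stage with diverse peak phases.
Splitting a phase-annotated gene list into four 90°-wide bins centred at 0°,
90°, 180° and 270° and subtracting the anti-phase pairs yields two orthogonal
timing readouts per sample,

    x_s = mean(bin 1) - mean(bin 3),    y_s = mean(bin 2) - mean(bin 4),

computed on gene-level mean-normalized log2 expression.  Samples trace a
counterclockwise circle in (x, y) as development proceeds; atan2 gives each
sample a wrapped angle, which is unwrapped along collection order and
smoothed (LOESS) into a continuous pseudo-time.  A final rotation calibrates
phases so that 0° corresponds to molt exit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .rhythm_fit import SampleTiming

__all__ = [
    "PhaseBins",
    "bin_genes",
    "trajectory_readout",
    "pseudotime_from_xy",
    "calibrate_phases",
]

BIN_CENTERS = np.array([0.0, 90.0, 180.0, 270.0])


@dataclass
class PhaseBins:
    """Four phase-binned gene sets partitioning [0, 360).

    Bin i (1-based) holds genes peaking at ``BIN_CENTERS[i-1] ± 45°``;
    boundary ties go to the lower bin index.
    """

    assignment: pd.Series  # gene -> bin in {1, 2, 3, 4}

    def genes(self, b: int) -> pd.Index:
        return self.assignment.index[self.assignment == b]

    def __post_init__(self) -> None:
        counts = self.assignment.value_counts()
        self.sizes = {b: int(counts.get(b, 0)) for b in (1, 2, 3, 4)}


def bin_genes(phases: pd.Series) -> PhaseBins:
    """Assign each gene to its nearest bin centre (wrapped); ties -> lower bin."""
    p = np.asarray(phases, dtype=float)
    if np.any((p < 0) | (p >= 360)):
        raise ValueError("phases must lie in [0, 360)")
    # circular distance to each centre
    d = np.abs((p[:, None] - BIN_CENTERS[None, :] + 180.0) % 360.0 - 180.0)
    # argmin takes the first (lower-index) bin on exact ties
    bins = np.argmin(np.round(d, 9), axis=1) + 1
    return PhaseBins(pd.Series(bins, index=phases.index, name="bin"))


def trajectory_readout(expr: pd.DataFrame, bins: PhaseBins) -> pd.DataFrame:
    """Orthogonal timing readouts (x_s, y_s) per sample.

    ``expr`` is a genes x samples log2 matrix; it is mean-normalized at the
    gene level here (idempotent if already centred).
    """
    for b in (1, 2, 3, 4):
        if bins.sizes[b] == 0:
            raise ValueError(f"phase bin {b} is empty")
    centred = expr.sub(expr.mean(axis=1), axis=0)
    means = {
        b: centred.loc[centred.index.intersection(bins.genes(b))].mean(axis=0)
        for b in (1, 2, 3, 4)
    }
    for b in (1, 2, 3, 4):
        if means[b].isna().any():
            raise ValueError(f"no expression data for genes of bin {b}")
    return pd.DataFrame({"x": means[1] - means[3], "y": means[2] - means[4]})


def _unwrap_deg(angles: np.ndarray) -> np.ndarray:
    return np.rad2deg(np.unwrap(np.deg2rad(angles)))


def pseudotime_from_xy(
    xy: pd.DataFrame,
    smooth_span: float = 0.75,
    replicate: np.ndarray | None = None,
) -> SampleTiming:
    """Pseudo-time per sample from trajectory readouts.

    Angle = atan2(y, x); unwrapped along collection order (each replicate
    independently) by minimizing successive jumps; LOESS of unwrapped angle
    on sample index gives the final pseudo-time.  Monotonicity is not
    enforced.
    """
    if len(xy) < 4:
        raise ValueError("at least 4 samples required")
    angles = np.rad2deg(np.arctan2(xy["y"].to_numpy(), xy["x"].to_numpy()))
    rep = np.zeros(len(xy), dtype=int) if replicate is None else np.asarray(replicate)
    unwrapped = np.empty(len(xy))
    for r in np.unique(rep):
        mask = rep == r
        idx = np.flatnonzero(mask)
        u = _unwrap_deg(angles[mask])
        smoothed = lowess(
            u, np.arange(idx.size, dtype=float), frac=smooth_span, return_sorted=False
        )
        unwrapped[idx] = smoothed
    return SampleTiming(samples=list(xy.index), unwrapped=unwrapped, replicate=rep)


def calibrate_phases(
    phases: np.ndarray | pd.Series | float,
    molt_exit_angle: float,
) -> np.ndarray | pd.Series | float:
    """Rotate phases so molt exit sits at 0°: ``(phase - molt_exit) mod 360``.

    A pure rotation — pairwise phase differences are preserved exactly.
    """
    out = np.mod(np.asarray(phases, dtype=float) - molt_exit_angle, 360.0)
    if isinstance(phases, pd.Series):
        return pd.Series(out, index=phases.index, name=phases.name)
    if np.ndim(phases) == 0:
        return float(out)
    return out
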