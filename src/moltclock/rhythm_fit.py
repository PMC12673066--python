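"""Harmonic ("cosinor") fitting of rhythmic time-course signals.

Chromatin accessibility and gene expression during C. elegans larval
development oscillate once per larval stage.  On a log2 scale, an element g
measured at developmental phase ``phi_s`` (degrees; one stage = 360°) is
modelled as

    z_{g,s} = mu_g + x_g * cos(phi_s) + y_g * sin(phi_s) + gamma_g * lambda_s + eps

where ``(x_g, y_g)`` are Cartesian phase coordinates (amplitude
``A = sqrt(x^2 + y^2)``, peak phase ``phi = atan2(y, x)``), and ``lambda_s``
is a monotone trend covariate capturing graded (non-oscillatory) drift.
Elements are classified as oscillating (A above an amplitude cutoff),
graded (|gamma| above a trend cutoff) or flat.

This module also provides the matrix normalization applied before fitting
(quantile normalization plus log2 with pseudocount), a two-sample batch
correction, promoter-window peak-to-gene assignment, and circular phase-delay
statistics between linked chromatin and mRNA rhythms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SampleTiming",
    "normalize_matrix",
    "batch_correct_pair",
    "fit_cosine",
    "classify",
    "assign_peaks_to_genes",
    "phase_delay",
]

OSCILLATING = "oscillating"
GRADED = "graded"
FLAT = "flat"


@dataclass
class SampleTiming:
    """Developmental timing of the samples of a time course.

    Parameters
    ----------
    samples
        Sample identifiers, in collection order within each replicate.
    unwrapped
        Monotone (within replicate) developmental pseudo-time in degrees.
    replicate
        Replicate label per sample; fits share coefficients across
        replicates but each sample keeps its own phase.
    condition
        Optional condition label (e.g. vehicle/auxin) per sample.
    """

    samples: list[str]
    unwrapped: np.ndarray
    replicate: np.ndarray | None = None
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unwrapped = np.asarray(self.unwrapped, dtype=float)
        if len(self.samples) != self.unwrapped.size:
            raise ValueError("samples and unwrapped must have equal length")
        if self.replicate is None:
            self.replicate = np.zeros(self.unwrapped.size, dtype=int)
        self.replicate = np.asarray(self.replicate)

    @property
    def is_monotone(self) -> bool:
        """True if unwrapped time is non-decreasing within every replicate.

        Inferred pseudo-time is not forced monotone, so this is advisory.
        """
        return all(
            not np.any(np.diff(self.unwrapped[self.replicate == rep]) < 0)
            for rep in np.unique(self.replicate)
        )

    @property
    def wrapped(self) -> np.ndarray:
        """Phase in [0, 360) per sample."""
        return np.mod(self.unwrapped, 360.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample": self.samples,
                "wrapped": self.wrapped,
                "unwrapped": self.unwrapped,
                "replicate": self.replicate,
            }
        )
        if self.condition is not None:
            df["condition"] = self.condition
        return df


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the cross-sample mean distribution.

    Each column's sorted values are replaced by the row means of the
    column-wise sorted matrix; ties within a column receive the mean of the
    reference values at their tied ranks (mean-rank tie policy).
    """
    n, m = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(m):
        col = values[:, j]
        # average reference over tied ranks
        ranks = np.empty(n, dtype=int)
        ranks[order[:, j]] = np.arange(n)
        uniq, inv = np.unique(col, return_inverse=True)
        ref_by_rank = np.empty(n)
        ref_by_rank[:] = reference
        sums = np.zeros(uniq.size)
        counts = np.zeros(uniq.size)
        np.add.at(sums, inv, ref_by_rank[ranks])
        np.add.at(counts, inv, 1.0)
        out[:, j] = (sums / counts)[inv]
    return out


def normalize_matrix(
    counts: pd.DataFrame,
    pseudocount: float = 8.0,
    quantile: bool = True,
    library_scale: bool = False,
) -> pd.DataFrame:
    """Normalize a nonnegative count matrix (elements x samples) to log2 scale.

    With ``quantile=True`` each sample's distribution is replaced by the
    cross-sample average distribution (correcting nonlinear trends) before
    ``log2(v + pseudocount)``.  ``library_scale=True`` first rescales every
    sample to the mean library size (used for RNA counts).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    if library_scale:
        lib = values.sum(axis=0)
        if np.any(lib == 0):
            raise ValueError("sample with zero library size")
        values = values / lib * lib.mean()
    if quantile:
        values = _quantile_normalize(values)
    out = np.log2(values + pseudocount)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def batch_correct_pair(
    matrix: pd.DataFrame,
    outliers: list[str],
    neighbors: list[str],
) -> pd.DataFrame:
    """Correct a pair of outlier samples against their time-course neighbours.

    The correction vector is ``rowmean(outliers) - rowmean(neighbors)``; it is
    subtracted from the outlier columns only.
    """
    if len(outliers) != 2:
        raise ValueError("exactly 2 outlier samples required")
    if len(neighbors) != 4:
        raise ValueError("exactly 4 neighbor samples required")
    if set(outliers) & set(neighbors):
        raise ValueError("outliers and neighbors must be disjoint")
    missing = (set(outliers) | set(neighbors)) - set(matrix.columns)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)}")
    out = matrix.copy()
    correction = matrix[outliers].mean(axis=1) - matrix[neighbors].mean(axis=1)
    for s in outliers:
        out[s] = matrix[s] - correction
    return out


def _design_matrix(timing: SampleTiming, trend: np.ndarray | None) -> np.ndarray:
    phi = np.deg2rad(timing.unwrapped)
    cols = [np.ones_like(phi), np.cos(phi), np.sin(phi)]
    if trend is not None:
        cols.append(np.asarray(trend, dtype=float))
    return np.column_stack(cols)


def fit_cosine(
    z: pd.DataFrame | np.ndarray,
    timing: SampleTiming,
    trend: np.ndarray | None = None,
    amp_cut: float = 0.25,
    graded_cut: float = 0.25,
) -> pd.DataFrame:
    """OLS cosine + trend fit per element (rows of ``z``).

    Both replicates enter one joint fit through their own sample phases with
    shared coefficients.  Returns a table with columns
    ``mu, x, y, gamma, amplitude, phase, class`` (phase in degrees, [0,360)).

    Requires at least 5 samples spanning more than 180 degrees of wrapped
    phase, otherwise the harmonic coefficients are not reliably identifiable.
    """
    if isinstance(z, pd.Series):
        z = z.to_frame().T
    values = np.atleast_2d(np.asarray(z, dtype=float))
    index = z.index if isinstance(z, pd.DataFrame) else pd.RangeIndex(values.shape[0])
    n = values.shape[1]
    if n != timing.unwrapped.size:
        raise ValueError("signal and timing lengths differ")
    if n < 5:
        raise ValueError("at least 5 samples required")
    if _phase_span(timing.wrapped) <= 180.0:
        raise ValueError("sample phases must span more than 180 degrees")
    X = _design_matrix(timing, trend)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design; phases (or trend) degenerate")
    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    mu, xc, yc = beta[0], beta[1], beta[2]
    gamma = beta[3] if trend is not None else np.zeros_like(mu)
    amp = np.hypot(xc, yc)
    phase = np.mod(np.rad2deg(np.arctan2(yc, xc)), 360.0)
    labels = classify(amp, gamma, amp_cut=amp_cut, graded_cut=graded_cut)
    return pd.DataFrame(
        {
            "mu": mu,
            "x": xc,
            "y": yc,
            "gamma": gamma,
            "amplitude": amp,
            "phase": phase,
            "class": labels,
        },
        index=index,
    )


def _phase_span(wrapped: np.ndarray) -> float:
    """Angular span covered by wrapped phases: 360 minus the largest gap."""
    phis = np.sort(np.unique(np.mod(wrapped, 360.0)))
    if phis.size < 2:
        return 0.0
    gaps = np.diff(np.concatenate([phis, [phis[0] + 360.0]]))
    return 360.0 - gaps.max()


def classify(
    amplitude: np.ndarray | float,
    gamma: np.ndarray | float,
    amp_cut: float = 0.25,
    graded_cut: float = 0.25,
) -> np.ndarray | str:
    """Classify fits: oscillating iff A > amp_cut, else graded iff |gamma| >
    graded_cut, else flat."""
    amp = np.asarray(amplitude, dtype=float)
    g = np.asarray(gamma, dtype=float)
    labels = np.where(amp > amp_cut, OSCILLATING, np.where(np.abs(g) > graded_cut, GRADED, FLAT))
    if labels.ndim == 0:
        return str(labels)
    return labels


def promoter_window(tss: int, strand: str, upstream: int = 2000, into_gene: int = 500) -> tuple[int, int]:
    """Promoter window around a TSS, 0-based half-open.

    For a + strand gene the window reaches ``upstream`` bp before the TSS and
    ``into_gene`` bp into the gene body; the - strand window is the mirror.
    """
    if strand == "+":
        return tss - upstream, tss + into_gene
    if strand == "-":
        return tss - into_gene, tss + upstream
    raise ValueError(f"unknown strand {strand!r}")


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    upstream: int = 2000,
    into_gene: int = 500,
    amplitudes: pd.Series | None = None,
) -> pd.DataFrame:
    """Link peaks to genes whose promoter window they overlap by >= 1 bp.

    ``peaks`` needs columns chrom/start/end/name (BED, 0-based half-open);
    ``tss`` needs gene/chrom/start/end/strand with TSS = start on +, end on -.
    Links are many-to-many.  If per-peak ``amplitudes`` are given, the linked
    peak of maximal amplitude per gene is flagged ``top``.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples():
            if row.start >= row.end:
                raise ValueError(f"empty interval for peak {row.name}")
            tree.addi(row.start, row.end, row.name)
        trees[chrom] = tree
    links = []
    for row in tss.itertuples():
        t = row.start if row.strand == "+" else row.end
        lo, hi = promoter_window(t, row.strand, upstream, into_gene)
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(lo, hi):
            links.append((hit.data, row.gene))
    out = pd.DataFrame(links, columns=["peak", "gene"]).drop_duplicates()
    out = out.sort_values(["gene", "peak"]).reset_index(drop=True)
    if amplitudes is not None and not out.empty:
        out["amplitude"] = amplitudes.reindex(out["peak"]).to_numpy()
        top_idx = out.groupby("gene")["amplitude"].idxmax()
        out["top"] = False
        out.loc[top_idx, "top"] = True
    return out


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, in (-180, 180]."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))


def phase_delay(
    peak_phases: np.ndarray,
    gene_phases: np.ndarray,
    period_minutes: float,
) -> tuple[float, float]:
    """Circular mean delay of mRNA phase behind chromatin phase.

    Returns ``(degrees, minutes)``; minutes = degrees / 360 * period.
    """
    peak_phases = np.asarray(peak_phases, dtype=float)
    gene_phases = np.asarray(gene_phases, dtype=float)
    if peak_phases.size == 0:
        raise ValueError("at least one pair required")
    if peak_phases.shape != gene_phases.shape:
        raise ValueError("phase arrays must match")
    delay = circular_mean_deg(gene_phases - peak_phases)
    return delay, delay / 360.0 * period_minutes
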