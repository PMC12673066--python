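"""Predictor matrices for the TF phase-vector models.

Four flavours of peaks x TFs feature matrix are built here:

* quantitative — log2 ChIP-vs-input enrichment per peak, library scaled,
  mode-centred per factor (the modal, i.e. unbound, enrichment sits at 0)
  and rescaled so all factors share a common 99th percentile;
* binary occupancy — 1 iff any ChIP peak of the factor overlaps the peak;
* binned — each factor's quantitative enrichment cut into equidistant bins
  for threshold-free dose-response modelling;
* motif bins — counts of weak/medium/strong/very strong PWM hits per peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import gaussian_kde

__all__ = [
    "EnrichmentMatrix",
    "normalize_chip",
    "rescale_p99",
    "occupancy_from_peaks",
    "bin_enrichment",
    "one_hot_bins",
    "motif_bin_counts",
    "pwm_log_odds",
]


@dataclass
class EnrichmentMatrix:
    """Peaks x TFs predictor matrix with its normalization metadata."""

    values: pd.DataFrame
    mode: str  # binary | quantitative | binned | motif_bins
    mode_shift: pd.Series | None = None  # per-TF centering applied
    p99_scale: pd.Series | None = None  # per-TF rescale factors
    removed_peaks: pd.Index | None = None
    n_bins: int | None = None


def _library_scale(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return counts / lib * lib.mean()


def kde_mode(values: np.ndarray, bandwidth: float = 0.04, n_grid: int = 2048) -> float:
    """Location of the density maximum, Gaussian KDE with absolute bandwidth."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        return float(v[0])
    kde = gaussian_kde(v, bw_method=bandwidth / sd)
    grid = np.linspace(v.min(), v.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def normalize_chip(
    ip: pd.DataFrame,
    input_counts: pd.DataFrame,
    pseudocount: float = 8.0,
    input_cut: float = 11.0,
    kde_bandwidth: float = 0.04,
) -> EnrichmentMatrix:
    """Quantitative log2 ChIP enrichment, mode-centred per factor.

    IP and input count matrices (peaks x factors, aligned rows/columns) are
    library-scaled to the average library size and log2-transformed with a
    pseudocount; enrichment = IP - input.  Peaks whose input log2 count
    exceeds ``input_cut`` in any factor are removed (repeat artifacts).
    Each factor's column is shifted so the modal enrichment — the unbound
    bulk of peaks, located by a KDE with bandwidth 0.04 — sits at 0.
    """
    if not ip.index.equals(input_counts.index) or not ip.columns.equals(input_counts.columns):
        raise ValueError("ip and input must be aligned on the same peaks and TFs")
    log_ip = np.log2(_library_scale(ip) + pseudocount)
    log_in = np.log2(_library_scale(input_counts) + pseudocount)
    removed = log_in.index[(log_in > input_cut).any(axis=1)]
    enr = (log_ip - log_in).drop(index=removed)
    if enr.empty:
        raise ValueError("all peaks removed by the input filter")
    shifts = {}
    for tf in enr.columns:
        shifts[tf] = kde_mode(enr[tf].to_numpy(), bandwidth=kde_bandwidth)
    shift = pd.Series(shifts, name="mode_shift")
    centred = enr - shift
    return EnrichmentMatrix(
        values=centred,
        mode="quantitative",
        mode_shift=shift,
        removed_peaks=removed,
    )


def rescale_p99(E: EnrichmentMatrix) -> EnrichmentMatrix:
    """Rescale factors to a common 99th percentile.

    Each column is divided by its own p99 and multiplied by the average p99
    over all factors, so factors operate on a numerically similar range
    without changing within-factor rank order.
    """
    if E.mode != "quantitative":
        raise ValueError("p99 rescaling applies to quantitative enrichment")
    if len(E.values) < 100:
        raise ValueError("at least 100 peaks per TF required for a stable p99")
    p99 = E.values.quantile(0.99)
    if (p99 <= 0).any():
        raise ValueError("non-positive 99th percentile")
    scale = p99.mean() / p99
    return EnrichmentMatrix(
        values=E.values * scale,
        mode="quantitative",
        mode_shift=E.mode_shift,
        p99_scale=scale.rename("p99_scale"),
        removed_peaks=E.removed_peaks,
    )


def _tree(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        t = IntervalTree()
        for row in sub.itertuples():
            t.addi(row.start, row.end, getattr(row, "name", None))
        trees[chrom] = t
    return trees


def occupancy_from_peaks(
    chip_peaks: dict[str, pd.DataFrame],
    atac_peaks: pd.DataFrame,
    min_hits: int = 10,
    osc_class: pd.Series | None = None,
) -> tuple[EnrichmentMatrix, pd.DataFrame]:
    """Binary occupancy matrix from per-TF ChIP peak interval sets.

    Cell (peak, TF) is 1 iff any ChIP peak of that TF overlaps the ATAC peak
    by >= 1 bp; TFs occupying fewer than ``min_hits`` ATAC peaks are dropped.
    Per-TF stats report the occupied-peak count and, when peak class labels
    are provided, the oscillating fraction among occupied peaks next to the
    overall (background) oscillating fraction.
    """
    cols = {}
    for tf, intervals in chip_peaks.items():
        trees = _tree(intervals)
        hits = np.zeros(len(atac_peaks), dtype=int)
        for i, row in enumerate(atac_peaks.itertuples()):
            t = trees.get(row.chrom)
            if t is not None and t.overlap(row.start, row.end):
                hits[i] = 1
        cols[tf] = hits
    occ = pd.DataFrame(cols, index=atac_peaks["name"].to_numpy())
    keep = occ.sum(axis=0) >= min_hits
    occ = occ.loc[:, keep]
    stats = pd.DataFrame({"n_occupied": occ.sum(axis=0)})
    if osc_class is not None:
        is_osc = (osc_class.reindex(occ.index) == "oscillating").to_numpy()
        stats["frac_oscillating"] = [
            is_osc[occ[tf].to_numpy() == 1].mean() if occ[tf].sum() else np.nan
            for tf in occ.columns
        ]
        stats["background_frac"] = is_osc.mean()
    return EnrichmentMatrix(values=occ, mode="binary"), stats


def bin_enrichment(E: EnrichmentMatrix, n_bins: int = 7) -> EnrichmentMatrix:
    """Stratify each factor's enrichment into equidistant bins (codes 1..n).

    Bin edges are equally spaced between the factor's observed min and max;
    the maximum falls in the top bin (inclusive upper edge).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    out = {}
    for tf in E.values.columns:
        col = E.values[tf].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            raise ValueError(f"zero-range column {tf!r}")
        codes = np.floor((col - lo) / (hi - lo) * n_bins).astype(int) + 1
        out[tf] = np.clip(codes, 1, n_bins)
    return EnrichmentMatrix(
        values=pd.DataFrame(out, index=E.values.index), mode="binned", n_bins=n_bins
    )


def one_hot_bins(E: EnrichmentMatrix) -> pd.DataFrame:
    """One-hot expansion of a binned matrix; bin 1 is the implicit reference
    (absorbed by the model intercept, so bin paths start at the origin)."""
    if E.mode != "binned":
        raise ValueError("one_hot_bins expects a binned matrix")
    cols = {}
    for tf in E.values.columns:
        codes = E.values[tf].to_numpy()
        for b in range(2, E.n_bins + 1):
            cols[f"{tf}:bin{b}"] = (codes == b).astype(float)
    return pd.DataFrame(cols, index=E.values.index)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def pwm_log_odds(pwm: np.ndarray, background: np.ndarray | None = None) -> np.ndarray:
    """Log-odds matrix (4 x width) from a probability PWM.

    Columns are renormalized after adding a 1e-3 pseudo-probability; the
    background defaults to uniform 0.25.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("pwm must be 4 x width (rows A, C, G, T)")
    if np.any(pwm.sum(axis=0) == 0):
        raise ValueError("pwm contains an all-zero column")
    p = pwm + 1e-3
    p = p / p.sum(axis=0, keepdims=True)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return np.log2(p / bg[:, None])


def _scan_scores(seq: str, lods: np.ndarray) -> np.ndarray:
    """Sliding-window log-odds scores on one strand; N contributes 0."""
    w = lods.shape[1]
    n = len(seq)
    if n < w:
        return np.empty(0)
    # one-hot with N as all-zero row -> contributes 0 log-odds
    onehot = np.zeros((4, n))
    for i, base in enumerate(seq.upper()):
        j = _BASE_INDEX.get(base)
        if j is not None:
            onehot[j, i] = 1.0
    scores = np.zeros(n - w + 1)
    for k in range(w):
        scores += lods[:, k] @ onehot[:, k : k + n - w + 1]
    return scores


def motif_bin_counts(
    sequences: dict[str, str],
    pwms: dict[str, np.ndarray],
    n_bins: int = 4,
    base_cutoff_frac: float = 0.6,
    background: np.ndarray | None = None,
) -> EnrichmentMatrix:
    """Counts of binned-strength motif hits per peak.

    Both strands of each peak sequence are scanned with each factor's
    log-odds matrix; positions scoring above ``base_cutoff_frac`` of the
    maximum achievable score are hits, stratified into ``n_bins`` equidistant
    score bins up to that maximum (weak .. very strong for the default 4).
    The result has ``len(pwms) * n_bins`` columns.
    """
    bin_labels = (
        ["weak", "medium", "strong", "very_strong"]
        if n_bins == 4
        else [f"bin{b}" for b in range(1, n_bins + 1)]
    )
    cols: dict[str, np.ndarray] = {}
    peaks = list(sequences)
    for tf, pwm in pwms.items():
        lods = pwm_log_odds(pwm, background)
        max_score = lods.max(axis=0).sum()
        cutoff = base_cutoff_frac * max_score
        edges = np.linspace(cutoff, max_score, n_bins + 1)
        counts = np.zeros((len(peaks), n_bins), dtype=int)
        for i, pk in enumerate(peaks):
            seq = sequences[pk]
            rc = seq.translate(_COMPLEMENT)[::-1]
            scores = np.concatenate([_scan_scores(seq, lods), _scan_scores(rc, lods)])
            hits = scores[scores >= cutoff]
            if hits.size:
                codes = np.clip(
                    np.searchsorted(edges, hits, side="right") - 1, 0, n_bins - 1
                )
                for b in range(n_bins):
                    counts[i, b] = int(np.sum(codes == b))
        for b, lab in enumerate(bin_labels):
            cols[f"{tf}:{lab}"] = counts[:, b]
    return EnrichmentMatrix(
        values=pd.DataFrame(cols, index=pd.Index(peaks, name="peak")),
        mode="motif_bins",
        n_bins=n_bins,
    )
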