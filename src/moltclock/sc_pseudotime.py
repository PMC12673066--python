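"""Circular pseudo-time on single-cell data.

Many C. elegans tissues progress through the molting cycle asynchronously
across a population, so cells of one tissue arrange on a closed ring in
expression space.  This module goes from raw counts and a 2D embedding to
per-tissue rhythmic expression profiles:

1. cell/gene filtering and library normalization;
2. density-based segmentation of the embedding into cell clusters;
3. per-cluster PCA and a circularity check on PC1/PC2;
4. angular pseudo-time via atan2 around a robust ring centre;
5. smoothing-spline expression profiles on a fixed 36-point angle grid
   (10° steps), with the data wrapped by +-360° so the profile is
   continuous across 0°;
6. synchronization of each relative profile against a phase-annotated
   reference by exhaustive search over all 36 starting points x 2
   orientations = 72 candidate versions;
7. weighted in-silico reconstitution of a bulk time course from the
   synchronized tissue profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import make_smoothing_spline
from sklearn.decomposition import PCA

from .utils import pearson

__all__ = [
    "GRID_DEG",
    "PseudotimeProfile",
    "RingResult",
    "preprocess_cells",
    "segment_embedding",
    "cluster_ring",
    "ring_angles",
    "smooth_profile",
    "apply_sync",
    "reference_profiles",
    "max_normalize",
    "synchronize_profile",
    "reconstitute_bulk",
]

N_GRID = 36
GRID_DEG = np.arange(N_GRID) * 10.0  # 0, 10, ..., 350

# spar -> penalty mapping for the smoothing spline (see smooth_profile)
_SPAR_BASE = 6.7e-11


@dataclass
class PseudotimeProfile:
    """Gene x 36-angle-grid expression profile for one cell cluster.

    ``direction``/``offset`` are unset for a relative profile and filled by
    :func:`synchronize_profile`; ``apply_sync(expression, offset, direction)``
    then yields the absolutely timed profile.
    """

    expression: pd.DataFrame  # genes x 36, columns = GRID_DEG
    direction: int | None = None
    offset: int | None = None
    sync_correlation: float | None = None
    n_local_maxima: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expression.shape[1] != N_GRID:
            raise ValueError(f"profile must have exactly {N_GRID} grid columns")

    @property
    def synchronized(self) -> pd.DataFrame:
        if self.direction is None or self.offset is None:
            raise ValueError("profile not synchronized yet")
        return apply_sync(self.expression, self.offset, self.direction)


def preprocess_cells(
    counts: pd.DataFrame,
    min_umis: int = 750,
    min_gene_frac: float = 0.0005,
) -> pd.DataFrame:
    """Filter and normalize a cells x genes count matrix.

    Keeps cells with at least ``min_umis`` total UMIs and genes expressed in
    at least ``min_gene_frac`` of the retained cells, scales every cell to
    the average library size and returns ``log2(v + 1)``.
    """
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    lib = values.sum(axis=1)
    cells_ok = lib >= min_umis
    if not cells_ok.any():
        raise ValueError("no cells pass the UMI filter")
    kept = counts.loc[cells_ok]
    frac = (kept.to_numpy() > 0).mean(axis=0)
    genes_ok = frac >= min_gene_frac
    if not genes_ok.any():
        raise ValueError("no genes pass the expression filter")
    kept = kept.loc[:, genes_ok]
    lib = kept.sum(axis=1).to_numpy(dtype=float)
    scaled = kept.to_numpy(dtype=float) / lib[:, None] * lib.mean()
    return pd.DataFrame(np.log2(scaled + 1.0), index=kept.index, columns=kept.columns)


def segment_embedding(
    xy: pd.DataFrame,
    bandwidth: float = 0.15,
    grid: int = 800,
    min_cells: int = 100,
    threshold_quantile: float | None = None,
) -> pd.Series:
    """Cluster cells by segmenting a 2D embedding density into territories.

    A binned Gaussian kernel density estimate (``bandwidth`` in embedding
    units, ``grid`` x ``grid`` bins) is thresholded and its super-threshold
    region split into 4-connected components; components holding fewer than
    ``min_cells`` cells are dropped (label -1 = unassigned).

    The density cutoff is the given quantile of positive density values; when
    ``threshold_quantile`` is None a deterministic scan picks the quantile
    that maximizes the number of >= min_cells components (ties -> lowest
    quantile, i.e. most cells kept).
    """
    pts = xy.to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("embedding coordinates must be finite")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate embedding: all coordinates identical")
    lo = pts.min(axis=0) - 3 * bandwidth
    hi = pts.max(axis=0) + 3 * bandwidth
    edges = [np.linspace(lo[d], hi[d], grid + 1) for d in range(2)]
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=edges)
    cell_size = [(hi[d] - lo[d]) / grid for d in range(2)]
    sigma = [bandwidth / cell_size[d] for d in range(2)]
    density = ndimage.gaussian_filter(hist, sigma=sigma)

    ix = np.clip(np.searchsorted(edges[0], pts[:, 0], side="right") - 1, 0, grid - 1)
    iy = np.clip(np.searchsorted(edges[1], pts[:, 1], side="right") - 1, 0, grid - 1)
    positive = density[density > 0]
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity

    def labels_at(q: float) -> tuple[pd.Series, int]:
        level = np.quantile(positive, q)
        mask = density > level
        comp, _ = ndimage.label(mask, structure=structure)
        lab = comp[ix, iy]
        out = np.full(len(pts), -1, dtype=int)
        n_big = 0
        for c in np.unique(lab):
            if c == 0:
                continue
            members = lab == c
            if members.sum() >= min_cells:
                n_big += 1
                out[members] = n_big
        return pd.Series(out, index=xy.index, name="cluster"), n_big

    if threshold_quantile is not None:
        return labels_at(threshold_quantile)[0]
    best = None
    for q in np.round(np.arange(0.05, 1.0, 0.05), 2):
        lab, n_big = labels_at(q)
        if best is None or n_big > best[1]:
            best = (lab, n_big)
    return best[0]


@dataclass
class RingResult:
    """PCA of one cluster plus its ring diagnostics."""

    pcs: pd.DataFrame  # all cells x n_pcs (outliers projected too)
    retained: pd.Series  # bool per cell: used to fit the PCA
    radius_cv: float
    angular_coverage_deg: float
    is_ring: bool


def cluster_ring(
    counts: pd.DataFrame,
    n_pcs: int = 10,
    outlier_fold: float = 1.5,
    n_hvg: int = 2000,
    cv_cut: float = 0.4,
    coverage_cut: float = 300.0,
) -> RingResult:
    """Within-cluster PCA with outlier-aware fitting and a circularity score.

    Cells are renormalized within the cluster; cells whose detected-gene
    count deviates more than ``outlier_fold``-fold from the median are
    excluded from the PCA fit but still projected.  The cluster is flagged as
    a ring when the PC1/PC2 radius distribution has a coefficient of
    variation below ``cv_cut`` and the angular coverage exceeds
    ``coverage_cut`` degrees.  The flag is advisory.
    """
    if len(counts) < 100:
        raise ValueError("at least 100 cells required")
    values = counts.to_numpy(dtype=float)
    lib = values.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("cell with zero library")
    norm = np.log2(values / lib[:, None] * lib.mean() + 1.0)
    detected = (values > 0).sum(axis=1)
    med = np.median(detected)
    retained = (detected <= outlier_fold * med) & (detected >= med / outlier_fold)
    if retained.sum() < n_pcs + 1:
        raise ValueError("too few cells left after outlier removal")
    var = norm[retained].var(axis=0)
    hvg = np.argsort(var)[::-1][: min(n_hvg, norm.shape[1])]
    sub = norm[:, hvg]
    pca = PCA(n_components=min(n_pcs, len(hvg)), random_state=0)
    pca.fit(sub[retained])
    pcs = pca.transform(sub)
    pcs_df = pd.DataFrame(
        pcs, index=counts.index, columns=[f"PC{i+1}" for i in range(pcs.shape[1])]
    )
    xy = pcs[:, :2]
    cx = (np.quantile(xy[:, 0], 0.05) + np.quantile(xy[:, 0], 0.95)) / 2
    cy = (np.quantile(xy[:, 1], 0.05) + np.quantile(xy[:, 1], 0.95)) / 2
    r = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
    radius_cv = float(r.std() / r.mean()) if r.mean() > 0 else np.inf
    ang = np.mod(np.rad2deg(np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx)), 360.0)
    occupied = np.unique((ang // 10).astype(int))
    coverage = float(occupied.size * 10.0)
    return RingResult(
        pcs=pcs_df,
        retained=pd.Series(retained, index=counts.index, name="retained"),
        radius_cv=radius_cv,
        angular_coverage_deg=coverage,
        is_ring=(radius_cv < cv_cut) and (coverage > coverage_cut),
    )


def ring_angles(pcs: pd.DataFrame) -> pd.Series:
    """Angular pseudo-time of each cell around the ring centre.

    The centre is the mean of the 5% and 95% quantiles per axis (robust to
    uneven occupancy); angles are atan2 results mapped to [0, 360).
    """
    x = pcs.iloc[:, 0].to_numpy(dtype=float)
    y = pcs.iloc[:, 1].to_numpy(dtype=float)
    cx = (np.quantile(x, 0.05) + np.quantile(x, 0.95)) / 2
    cy = (np.quantile(y, 0.05) + np.quantile(y, 0.95)) / 2
    ang = np.mod(np.rad2deg(np.arctan2(y - cy, x - cx)), 360.0)
    return pd.Series(ang, index=pcs.index, name="angle")


def smooth_profile(
    angles: pd.Series,
    expr: pd.DataFrame,
    spar: float = 0.9,
    lam: float | None = None,
) -> PseudotimeProfile:
    """Per-gene smoothing-spline profile on the 36-point angle grid.

    The (angle, expression) data is duplicated at angle-360 and angle+360 so
    the cubic smoothing spline is continuous across the 0/360 boundary, then
    resampled at 0..350° in 10° steps.

    The smoothing level follows an R-style ``spar`` in [0, 1] mapped to the
    roughness penalty as ``lam = n * 6.7e-11 * 256**(3*spar - 1)`` on the
    unit-scaled angle axis; the constant is chosen so spar = 0.9 corresponds
    to an equivalent-kernel bandwidth of roughly 10° while small spar
    approaches interpolation.  Pass ``lam`` to override the mapping.
    """
    if len(angles) < 50:
        raise ValueError("at least 50 cells required")
    a = np.asarray(angles, dtype=float)
    values = expr.loc[angles.index].to_numpy(dtype=float)
    x3 = np.concatenate([a - 360.0, a, a + 360.0])
    y3 = np.vstack([values, values, values])
    order = np.argsort(x3, kind="stable")
    x3, y3 = x3[order], y3[order]
    # collapse duplicate angles (splines need strictly increasing x)
    ux, inv = np.unique(x3, return_inverse=True)
    if ux.size < x3.size:
        sums = np.zeros((ux.size, y3.shape[1]))
        counts = np.zeros(ux.size)
        np.add.at(sums, inv, y3)
        np.add.at(counts, inv, 1.0)
        y3 = sums / counts[:, None]
        x3 = ux
    span = x3[-1] - x3[0]
    xs = (x3 - x3[0]) / span
    if lam is None:
        lam = x3.size * _SPAR_BASE * 256.0 ** (3.0 * spar - 1.0)
    grid_s = (GRID_DEG - x3[0]) / span
    out = np.empty((values.shape[1], N_GRID))
    for j in range(values.shape[1]):
        col = y3[:, j]
        if np.allclose(col, col[0]):
            out[j] = col[0]
            continue
        spline = make_smoothing_spline(xs, col, lam=lam)
        out[j] = spline(grid_s)
    return PseudotimeProfile(
        expression=pd.DataFrame(out, index=expr.columns, columns=GRID_DEG)
    )


def apply_sync(expression: pd.DataFrame, offset: int, direction: int) -> pd.DataFrame:
    """Re-time a grid profile: column j of the output reads the input at grid
    index ``(direction * j + offset) mod 36``."""
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    idx = np.mod(direction * np.arange(N_GRID) + offset, N_GRID)
    out = expression.to_numpy()[:, idx]
    return pd.DataFrame(out, index=expression.index, columns=GRID_DEG)


def reference_profiles(phases: pd.Series, sd_deg: float = 45.0) -> pd.DataFrame:
    """Synthesized reference: per gene a wrapped normal bump peaking at the
    annotated phase, max-normalized to 1."""
    d = (GRID_DEG[None, :] - np.asarray(phases, float)[:, None] + 180.0) % 360.0 - 180.0
    prof = np.exp(-0.5 * (d / sd_deg) ** 2)
    return pd.DataFrame(prof, index=phases.index, columns=GRID_DEG)


def max_normalize(profiles: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Divide each gene (linear space) by its maximum level in any cell type."""
    union = None
    for df in profiles.values():
        m = df.max(axis=1)
        union = m if union is None else pd.concat([union, m], axis=1).max(axis=1)
    out = {}
    for name, df in profiles.items():
        denom = union.reindex(df.index).replace(0, np.nan)
        out[name] = df.div(denom, axis=0).fillna(0.0)
    return out


def synchronize_profile(
    profile: PseudotimeProfile,
    reference: pd.DataFrame,
) -> PseudotimeProfile:
    """Align a relative profile to the phase-annotated reference.

    All 36 starting offsets in both orientations (72 candidate versions) are
    scored by Pearson correlation on the flattened shared-gene x grid matrix;
    the argmax sets (offset, direction).  The count of local correlation
    maxima per direction is recorded as a uniqueness diagnostic.
    """
    shared = profile.expression.index.intersection(reference.index)
    if len(shared) < 10:
        raise ValueError("at least 10 genes shared with the reference required")
    prof = profile.expression.loc[shared]
    ref = reference.loc[shared].to_numpy()
    scores: dict[int, np.ndarray] = {}
    for direction in (1, -1):
        r = np.empty(N_GRID)
        for offset in range(N_GRID):
            cand = apply_sync(prof, offset, direction).to_numpy()
            r[offset] = pearson(cand, ref)
        scores[direction] = r
    best_dir = max((1, -1), key=lambda d: scores[d].max())
    best_off = int(np.argmax(scores[best_dir]))
    return PseudotimeProfile(
        expression=profile.expression,
        direction=best_dir,
        offset=best_off,
        sync_correlation=float(scores[best_dir][best_off]),
        n_local_maxima={d: _count_local_maxima(r) for d, r in scores.items()},
    )


def _count_local_maxima(r: np.ndarray) -> int:
    """Local maxima of a circular sequence (strictly above both neighbours)."""
    return int(np.sum((r > np.roll(r, 1)) & (r > np.roll(r, -1))))


def reconstitute_bulk(
    profiles: dict[str, pd.DataFrame],
    static_means: pd.DataFrame | None,
    weights: pd.Series,
) -> pd.DataFrame:
    """Weighted in-silico bulk time course.

    Oscillating tissues contribute their synchronized 36-point profiles;
    every other tissue contributes its static mean expression repeated at all
    36 timepoints; each tissue is weighted by its nuclei count.  The result
    is linear in the weights.
    """
    w = pd.Series(weights, dtype=float)
    if w.sum() == 0:
        raise ValueError("weights sum to zero")
    genes = None
    for df in profiles.values():
        genes = df.index if genes is None else genes.union(df.index)
    if static_means is not None:
        genes = static_means.index if genes is None else genes.union(static_means.index)
    bulk = pd.DataFrame(0.0, index=genes, columns=GRID_DEG)
    for tissue, df in profiles.items():
        bulk = bulk.add(df.reindex(genes).fillna(0.0) * w.get(tissue, 0.0), fill_value=0.0)
    if static_means is not None:
        for tissue in static_means.columns:
            if tissue in profiles:
                continue
            col = static_means[tissue].reindex(genes).fillna(0.0)
            bulk = bulk.add(
                pd.DataFrame(
                    np.repeat(col.to_numpy()[:, None], N_GRID, axis=1) * w.get(tissue, 0.0),
                    index=genes,
                    columns=GRID_DEG,
                ),
                fill_value=0.0,
            )
    return bulk
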