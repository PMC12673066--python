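"""Vector-path geometry of TF phase vectors on peak clusters.

Once TF activity vectors are fitted, every peak's predicted oscillation is a
vector sum of enrichment-scaled TF vectors.  This module clusters peaks by
their TF enrichment, draws per-cluster vector paths (TF contributions added
tip-to-tail), and quantifies destructive interference: the output vector's
length is bounded by the total path length (triangle inequality) and
saturates when co-bound TFs point in opposing phase directions.  An
angle-permutation null rewires which TF points where, while preserving each
peak's multiset of contribution magnitudes, to show the observed TF phase
arrangement produces more cancellation than chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .chip_features import EnrichmentMatrix
from .tf_model import XYModel, fit_xy, predict_xy

__all__ = [
    "ClusterVectorPath",
    "cluster_peaks",
    "build_paths",
    "split_fit_validate",
    "path_saturation",
    "randomize_angles",
    "plot_paths",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterVectorPath:
    """Per-cluster TF contribution vectors and their sum.

    ``contributions`` holds one row per TF: the mean-enrichment-scaled
    activity vector (vx, vy) and its length; ``order`` is the tip-to-tail
    drawing order (ascending length — presentation only, the sum is
    order-invariant).
    """

    cluster: int
    contributions: pd.DataFrame  # TF x [vx, vy, length]
    order: list[str]
    predicted_x: float
    predicted_y: float
    measured_x: float
    measured_y: float
    path_length: float
    output_length: float
    n_peaks: int


def _features(C: EnrichmentMatrix | pd.DataFrame) -> pd.DataFrame:
    return C.values if isinstance(C, EnrichmentMatrix) else C


def cluster_peaks(
    C: EnrichmentMatrix | pd.DataFrame,
    k: int = 100,
    seed: int = 0,
    n_init: int = 10,
) -> pd.Series:
    """K-means over the peaks x TFs enrichment rows.

    Cluster labels are relabelled by descending mean total enrichment, so
    cluster 1 holds the most heavily bound peaks.  Deterministic given seed.
    """
    features = _features(C)
    if k >= len(features):
        raise ValueError("k must be smaller than the number of peaks")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(features.to_numpy(dtype=float))
    totals = features.sum(axis=1).groupby(raw).mean().sort_values(ascending=False)
    relabel = {old: new + 1 for new, old in enumerate(totals.index)}
    return pd.Series([relabel[r] for r in raw], index=features.index, name="cluster")


def build_paths(
    membership: pd.Series,
    C: EnrichmentMatrix | pd.DataFrame,
    model: XYModel,
    fits: pd.DataFrame,
) -> list[ClusterVectorPath]:
    """Vector path per cluster: contribution v_f = mean enrichment_f * (x'_f, y'_f).

    The predicted output is the (intercept-free) vector sum of contributions;
    the measured output is the mean fitted (x_g, y_g) over member peaks.
    """
    features = _features(C)
    coef = model.coefficients
    paths = []
    for cl in sorted(membership.unique()):
        members = membership.index[membership == cl]
        mean_enr = features.loc[members, coef.index].mean(axis=0)
        vx = mean_enr * coef["x_coef"]
        vy = mean_enr * coef["y_coef"]
        length = np.hypot(vx, vy)
        contributions = pd.DataFrame({"vx": vx, "vy": vy, "length": length})
        order = list(length.sort_values().index)
        px, py = float(vx.sum()), float(vy.sum())
        shared = fits.index.intersection(members)
        mx = float(fits.loc[shared, "x"].mean())
        my = float(fits.loc[shared, "y"].mean())
        paths.append(
            ClusterVectorPath(
                cluster=int(cl),
                contributions=contributions,
                order=order,
                predicted_x=px,
                predicted_y=py,
                measured_x=mx,
                measured_y=my,
                path_length=float(length.sum()),
                output_length=float(np.hypot(px, py)),
                n_peaks=len(members),
            )
        )
    return paths


def split_fit_validate(
    responses: pd.DataFrame,
    C: EnrichmentMatrix | pd.DataFrame,
    train_frac: float = 0.10,
    k: int = 100,
    seed: int = 0,
) -> dict:
    """Fit on a small amplitude-stratified subset, validate on the rest.

    The training set is sampled within amplitude deciles (preserving the
    amplitude distribution); the refit model predicts the held-out peaks,
    which are clustered for cluster-level predicted-vs-measured correlations.
    Also reports the correlation between train-set and full-fit coefficients.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    features = _features(C)
    rng = np.random.default_rng(seed)
    amp = np.hypot(responses["x"], responses["y"])
    deciles = pd.qcut(amp.rank(method="first"), 10, labels=False)
    train_idx = []
    for d in range(10):
        stratum = responses.index[deciles == d]
        if len(stratum) < 2:
            logger.warning("amplitude stratum %d too small; merged upward", d)
            continue
        n_take = max(1, int(round(train_frac * len(stratum))))
        train_idx.extend(rng.choice(stratum, size=n_take, replace=False))
    train = pd.Index(train_idx)
    test = responses.index.difference(train)
    model_train = fit_xy(features.loc[train], responses.loc[train])
    model_full = fit_xy(features, responses)
    pred = predict_xy(features.loc[test], model_train)
    membership = cluster_peaks(features.loc[test], k=min(k, len(test) - 1), seed=seed)
    cl_pred = pred.groupby(membership).mean()
    cl_meas = responses.loc[test].groupby(membership).mean()
    coef_corr = float(
        np.corrcoef(
            np.concatenate(
                [
                    model_train.coefficients["x_coef"],
                    model_train.coefficients["y_coef"],
                ]
            ),
            np.concatenate(
                [model_full.coefficients["x_coef"], model_full.coefficients["y_coef"]]
            ),
        )[0, 1]
    )
    return {
        "model_train": model_train,
        "model_full": model_full,
        "train_peaks": train,
        "r_cluster_x": float(np.corrcoef(cl_pred["x"], cl_meas["x"])[0, 1]),
        "r_cluster_y": float(np.corrcoef(cl_pred["y"], cl_meas["y"])[0, 1]),
        "coef_correlation": coef_corr,
    }


def _contribution_vectors(
    C: EnrichmentMatrix | pd.DataFrame, model: XYModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak per-TF contribution magnitudes L and angles theta (radians).

    The TF vector is split into a unit direction and a length folded into
    the enrichment: contribution = C_{g,f} |v_f| * unit(theta_f)."""
    features = _features(C)[model.coefficients.index].to_numpy(dtype=float)
    vx = model.coefficients["x_coef"].to_numpy()
    vy = model.coefficients["y_coef"].to_numpy()
    lengths = np.hypot(vx, vy)
    angles = np.arctan2(vy, vx)
    L = features * lengths[None, :]
    return L, angles


def path_saturation(
    C: EnrichmentMatrix | pd.DataFrame,
    model: XYModel,
    n_quantile_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak total path length vs output vector length (intercepts excluded).

    path_length = sum_f |C_{g,f} v_f|; output_length = |sum_f C_{g,f} v_f|.
    The binned summary averages output length over path-length quantile bins;
    interference shows up as the binned curve flattening (saturating) while
    path length keeps growing.
    """
    L, angles = _contribution_vectors(C, model)
    sx = L @ np.cos(angles)
    sy = L @ np.sin(angles)
    features = _features(C)
    table = pd.DataFrame(
        {
            "path_length": L.sum(axis=1),
            "output_length": np.hypot(sx, sy),
        },
        index=features.index,
    )
    ranks = table["path_length"].rank(method="first")
    bins = pd.qcut(ranks, n_quantile_bins, labels=False) + 1
    summary = table.groupby(bins).mean()
    summary.index.name = "path_length_bin"
    return table, summary


def randomize_angles(
    C: EnrichmentMatrix | pd.DataFrame,
    model: XYModel,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Angle-permutation null for the output-length distribution.

    Each TF's activity vector is normalized to unit length with the length
    folded into that TF's enrichment column; for every peak the unit-vector
    angles are then permuted across TFs before summation, preserving the
    per-peak multiset of contribution magnitudes while rewiring which TF
    points in which phase direction.  Returns per-peak mean null output
    length and the observed value.
    """
    L, angles = _contribution_vectors(C, model)
    n_tfs = angles.size
    if np.count_nonzero(np.hypot(
        model.coefficients["x_coef"], model.coefficients["y_coef"]
    )) < 2:
        raise ValueError("need at least 2 TFs with nonzero vectors")
    rng = np.random.default_rng(seed)
    obs = np.hypot(L @ np.cos(angles), L @ np.sin(angles))
    null = np.empty((n_perm, L.shape[0]))
    for p in range(n_perm):
        perms = np.argsort(rng.random((L.shape[0], n_tfs)), axis=1)
        ca = np.cos(angles)[perms]
        sa = np.sin(angles)[perms]
        null[p] = np.abs((L * ca).sum(axis=1) + 1j * (L * sa).sum(axis=1))
    features = _features(C)
    return pd.DataFrame(
        {
            "observed": obs,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0),
            "path_length": L.sum(axis=1),
        },
        index=features.index,
    )


def plot_paths(
    paths: list[ClusterVectorPath],
    out_path: str | None = None,
    max_panels: int = 25,
):
    """Tip-to-tail vector-path panels (shortest contribution first), with the
    measured output vector overlaid; save as SVG when ``out_path`` is set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = min(len(paths), max_panels)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow))
    for ax, p in zip(np.atleast_1d(axes).ravel(), paths[:n]):
        x = y = 0.0
        for tf in p.order:
            vx, vy = p.contributions.loc[tf, ["vx", "vy"]]
            ax.annotate(
                "", xy=(x + vx, y + vy), xytext=(x, y),
                arrowprops={"arrowstyle": "->", "color": "tab:blue", "lw": 1.2},
            )
            x, y = x + vx, y + vy
        ax.annotate(
            "", xy=(p.measured_x, p.measured_y), xytext=(0, 0),
            arrowprops={"arrowstyle": "->", "color": "tab:red", "lw": 1.2},
        )
        lim = max(0.1, 1.1 * max(p.path_length, abs(p.measured_x), abs(p.measured_y)))
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)
        ax.set_title(f"cluster {p.cluster} (n={p.n_peaks})", fontsize=7)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in np.atleast_1d(axes).ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
        plt.close(fig)
    return fig
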