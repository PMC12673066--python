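"""Per-timepoint TF activity inference from two-condition time courses.

An auxin-inducible degron collapses one TF's activity within about an hour
of treatment.  With the TF enrichment matrix C fixed, accessibility at every
timepoint s and condition c is modelled independently as

    z_{g,s,c} = mu_{s,c} + sum_f C_{g,f} * a_{f,s,c}

so each OLS solve yields a snapshot of all TF activities.  Comparing the
vehicle and auxin activity trajectories isolates the depletion response;
applying the activity difference to held-out peaks predicts their
accessibility changes, and the same machinery predicts expression changes of
genes through their linked promoter peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.cluster import KMeans

from .chip_features import EnrichmentMatrix
from .rhythm_fit import circular_mean_deg
from .utils import pearson

__all__ = [
    "ActivityTrajectory",
    "normalize_to_control",
    "fit_timepoint_activities",
    "smooth_activities",
    "predict_changes",
    "select_differential",
    "cluster_differential",
    "link_rna_model",
]


@dataclass
class ActivityTrajectory:
    """Inferred TF activities per (timepoint, condition).

    ``activities[condition]`` is a TFs x samples table; ``intercepts`` holds
    the per-sample model intercepts; ``smoothed`` mirrors ``activities``
    after spline regression (None until :func:`smooth_activities`).
    """

    activities: dict[str, pd.DataFrame]
    intercepts: dict[str, pd.Series]
    smoothed: dict[str, pd.DataFrame] | None = None

    @property
    def conditions(self) -> list[str]:
        return list(self.activities)

    def difference(self, treated: str = "auxin", control: str = "vehicle") -> pd.DataFrame:
        """Activity difference (treated - control), TFs x samples."""
        return self.activities[treated] - self.activities[control]


def normalize_to_control(
    matrices: dict[str, pd.DataFrame],
    control: str = "vehicle",
) -> dict[str, pd.DataFrame]:
    """Mean-normalize each peak to the control condition's cycle mean.

    The per-peak mean over the control samples is subtracted from every
    condition identically, so treated-vs-control differences are preserved.
    """
    baseline = matrices[control].mean(axis=1)
    return {c: m.sub(baseline, axis=0) for c, m in matrices.items()}


def fit_timepoint_activities(
    Z: dict[str, pd.DataFrame],
    C: EnrichmentMatrix | pd.DataFrame,
) -> ActivityTrajectory:
    """One OLS per sample column: z_{.,s} = mu_s + C a_{.,s}.

    ``Z`` maps condition -> peaks x samples matrix, mean-normalized against
    the control cycle; ``C`` is the fixed quantitative enrichment matrix.
    """
    features = C.values if isinstance(C, EnrichmentMatrix) else C
    activities: dict[str, pd.DataFrame] = {}
    intercepts: dict[str, pd.Series] = {}
    for cond, mat in Z.items():
        rows = mat.index.intersection(features.index)
        if rows.empty:
            raise ValueError(f"no shared peaks for condition {cond!r}")
        M = features.loc[rows].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(rows)), M])
        Y = mat.loc[rows].to_numpy(dtype=float)
        if np.isnan(Y).all(axis=0).any():
            raise ValueError("sample with all-missing values")
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        activities[cond] = pd.DataFrame(
            beta[1:], index=features.columns, columns=mat.columns
        )
        intercepts[cond] = pd.Series(beta[0], index=mat.columns, name="intercept")
    return ActivityTrajectory(activities=activities, intercepts=intercepts)


def _bspline_basis(t: np.ndarray, n_components: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis with ``n_components`` functions, knots equally
    spaced over the sampled range."""
    n_inner = n_components - degree - 1
    if n_inner < 0:
        raise ValueError("n_components too small for a cubic basis")
    inner = np.linspace(t[0], t[-1], n_inner + 2)[1:-1]
    knots = np.concatenate([[t[0]] * (degree + 1), inner, [t[-1]] * (degree + 1)])
    return BSpline.design_matrix(t, knots, degree).toarray()


def smooth_activities(
    traj: ActivityTrajectory,
    n_components: int = 6,
    times: np.ndarray | None = None,
) -> ActivityTrajectory:
    """Least-squares spline regression of each activity curve.

    A six-function cubic B-spline basis over the sampled time range is fitted
    per TF per condition; raw activities are retained alongside.
    """
    smoothed: dict[str, pd.DataFrame] = {}
    for cond, act in traj.activities.items():
        n_t = act.shape[1]
        if n_t < n_components + 1:
            raise ValueError("need at least n_components + 1 timepoints")
        t = np.arange(n_t, dtype=float) if times is None else np.asarray(times, float)
        B = _bspline_basis(t, n_components)
        coefs, _, _, _ = np.linalg.lstsq(B, act.to_numpy(dtype=float).T, rcond=None)
        smoothed[cond] = pd.DataFrame(
            (B @ coefs).T, index=act.index, columns=act.columns
        )
    return ActivityTrajectory(
        activities=traj.activities, intercepts=traj.intercepts, smoothed=smoothed
    )


def predict_changes(
    C_heldout: EnrichmentMatrix | pd.DataFrame,
    traj: ActivityTrajectory,
    measured: dict[str, pd.DataFrame] | None = None,
    train_peaks: pd.Index | None = None,
    treated: str = "auxin",
    control: str = "vehicle",
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Predicted treatment-induced change per held-out peak per timepoint.

    delta_hat_{g,s} = sum_f C_{g,f} (a_{f,s,treated} - a_{f,s,control}).
    When measured matrices are given, the per-timepoint Pearson r between
    predicted and measured deltas is reported.  Held-out peaks must not
    overlap the peaks the trajectory was trained on.
    """
    features = C_heldout.values if isinstance(C_heldout, EnrichmentMatrix) else C_heldout
    if train_peaks is not None and len(features.index.intersection(train_peaks)):
        raise ValueError("held-out peaks overlap the training set")
    diff = traj.difference(treated, control)
    pred = pd.DataFrame(
        features[diff.index].to_numpy(dtype=float) @ diff.to_numpy(),
        index=features.index,
        columns=diff.columns,
    )
    r = None
    if measured is not None:
        meas = (
            measured[treated].loc[features.index]
            - measured[control].loc[features.index]
        )
        r = pd.Series(
            {
                s: pearson(pred[s].to_numpy(), meas[s].to_numpy())
                for s in pred.columns
            },
            name="pearson_r",
        )
    return pred, r


def select_differential(delta: pd.DataFrame, cut: float = 0.25) -> pd.Index:
    """Peaks whose maximum absolute log2 change exceeds the cutoff."""
    return delta.index[delta.abs().max(axis=1) > cut]


def cluster_differential(
    members: pd.Index,
    delta_pred: pd.DataFrame,
    delta_meas: pd.DataFrame,
    fits_wt: pd.DataFrame,
    C: EnrichmentMatrix | pd.DataFrame,
    traj: ActivityTrajectory,
    k: int = 20,
    seed: int = 0,
    treated: str = "auxin",
    control: str = "vehicle",
) -> dict:
    """Cluster differential peaks on measured change profiles.

    Clusters are ordered by the circular mean of their members' wild-type
    peak phases (start to end of stage); for each cluster the mean measured
    and predicted change curves are reported together with the per-TF
    contribution curves ``mean(C_f) * (a_treated - a_control)``, whose sum
    equals the mean predicted curve exactly.
    """
    if len(members) == 0:
        raise ValueError("no differential peaks to cluster")
    if k > len(members):
        raise ValueError("k exceeds the number of differential peaks")
    features = C.values if isinstance(C, EnrichmentMatrix) else C
    X = delta_meas.loc[members].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    membership = pd.Series(raw, index=members)
    phase_order = {
        cl: np.mod(
            circular_mean_deg(fits_wt.loc[membership.index[membership == cl], "phase"]),
            360.0,
        )
        for cl in range(k)
    }
    ordered = sorted(phase_order, key=phase_order.get)
    relabel = {old: new + 1 for new, old in enumerate(ordered)}
    membership = membership.map(relabel)
    diff = traj.difference(treated, control)
    clusters = {}
    for cl in range(1, k + 1):
        idx = membership.index[membership == cl]
        mean_enr = features.loc[idx, diff.index].mean(axis=0)
        contrib = diff.mul(mean_enr, axis=0)  # TF x time contribution curves
        clusters[cl] = {
            "mean_measured": delta_meas.loc[idx].mean(axis=0),
            "mean_predicted": delta_pred.loc[idx].mean(axis=0),
            "tf_contributions": contrib,
            "wt_phase": phase_order[ordered[cl - 1]],
            "n_peaks": len(idx),
        }
    return {"membership": membership, "clusters": clusters}


def link_rna_model(
    links: pd.DataFrame,
    rna_Z: dict[str, pd.DataFrame],
    C: EnrichmentMatrix | pd.DataFrame,
    gene_fits: pd.DataFrame,
    peak_fits: pd.DataFrame,
    gene_amp_cut: float = 0.5,
    peak_amp_cut: float = 0.25,
) -> tuple[ActivityTrajectory, pd.DataFrame]:
    """Timepoint activity model with gene expression as the response.

    Links are restricted to pairs where both partners oscillate (gene
    amplitude > 0.5, peak amplitude > 0.25); each gene's expression row is
    regressed on its linked peak's enrichment row.  Returns the trajectory
    and the retained links.
    """
    features = C.values if isinstance(C, EnrichmentMatrix) else C
    keep = links[
        links["gene"].map(gene_fits["amplitude"]).gt(gene_amp_cut)
        & links["peak"].map(peak_fits["amplitude"]).gt(peak_amp_cut)
        & links["peak"].isin(features.index)
    ].drop_duplicates(subset="gene")
    if keep.empty:
        raise ValueError("no links pass the amplitude filters")
    # gene-level responses paired with the linked peak's enrichment row
    C_genes = features.loc[keep["peak"]].set_axis(keep["gene"], axis=0)
    Z_genes = {
        cond: mat.loc[mat.index.intersection(keep["gene"])]
        for cond, mat in rna_Z.items()
    }
    for cond, mat in Z_genes.items():
        if mat.empty:
            raise ValueError(f"no linked genes measured in condition {cond!r}")
    traj = fit_timepoint_activities(Z_genes, C_genes)
    return traj, keep
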