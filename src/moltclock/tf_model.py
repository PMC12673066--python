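"""Additive TF phase-vector models of rhythmic regulatory elements.

A rhythmic element's cosine fit gives Cartesian phase coordinates
``(x_g, y_g)``.  Two paired linear models regress these on TF features,

    x_g = b_x + sum_f C_{g,f} * x'_f,      y_g = b_y + sum_f C_{g,f} * y'_f,

so each TF f acquires an activity vector ``(x'_f, y'_f)``: its angle is the
phase of peak TF activity, its length the amplitude contributed per unit of
enrichment.  Predictions are vector sums — co-bound TFs with anti-phase
vectors interfere destructively and predict a low-amplitude element despite
strong binding.  TFs are ranked by Fisher-combining the x and y coefficient
p-values; an interaction variant tests whether pairwise TF products add
explanatory power beyond additivity.

The modeling universe ("Osc+") is the union of oscillating peaks and
non-oscillating peaks exclusive to oscillating tissues, whose near-zero
(x, y) anchor destructive interference in the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .chip_features import EnrichmentMatrix

__all__ = [
    "OscPlusSet",
    "XYModel",
    "build_osc_plus",
    "fit_xy",
    "fit_xy_interactions",
    "rank_tfs",
    "predict_xy",
]

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny  # smallest positive normal float, p-value floor


@dataclass
class OscPlusSet:
    """Modeling universe: responses (x_g, y_g) with per-peak provenance."""

    responses: pd.DataFrame  # peaks x [x, y]
    provenance: pd.Series  # 'oscillating' | 'tissue_specific_flat'

    @property
    def peaks(self) -> pd.Index:
        return self.responses.index


@dataclass
class XYModel:
    """Paired OLS fits of the x and y phase coordinates.

    ``coefficients`` has one row per predictor with the activity-vector
    components (x_coef, y_coef) and their two-sided t-test p-values.
    """

    coefficients: pd.DataFrame  # predictor x [x_coef, y_coef, p_x, p_y]
    intercept_x: float
    intercept_y: float
    adj_r2_x: float
    adj_r2_y: float
    r2_x: float
    r2_y: float
    n_obs: int
    mode: str = "quantitative"
    dropped_predictors: list[str] | None = None

    @property
    def vector_angles(self) -> pd.Series:
        """Activity-vector angle per predictor, degrees in [0, 360)."""
        ang = np.rad2deg(
            np.arctan2(self.coefficients["y_coef"], self.coefficients["x_coef"])
        )
        return np.mod(ang, 360.0).rename("angle")

    @property
    def vector_lengths(self) -> pd.Series:
        return np.hypot(
            self.coefficients["x_coef"], self.coefficients["y_coef"]
        ).rename("length")


def build_osc_plus(
    fits: pd.DataFrame,
    tissue_flags: pd.Series | None = None,
) -> OscPlusSet:
    """Oscillating peaks plus flagged tissue-specific non-oscillating peaks.

    ``fits`` is a cosine-fit table (columns x, y, class).  A peak both
    oscillating and flagged enters once, with oscillating provenance.
    """
    osc = fits.index[fits["class"] == "oscillating"]
    extra = pd.Index([])
    if tissue_flags is not None:
        flagged = tissue_flags.index[tissue_flags.astype(bool)]
        extra = fits.index.intersection(flagged).difference(osc)
    members = osc.append(extra)
    if members.empty:
        raise ValueError("empty Osc+ set")
    prov = pd.Series("oscillating", index=members, name="provenance")
    prov.loc[extra] = "tissue_specific_flat"
    return OscPlusSet(responses=fits.loc[members, ["x", "y"]], provenance=prov)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later-indexed columns until the design (with intercept) has full
    rank; exact duplicates in occupancy matrices are the common case."""
    arr = X.to_numpy(dtype=float)
    design = np.ones((len(X), 1))
    if np.linalg.matrix_rank(np.column_stack([design, arr])) == arr.shape[1] + 1:
        return X, []
    kept: list[str] = []
    dropped: list[str] = []
    rank = 1
    for j, col in enumerate(X.columns):
        trial = np.column_stack([design, arr[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            design, rank = trial, r
            kept.append(col)
        else:
            dropped.append(col)
    logger.warning("dropped collinear predictor columns: %s", dropped)
    return X[kept], dropped


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """OLS with intercept in column 0; returns (beta, p-values, R2, adj R2)."""
    n, p_tot = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - p_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_tot) if n > p_tot else np.nan
    sigma2 = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, np.maximum(pvals, _TINY), r2, adj


def fit_xy(
    C: EnrichmentMatrix | pd.DataFrame,
    responses: pd.DataFrame,
    mode: str | None = None,
) -> XYModel:
    """Fit the paired x/y linear models on a feature matrix.

    ``C`` rows are aligned to ``responses`` (peaks x [x, y]) by index.
    Exactly collinear predictor columns are dropped (later-indexed first)
    with a logged warning.
    """
    if isinstance(C, EnrichmentMatrix):
        features = C.values
        mode = mode or C.mode
    else:
        features = C
        mode = mode or "quantitative"
    features = features.loc[responses.index]
    n, p = features.shape
    if n <= p + 1:
        raise ValueError("need more peaks than predictors")
    features, dropped = _drop_collinear(features)
    X = np.column_stack([np.ones(n), features.to_numpy(dtype=float)])
    bx, px, r2x, adjx = _ols(X, responses["x"].to_numpy(dtype=float))
    by, py, r2y, adjy = _ols(X, responses["y"].to_numpy(dtype=float))
    coef = pd.DataFrame(
        {
            "x_coef": bx[1:],
            "y_coef": by[1:],
            "p_x": px[1:],
            "p_y": py[1:],
        },
        index=features.columns,
    )
    return XYModel(
        coefficients=coef,
        intercept_x=float(bx[0]),
        intercept_y=float(by[0]),
        adj_r2_x=adjx,
        adj_r2_y=adjy,
        r2_x=r2x,
        r2_y=r2y,
        n_obs=n,
        mode=mode,
        dropped_predictors=dropped or None,
    )


def fit_xy_interactions(
    C: EnrichmentMatrix | pd.DataFrame,
    responses: pd.DataFrame,
) -> tuple[XYModel, dict[str, float]]:
    """Main-effects + all pairwise product terms.

    Returns the interaction model and the change in adjusted R-squared
    relative to the main-effects-only model.
    """
    features = C.values if isinstance(C, EnrichmentMatrix) else C
    features = features.loc[responses.index]
    main = fit_xy(features, responses)
    ext = features.copy()
    for a, b in combinations(features.columns, 2):
        ext[f"{a}*{b}"] = features[a] * features[b]
    inter = fit_xy(ext, responses, mode="interactions")
    delta = {
        "delta_adj_r2_x": inter.adj_r2_x - main.adj_r2_x,
        "delta_adj_r2_y": inter.adj_r2_y - main.adj_r2_y,
    }
    return inter, delta


def rank_tfs(model: XYModel, log10p_cut: float = -10.0) -> pd.DataFrame:
    """Rank predictors by Fisher-combined significance of (x', y').

    X = -2 (ln p_x + ln p_y) is chi-square with 4 degrees of freedom under
    the null; predictors are sorted by combined P ascending, with a flag at
    the conventional log10(P) < -10 threshold.
    """
    p_x = model.coefficients["p_x"].to_numpy()
    p_y = model.coefficients["p_y"].to_numpy()
    X = -2.0 * (np.log(np.maximum(p_x, _TINY)) + np.log(np.maximum(p_y, _TINY)))
    combined = np.maximum(stats.chi2.sf(X, df=4), _TINY)
    out = model.coefficients.copy()
    out["fisher_stat"] = X
    out["combined_p"] = combined
    out["log10_p"] = np.log10(combined)
    out["significant"] = out["log10_p"] < log10p_cut
    return out.sort_values("combined_p")


def predict_xy(
    C_new: EnrichmentMatrix | pd.DataFrame,
    model: XYModel,
) -> pd.DataFrame:
    """Predicted (x, y, amplitude, phase) per peak by activity-vector summation.

    Exact additivity: a peak's prediction is the sum of its single-TF
    contributions plus the intercepts.
    """
    features = C_new.values if isinstance(C_new, EnrichmentMatrix) else C_new
    wanted = list(model.coefficients.index)
    missing = set(wanted) - set(features.columns)
    if missing:
        raise ValueError(f"predictor columns missing: {sorted(missing)}")
    M = features[wanted].to_numpy(dtype=float)
    xhat = model.intercept_x + M @ model.coefficients["x_coef"].to_numpy()
    yhat = model.intercept_y + M @ model.coefficients["y_coef"].to_numpy()
    return pd.DataFrame(
        {
            "x": xhat,
            "y": yhat,
            "amplitude": np.hypot(xhat, yhat),
            "phase": np.mod(np.rad2deg(np.arctan2(yhat, xhat)), 360.0),
        },
        index=features.index,
    )
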