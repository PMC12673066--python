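import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moltclock import tf_model as tm


def _fits(xy, classes):
    return pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "class": classes,
        },
        index=[f"p{i}" for i in range(len(xy))],
    )


class TestBuildOscPlus:
    def test_oscillating_only_without_flags(self):
        fits = _fits(np.array([[0.5, 0.0], [0.0, 0.0]]), ["oscillating", "flat"])
        osc = tm.build_osc_plus(fits)
        assert list(osc.peaks) == ["p0"]

    def test_flagged_flat_peaks_added(self):
        fits = _fits(
            np.array([[0.5, 0.0], [0.01, 0.0], [0.0, 0.0]]),
            ["oscillating", "flat", "flat"],
        )
        flags = pd.Series({"p1": True, "p2": False})
        osc = tm.build_osc_plus(fits, flags)
        assert sorted(osc.peaks) == ["p0", "p1"]
        assert osc.provenance["p1"] == "tissue_specific_flat"

    def test_dedup_keeps_oscillating_provenance(self):
        fits = _fits(np.array([[0.5, 0.0]]), ["oscillating"])
        osc = tm.build_osc_plus(fits, pd.Series({"p0": True}))
        assert len(osc.peaks) == 1
        assert osc.provenance["p0"] == "oscillating"

    def test_empty_set_rejected(self):
        fits = _fits(np.array([[0.0, 0.0]]), ["flat"])
        with pytest.raises(ValueError):
            tm.build_osc_plus(fits)

    def test_synthetic_bookkeeping(self, truth9):
        fits = pd.DataFrame(
            {
                "x": truth9.peak_xy["x"],
                "y": truth9.peak_xy["y"],
                "class": truth9.peak_class,
            }
        )
        flags = pd.Series(True, index=truth9.tissue_specific_flat)
        osc = tm.build_osc_plus(fits, flags)
        n_osc = int((truth9.peak_class == "oscillating").sum())
        assert len(osc.peaks) == n_osc + len(truth9.tissue_specific_flat)


class TestFitXY:
    def test_single_binary_tf_exact(self):
        rng = np.random.default_rng(0)
        col = (rng.random(50) < 0.5).astype(float)
        C = pd.DataFrame({"tfA": col}, index=[f"p{i}" for i in range(50)])
        resp = pd.DataFrame({"x": col, "y": np.zeros(50)}, index=C.index)
        model = tm.fit_xy(C, resp)
        assert model.coefficients.loc["tfA", "x_coef"] == pytest.approx(1.0)
        assert model.coefficients.loc["tfA", "y_coef"] == pytest.approx(0.0, abs=1e-12)
        assert model.r2_x == pytest.approx(1.0)

    def test_noiseless_additive_recovery_machine_precision(self, truth9):
        C = truth9.peak_enrichment
        resp = truth9.peak_xy
        model = tm.fit_xy(C, resp)
        np.testing.assert_allclose(
            model.coefficients["x_coef"], truth9.tf_vectors["x"], atol=1e-10
        )
        np.testing.assert_allclose(
            model.coefficients["y_coef"], truth9.tf_vectors["y"], atol=1e-10
        )
        assert model.r2_x == pytest.approx(1.0)
        assert model.adj_r2_x <= model.r2_x

    def test_permuted_responses_zero_adj_r2(self, truth9):
        rng = np.random.default_rng(1)
        C = truth9.peak_enrichment
        resp = truth9.peak_xy.copy()
        vals = []
        for _ in range(20):
            perm = rng.permutation(len(resp))
            shuffled = pd.DataFrame(
                resp.to_numpy()[perm], index=resp.index, columns=resp.columns
            )
            m = tm.fit_xy(C, shuffled)
            vals.append(m.adj_r2_x)
        assert np.abs(np.mean(vals)) < 0.02

    def test_collinear_duplicate_column_dropped(self):
        rng = np.random.default_rng(2)
        a = rng.random(100)
        C = pd.DataFrame({"tfA": a, "tfB": a}, index=[f"p{i}" for i in range(100)])
        resp = pd.DataFrame({"x": a * 0.5, "y": a * 0.2}, index=C.index)
        model = tm.fit_xy(C, resp)
        assert model.dropped_predictors == ["tfB"]
        assert list(model.coefficients.index) == ["tfA"]

    def test_too_few_observations_rejected(self):
        C = pd.DataFrame(np.eye(3), index=list("abc"), columns=["t1", "t2", "t3"])
        resp = pd.DataFrame({"x": [1.0, 2, 3], "y": [0.0, 0, 0]}, index=list("abc"))
        with pytest.raises(ValueError):
            tm.fit_xy(C, resp)

    def test_inference_matches_statsmodels(self):
        # independent oracle for coefficients, p-values and adjusted R^2
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        C = pd.DataFrame(
            rng.lognormal(0, 0.4, (200, 4)),
            columns=[f"tf{i}" for i in range(4)],
            index=[f"p{i}" for i in range(200)],
        )
        resp = pd.DataFrame(
            {
                "x": C @ [0.3, 0.0, -0.1, 0.05] + rng.normal(0, 0.2, 200),
                "y": rng.normal(0, 0.2, 200),
            },
            index=C.index,
        )
        model = tm.fit_xy(C, resp)
        ref = sm.OLS(resp["x"], sm.add_constant(C)).fit()
        np.testing.assert_allclose(
            model.coefficients["x_coef"], ref.params.iloc[1:], atol=1e-10
        )
        np.testing.assert_allclose(
            model.coefficients["p_x"], ref.pvalues.iloc[1:], rtol=1e-8
        )
        assert model.adj_r2_x == pytest.approx(ref.rsquared_adj, abs=1e-12)
        assert model.intercept_x == pytest.approx(ref.params.iloc[0])

    def test_coefficient_invariance_under_column_rescale(self, truth9):
        C = truth9.peak_enrichment
        resp = truth9.peak_xy
        m1 = tm.fit_xy(C, resp)
        C2 = C.copy()
        C2.iloc[:, 0] = C2.iloc[:, 0] * 4.0
        m2 = tm.fit_xy(C2, resp)
        assert m2.coefficients["x_coef"].iloc[0] == pytest.approx(
            m1.coefficients["x_coef"].iloc[0] / 4.0
        )
        p1 = tm.predict_xy(C, m1)
        p2 = tm.predict_xy(C2, m2)
        np.testing.assert_allclose(
            p1[["x", "y"]].to_numpy(), p2[["x", "y"]].to_numpy(), atol=1e-9
        )


class TestRankTfs:
    def _model_with_p(self, p_pairs):
        coef = pd.DataFrame(
            {
                "x_coef": np.ones(len(p_pairs)),
                "y_coef": np.ones(len(p_pairs)),
                "p_x": [p[0] for p in p_pairs],
                "p_y": [p[1] for p in p_pairs],
            },
            index=[f"tf{i}" for i in range(len(p_pairs))],
        )
        return tm.XYModel(
            coefficients=coef,
            intercept_x=0.0,
            intercept_y=0.0,
            adj_r2_x=0.5,
            adj_r2_y=0.5,
            r2_x=0.5,
            r2_y=0.5,
            n_obs=100,
        )

    def test_unit_pvalues_give_combined_one(self):
        ranked = tm.rank_tfs(self._model_with_p([(1.0, 1.0)]))
        assert ranked["fisher_stat"].iloc[0] == pytest.approx(0.0)
        assert ranked["combined_p"].iloc[0] == pytest.approx(1.0)

    def test_fisher_closed_form(self):
        # X = -2(ln .05 + ln .05) = 11.98..., chi2(4) upper tail = 0.00175
        ranked = tm.rank_tfs(self._model_with_p([(0.05, 0.05)]))
        X = -2 * (np.log(0.05) + np.log(0.05))
        assert ranked["fisher_stat"].iloc[0] == pytest.approx(X)
        assert ranked["combined_p"].iloc[0] == pytest.approx(
            stats.chi2.sf(X, 4), rel=1e-12
        )

    def test_zero_pvalue_floored(self):
        ranked = tm.rank_tfs(self._model_with_p([(0.0, 0.0)]))
        assert np.isfinite(ranked["log10_p"].iloc[0])

    def test_sorted_by_significance_with_threshold_flag(self):
        ranked = tm.rank_tfs(self._model_with_p([(0.5, 0.5), (1e-12, 1e-12)]))
        assert list(ranked.index) == ["tf1", "tf0"]
        assert bool(ranked["significant"].iloc[0])
        assert not bool(ranked["significant"].iloc[1])

    def test_one_active_tf_ranked_first(self):
        # simulation study: a single truly active TF among nulls wins the
        # ranking in at least 95 of 100 replicates
        rng = np.random.default_rng(3)
        n, n_tfs = 2000, 21
        wins = 0
        for rep in range(100):
            C = rng.lognormal(0, 0.4, (n, n_tfs)) * (rng.random((n, n_tfs)) < 0.3)
            Cdf = pd.DataFrame(
                C, columns=[f"tf{i}" for i in range(n_tfs)],
                index=[f"p{i}" for i in range(n)],
            )
            resp = pd.DataFrame(
                {
                    "x": 0.25 * C[:, 0] + rng.normal(0, 0.1, n),
                    "y": 0.25 * C[:, 0] + rng.normal(0, 0.1, n),
                },
                index=Cdf.index,
            )
            ranked = tm.rank_tfs(tm.fit_xy(Cdf, resp))
            wins += ranked.index[0] == "tf0"
        assert wins >= 95

    def test_type_i_control_on_pure_noise(self):
        # no TF may pass the log10(P) < -10 threshold on noise responses
        rng = np.random.default_rng(4)
        n, n_tfs = 2000, 20
        n_pass = 0
        for rep in range(100):
            C = rng.lognormal(0, 0.4, (n, n_tfs)) * (rng.random((n, n_tfs)) < 0.3)
            Cdf = pd.DataFrame(
                C, columns=[f"tf{i}" for i in range(n_tfs)],
                index=[f"p{i}" for i in range(n)],
            )
            resp = pd.DataFrame(
                {"x": rng.normal(0, 0.3, n), "y": rng.normal(0, 0.3, n)},
                index=Cdf.index,
            )
            ranked = tm.rank_tfs(tm.fit_xy(Cdf, resp))
            n_pass += int(ranked["significant"].sum())
        assert n_pass == 0


class TestInteractions:
    def test_nine_tfs_give_45_predictors(self):
        # dense enrichment so every pairwise product is informative
        rng = np.random.default_rng(8)
        C = pd.DataFrame(
            rng.lognormal(0, 0.3, (300, 9)),
            columns=[f"tf{i}" for i in range(9)],
            index=[f"p{i}" for i in range(300)],
        )
        resp = pd.DataFrame(
            {"x": rng.normal(0, 1, 300), "y": rng.normal(0, 1, 300)}, index=C.index
        )
        model, delta = tm.fit_xy_interactions(C, resp)
        assert len(model.coefficients) == 45  # 9 + C(9,2)

    def test_additive_data_gains_nothing(self, truth9):
        rng = np.random.default_rng(5)
        C = truth9.peak_enrichment
        resp = truth9.peak_xy + rng.normal(0, 0.1, truth9.peak_xy.shape)
        _, delta = tm.fit_xy_interactions(C, resp)
        assert abs(delta["delta_adj_r2_x"]) < 0.01
        assert abs(delta["delta_adj_r2_y"]) < 0.01

    def test_product_term_detected(self):
        rng = np.random.default_rng(6)
        n = 2000
        cols = {f"tf{i}": rng.lognormal(0, 0.3, n) * (rng.random(n) < 0.5) for i in range(4)}
        C = pd.DataFrame(cols, index=[f"p{i}" for i in range(n)])
        inter = C["tf0"] * C["tf1"]
        resp = pd.DataFrame(
            {
                "x": 0.5 * inter + rng.normal(0, 0.05, n),
                "y": rng.normal(0, 0.05, n),
            },
            index=C.index,
        )
        model, delta = tm.fit_xy_interactions(C, resp)
        assert model.coefficients["p_x"].idxmin() == "tf0*tf1"
        assert delta["delta_adj_r2_x"] > 0.1


class TestPredictXY:
    def test_zero_row_predicts_intercepts(self, truth9):
        model = tm.fit_xy(truth9.peak_enrichment, truth9.peak_xy)
        zero = pd.DataFrame(
            np.zeros((1, truth9.peak_enrichment.shape[1])),
            columns=truth9.peak_enrichment.columns,
            index=["z"],
        )
        pred = tm.predict_xy(zero, model)
        assert pred.loc["z", "x"] == pytest.approx(model.intercept_x)
        assert pred.loc["z", "y"] == pytest.approx(model.intercept_y)

    def test_antiphase_destructive_interference_exact_zero(self):
        coef = pd.DataFrame(
            {
                "x_coef": [0.4, -0.4],
                "y_coef": [0.0, 0.0],
                "p_x": [0.01, 0.01],
                "p_y": [0.5, 0.5],
            },
            index=["tfA", "tfB"],
        )
        model = tm.XYModel(
            coefficients=coef,
            intercept_x=0.0,
            intercept_y=0.0,
            adj_r2_x=1.0,
            adj_r2_y=1.0,
            r2_x=1.0,
            r2_y=1.0,
            n_obs=10,
        )
        C = pd.DataFrame({"tfA": [1.0], "tfB": [1.0]}, index=["pk"])
        pred = tm.predict_xy(C, model)
        assert pred.loc["pk", "amplitude"] == 0.0

    def test_additivity_identity(self, truth9):
        # prediction of a multi-TF peak = sum of single-TF predictions
        # minus (k-1) intercepts
        model = tm.fit_xy(truth9.peak_enrichment, truth9.peak_xy)
        row = truth9.peak_enrichment.iloc[[0]]
        k = row.shape[1]
        singles = []
        for j, tf in enumerate(row.columns):
            single = row.copy()
            single.iloc[0, [i for i in range(k) if i != j]] = 0.0
            singles.append(tm.predict_xy(single, model).iloc[0])
        combined = tm.predict_xy(row, model).iloc[0]
        sum_x = sum(s["x"] for s in singles) - (k - 1) * model.intercept_x
        assert combined["x"] == pytest.approx(sum_x, abs=1e-10)

    def test_column_mismatch_rejected(self, truth9):
        model = tm.fit_xy(truth9.peak_enrichment, truth9.peak_xy)
        bad = truth9.peak_enrichment.iloc[:, :3]
        with pytest.raises(ValueError):
            tm.predict_xy(bad, model)

    def test_heldout_prediction_accuracy(self, world9, truth9):
        from moltclock.rhythm_fit import fit_cosine
        from moltclock.synthetic_data import graded_covariate

        fits = fit_cosine(
            world9.atac, world9.timing, trend=graded_covariate(world9.timing)
        )
        rng = np.random.default_rng(7)
        peaks = truth9.peaks
        train = pd.Index(rng.choice(peaks, size=len(peaks) // 10, replace=False))
        test = peaks.difference(train)
        model = tm.fit_xy(
            truth9.peak_enrichment.loc[train], fits.loc[train, ["x", "y"]]
        )
        pred = tm.predict_xy(truth9.peak_enrichment.loc[test], model)
        truth_xy = truth9.peak_xy.loc[test]
        assert np.corrcoef(pred["x"], truth_xy["x"])[0, 1] > 0.9
        assert np.corrcoef(pred["y"], truth_xy["y"])[0, 1] > 0.9
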