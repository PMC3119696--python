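import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from transgroup import stats as st
from transgroup.contours import BoundingBox
from transgroup.simulate import SimulationConfig, simulate_experiment
from transgroup.trials import censor_trials


class TestNormalizeMedians:
    def test_hand_computed_example(self):
        values = np.array([190.0, 200, 210, 290, 300, 310])
        subjects = np.array(["A", "A", "A", "B", "B", "B"])
        out = st.normalize_medians(values, subjects)
        assert np.allclose(out, [240, 250, 260, 240, 250, 260])

    def test_single_subject_unchanged(self):
        values = np.array([1.0, 5.0, 9.0])
        assert np.allclose(st.normalize_medians(values, np.zeros(3)), values)

    def test_subject_medians_equal_overall_median(self, sim_trials):
        out = st.normalize_medians(sim_trials["rt_ms"], sim_trials["subject_id"])
        overall = np.median(sim_trials["rt_ms"])
        for s in sim_trials["subject_id"].unique():
            assert np.median(out[sim_trials["subject_id"] == s]) == pytest.approx(overall)

    def test_within_subject_differences_preserved(self):
        rng = np.random.default_rng(0)
        values = rng.normal(600, 50, 60)
        subjects = np.repeat([0, 1, 2], 20)
        out = st.normalize_medians(values, subjects)
        for s in (0, 1, 2):
            d_in = np.diff(values[subjects == s])
            d_out = np.diff(out[subjects == s])
            assert np.allclose(d_in, d_out)


class TestSurvivalHazard:
    def test_hand_computed_example(self):
        table = st.survival_hazard([10.0, 20.0, 30.0, 40.0], bin_ms=10.0)
        assert np.allclose(table.survival["all"], [0.75, 0.5, 0.25, 0.0])
        assert np.allclose(table.hazard["all"], [0.25, 1 / 3, 0.5, 1.0])

    def test_single_value(self):
        table = st.survival_hazard([25.0], bin_ms=10.0)
        assert np.allclose(table.survival["all"], [1.0, 1.0, 0.0])
        assert np.allclose(table.hazard["all"], [0.0, 0.0, 1.0])

    def test_smoothing_leaves_constant_hazard_unchanged(self):
        assert np.allclose(st.moving_average(np.full(20, 0.3), 5), 0.3)

    def test_edge_windows_shrink_symmetrically(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        sm = st.moving_average(x, 5)
        assert sm[0] == 1.0  # window of one at the edge
        assert sm[1] == pytest.approx(2.0)  # three-bin window
        assert sm[2] == pytest.approx(3.0)  # full five-bin window

    def test_survival_reconstructs_from_hazard(self, sim_trials):
        table = st.survival_hazard(
            sim_trials["saccade_latency_ms"], 5.0, conditions=sim_trials["condition"]
        )
        for cond, hazard in table.hazard.items():
            recon = np.cumprod(1.0 - hazard)
            assert np.max(np.abs(recon - table.survival[cond])) < 1e-12

    def test_survival_is_one_minus_cumulative_proportion(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(1, 400, 500)
        table = st.survival_hazard(values, 15.0)
        edges = table.bin_edges[1:]
        cum = np.array([(values <= e).mean() for e in edges])
        assert np.allclose(table.survival["all"], 1.0 - cum)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            st.survival_hazard([], 5.0)


class TestAdjustRtForLanding:
    def trials_frame(self, dist, rt, subject=None):
        n = len(dist)
        return pd.DataFrame(
            {
                "subject_id": np.zeros(n, dtype=int) if subject is None else subject,
                "condition": ["uniform"] * n,
                "landing_x_deg": dist,
                "landing_y_deg": np.zeros(n),
                "rt_ms": rt,
            }
        )

    def test_zero_slope_data_unchanged(self):
        rng = np.random.default_rng(1)
        dist = rng.uniform(0, 1, 500)
        rt = np.full(500, 600.0) + np.tile([0.0, 1.0], 250)  # variance, no trend
        df, slope = st.adjust_rt_for_landing(self.trials_frame(dist, rt))
        assert abs(slope) < 5e-3
        assert np.allclose(df["log_rt_adj"], df["log_rt"], atol=5e-3)

    def test_exact_log_linear_construction(self):
        dist = np.linspace(0.0, 1.0, 100)
        rt = np.exp(np.log(500.0) + 0.1 * dist)
        df, slope = st.adjust_rt_for_landing(self.trials_frame(dist, rt))
        assert slope == pytest.approx(0.1, abs=1e-10)
        assert np.allclose(df["log_rt_adj"], np.log(500.0), atol=1e-10)

    def test_adjusted_rt_uncorrelated_with_distance_on_simulated_data(self):
        cfg = SimulationConfig.null(n_subjects=2, trials_per_condition=1000)
        raw = simulate_experiment(cfg, seed=21)
        kept, _ = censor_trials(raw)
        df, _ = st.adjust_rt_for_landing(kept)
        dist = np.hypot(df["landing_x_deg"], df["landing_y_deg"])
        assert abs(sps.pearsonr(df["log_rt_adj"], dist).statistic) < 0.03

    def test_zero_distance_variance_raises(self):
        df = self.trials_frame(np.full(10, 0.5), np.full(10, 600.0))
        with pytest.raises(ValueError):
            st.adjust_rt_for_landing(df)


def cells_frame(cells, conditions=st.CONDITIONS):
    """Expand a subjects x conditions cell-mean array to a trial frame."""
    rows = []
    for i, row in enumerate(cells):
        for c, v in zip(conditions, row):
            rows.append({"subject_id": i, "condition": c, "log_rt_adj": v})
    return pd.DataFrame(rows)


class TestConditionContrasts:
    def test_identical_conditions_give_zero_contrasts(self):
        # integer-valued cells keep the mean arithmetic exact
        cells = np.tile(np.arange(7.0)[:, None], (1, 5))
        table = st.condition_contrasts(cells_frame(cells))
        assert table.omnibus_F == 0.0
        for c in table.contrasts:
            assert c.estimate_log == pytest.approx(0.0, abs=1e-12)
            assert c.F == pytest.approx(0.0, abs=1e-12)

    def test_error_degrees_of_freedom_with_seven_subjects(self):
        rng = np.random.default_rng(2)
        cells = 6.4 + 0.05 * rng.standard_normal((7, 5))
        table = st.condition_contrasts(cells_frame(cells))
        assert table.omnibus_df == (4, 24)
        assert all(c.df == (1, 24) for c in table.contrasts)

    def test_missing_cell_raises_with_names(self):
        df = cells_frame(np.zeros((3, 5)))
        df = df[~((df["subject_id"] == 1) & (df["condition"] == "same"))]
        with pytest.raises(ValueError, match="same"):
            st.condition_contrasts(df)

    def test_omnibus_matches_anova_oracle_on_cell_means(self):
        # two-way (subject x condition) ANOVA identity on cell means
        rng = np.random.default_rng(3)
        cells = 6.4 + 0.05 * rng.standard_normal((6, 5))
        table = st.condition_contrasts(cells_frame(cells))
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = cells_frame(cells)
        fit = ols("log_rt_adj ~ C(condition) + C(subject_id)", data=df).fit()
        an = sm.stats.anova_lm(fit, typ=2)
        F_oracle = an.loc["C(condition)", "F"]
        assert table.omnibus_F == pytest.approx(F_oracle, rel=1e-10)

    def test_recovers_configured_same_different_gap(self):
        cfg = SimulationConfig(n_subjects=7, trials_per_condition=150)
        raw = simulate_experiment(cfg, seed=30)
        kept, _ = censor_trials(raw)
        kept = kept[kept["correct"] & (kept["rt_ms"] <= 1500)]
        adj, _ = st.adjust_rt_for_landing(kept)
        table = st.condition_contrasts(adj)
        gap = next(c for c in table.contrasts if c.name == "same_vs_different")
        lo, hi = gap.ci95_ms
        assert lo <= -35.0 <= hi


class TestAvov:
    def test_identical_groups_give_zero_F(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 0.3, (50, 2))
        landings = np.vstack([pts, pts])
        groups = np.array(["a"] * 50 + ["b"] * 50)
        res = st.avov_spread(landings, groups)
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.3, (1000, 2))
        b = a * 2.0  # scaled about its mean: variance ratio 4
        landings = np.vstack([a, b])
        groups = np.array(["a"] * 1000 + ["b"] * 1000)
        res = st.avov_spread(landings, groups, contrast=(("b",), ("a",)))
        assert res.contrast_F > 0
        assert res.group_mean_sqdev["b"] > res.group_mean_sqdev["a"]
        assert res.contrast_p < 0.01

    def test_matches_one_way_anova_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.3, (40, 2))
        b = rng.normal(0.2, 0.5, (60, 2))
        landings = np.vstack([a, b])
        groups = np.array(["a"] * 40 + ["b"] * 60)
        res = st.avov_spread(landings, groups)
        sq_a = ((a - a.mean(axis=0)) ** 2).sum(axis=1)
        sq_b = ((b - b.mean(axis=0)) ** 2).sum(axis=1)
        oracle = sps.f_oneway(sq_a, sq_b)
        assert res.F == pytest.approx(oracle.statistic, rel=1e-10)
        assert res.p == pytest.approx(oracle.pvalue, rel=1e-8)

    def test_singleton_group_raises(self):
        with pytest.raises(ValueError):
            st.avov_spread(np.zeros((3, 2)), np.array(["a", "a", "b"]))


class TestAccuracyLogistic:
    def test_no_effect_gives_small_coefficients(self):
        cfg = SimulationConfig.null(n_subjects=4, trials_per_condition=300)
        df = simulate_experiment(cfg, seed=40)
        table = st.accuracy_logistic(df)
        for _, row in table.iterrows():
            assert abs(row["beta"]) < 3 * row["se"]

    def test_matches_direct_likelihood_fit(self):
        cfg = SimulationConfig(n_subjects=2, trials_per_condition=20)
        # pull accuracy off the ceiling so the 200-trial MLE is finite
        cfg.accuracy_logit = {**cfg.accuracy_logit, "intercept": 1.0, "same": 0.8}
        df = simulate_experiment(cfg, seed=41)
        table = st.accuracy_logistic(df)

        conds = [c for c in st.CONDITIONS if c != "uniform"]
        X = np.column_stack(
            [np.ones(len(df))]
            + [(df["condition"] == c).to_numpy(float) for c in conds]
            + [(df["subject_id"] == 1).to_numpy(float)]
        )
        y = df["correct"].to_numpy(float)

        # independent maximum-likelihood fit: plain Newton-Raphson
        beta = np.zeros(X.shape[1])
        for _ in range(50):
            mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
            grad = X.T @ (y - mu)
            hess = (X * (mu * (1 - mu))[:, None]).T @ X
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-12:
                break
        for j, c in enumerate(conds):
            ours = float(table.loc[table["condition"] == c, "beta"].iloc[0])
            assert ours == pytest.approx(beta[1 + j], abs=1e-6)

    def test_complete_separation_raises(self, sim_trials):
        df = sim_trials.head(200).copy()
        df["correct"] = True
        with pytest.raises(ValueError):
            st.accuracy_logistic(df)


class TestLandingIsofrequency:
    def test_single_occupied_bin(self):
        landings = np.tile([[0.1, 0.1]], (20, 1))
        region = st.landing_isofrequency(landings)
        assert region.mask.sum() == 1
        assert region.enclosed_mass == 1.0

    def test_defining_mass_property(self):
        rng = np.random.default_rng(8)
        landings = rng.normal(0, 0.4, (2000, 2))
        region = st.landing_isofrequency(landings)
        assert region.enclosed_mass >= 0.90
        counts, _, _ = np.histogram2d(
            landings[:, 0], landings[:, 1], bins=(region.x_edges, region.y_edges)
        )
        smallest_selected = counts[region.mask].min()
        assert (region.enclosed_mass * len(landings) - smallest_selected) / len(landings) < 0.90

    def test_isotropic_normal_region_area_near_analytic(self):
        rng = np.random.default_rng(9)
        sigma = 0.3
        landings = rng.normal(0, sigma, (10_000, 2))
        region = st.landing_isofrequency(landings)
        r90 = sigma * np.sqrt(2 * np.log(10.0))  # Rayleigh 90% quantile
        assert region.area == pytest.approx(np.pi * r90**2, rel=0.10)

    def test_median_marker(self):
        rng = np.random.default_rng(10)
        landings = rng.normal([0.3, -0.2], 0.2, (500, 2))
        region = st.landing_isofrequency(landings)
        assert region.median_point[0] == pytest.approx(0.3, abs=0.05)
        assert region.median_point[1] == pytest.approx(-0.2, abs=0.05)

    def test_invalid_mass_raises(self):
        with pytest.raises(ValueError):
            st.landing_isofrequency(np.zeros((20, 2)), mass=1.5)


class TestCoarseShape:
    def frame(self, ori_diffs, rng, slope=0.0, noise=0.0, n_per=8):
        rows = []
        boxes = {}
        for sid, od in enumerate(ori_diffs):
            boxes[sid] = (
                BoundingBox(2.0, 1.0, 0.0, 2.0),
                BoundingBox(2.0, 1.0, od % 180.0, 2.0),
            )
            for subj in range(4):
                for _ in range(n_per):
                    rows.append(
                        {
                            "subject_id": subj,
                            "condition": "different",
                            "stimulus_id": sid,
                            "postsac_stimulus": 2,
                            "log_rt_adj": 6.4 + slope * od + noise * rng.standard_normal(),
                        }
                    )
        for subj in range(4):
            for _ in range(20):
                rows.append(
                    {
                        "subject_id": subj,
                        "condition": "localized",
                        "stimulus_id": 0,
                        "postsac_stimulus": 2,
                        "log_rt_adj": 6.4,
                    }
                )
        return pd.DataFrame(rows), boxes

    def test_identical_shapes_zero_orientation_difference(self):
        rng = np.random.default_rng(11)
        df, boxes = self.frame([0.0, 0.0, 0.0], rng, noise=0.01)
        res = st.coarse_shape_analysis(df, boxes)
        assert res.n_elongated == res.n_different
        assert res.r_orientation is None  # no orientation variance to correlate

    def test_circles_are_not_elongated(self):
        df, _ = self.frame([10.0], np.random.default_rng(12), noise=0.01)
        boxes = {0: (BoundingBox(1.0, 1.0, 0.0, 1.0), BoundingBox(1.0, 1.0, 10.0, 1.0))}
        res = st.coarse_shape_analysis(df, boxes)
        assert res.n_elongated == 0

    def test_linear_construction_recovers_positive_correlation(self):
        rng = np.random.default_rng(13)
        df, boxes = self.frame(np.linspace(0, 80, 9), rng, slope=0.002, noise=0.02)
        res = st.coarse_shape_analysis(df, boxes)
        assert res.r_orientation > 0.5
        assert res.p_orientation < 0.05

    def test_cost_reduction_when_large_differences_excluded(self):
        rng = np.random.default_rng(14)
        df, boxes = self.frame(np.linspace(0, 80, 9), rng, slope=0.002, noise=0.02)
        res = st.coarse_shape_analysis(df, boxes)
        assert res.cost_full_ms > res.cost_excluding_ms
        assert 0.0 < res.cost_reduction <= 1.0
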