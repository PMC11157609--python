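"""Feature expansion, L1 solver correctness (KKT + brute force),
logistic output, projection and clamping."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

import nichecast as nc
from nichecast.maxent import FeatureExpansion, compute_betas, fit_features


def brute_force_1d(F_pres, F_bg, beta, grid):
    """Dense 1-D grid search over the penalized objective (oracle)."""
    p_bar = F_pres.mean(axis=0)
    best, best_obj = None, -np.inf
    for lam in grid:
        obj = p_bar[0] * lam - logsumexp(F_bg[:, 0] * lam) - beta * abs(lam)
        if obj > best_obj:
            best, best_obj = lam, obj
    return best


class TestFeatureExpansion:
    def _exp(self, fc, n_vars=6, **kw):
        rng = np.random.default_rng(0)
        bg = rng.uniform(0, 10, size=(50, n_vars))
        return FeatureExpansion.from_background(
            bg, [f"v{i}" for i in range(n_vars)], fc, **kw), bg

    def test_linear_count(self):
        exp, _ = self._exp("l")
        assert exp.n_features == 6

    def test_linear_product_count(self):
        # 6 linear + C(6,2) products = 21
        exp, _ = self._exp("lp")
        assert exp.n_features == 6 + 15

    def test_threshold_hinge_counts(self):
        exp, _ = self._exp("th", n_vars=2, n_thresholds=5, n_hinges=4)
        # 2 vars * 5 thresholds + 2 vars * (4 forward + 4 reverse) hinges
        assert exp.n_features == 10 + 16

    def test_scaling_endpoints(self):
        exp, bg = self._exp("l")
        F = exp.transform(bg)
        assert F.min() == pytest.approx(0.0)
        assert F.max() == pytest.approx(1.0)
        at_min = exp.transform(exp.mins[None, :])
        at_max = exp.transform(exp.maxs[None, :])
        assert np.allclose(at_min, 0.0) and np.allclose(at_max, 1.0)

    def test_features_bounded_on_training(self):
        exp, bg = self._exp("lqpth", n_vars=3, n_thresholds=4, n_hinges=4)
        F = exp.transform(bg)
        assert F.min() >= 0.0 and F.max() <= 1.0 + 1e-12

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown feature class"):
            self._exp("lxz")

    def test_serialization_roundtrip(self):
        exp, bg = self._exp("lqh", n_hinges=5)
        back = FeatureExpansion.from_dict(exp.to_dict())
        assert np.array_equal(back.transform(bg), exp.transform(bg))


class TestFitMaxent:
    def test_huge_rm_drives_all_coefficients_to_zero(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(50, 2))
        pres = rng.normal(size=(10, 2))
        m = nc.fit_maxent(pres, bg, ["a", "b"], rm=1e6, fc="lq")
        assert m.k == 0
        # uniform raw output: 1/n_background per background row
        assert np.allclose(m.raw_at(bg, clamp=False), 1.0 / 50)

    def test_matches_1d_brute_force(self):
        # single linear feature over a 20-cell background
        rng = np.random.default_rng(2)
        bg = rng.uniform(0, 1, size=(20, 1))
        pres = rng.uniform(0.5, 1, size=(8, 1))
        m = nc.fit_maxent(pres, bg, ["x"], rm=1.0, fc="l")
        grid = np.arange(-20, 20, 0.0005)
        F_bg = m.expansion.transform(bg)
        F_pres = m.expansion.transform(pres)
        oracle = brute_force_1d(F_pres, F_bg, m.betas[0], grid)
        assert m.lambdas[0] == pytest.approx(oracle, abs=1e-3)

    def test_matches_2d_brute_force(self):
        # two linear features, <=30-cell background: exhaustive grid search
        rng = np.random.default_rng(3)
        bg = rng.uniform(0, 1, size=(25, 2))
        pres = bg[rng.choice(25, size=10, p=np.exp(2 * bg[:, 0]) / np.exp(2 * bg[:, 0]).sum())]
        m = nc.fit_maxent(pres, bg, ["x", "y"], rm=1.0, fc="l")
        F_bg = m.expansion.transform(bg)
        p_bar = m.expansion.transform(pres).mean(axis=0)
        grid1 = np.arange(-8, 8, 0.01)
        grid2 = grid1[::4]
        best, best_obj = None, -np.inf
        for l1 in grid1:
            lse = logsumexp(F_bg[:, [0]] * l1 + F_bg[:, [1]] * grid2[None, :], axis=0)
            objs = (p_bar[0] * l1 + p_bar[1] * grid2 - lse
                    - m.betas[0] * abs(l1) - m.betas[1] * np.abs(grid2))
            j = int(np.argmax(objs))
            if objs[j] > best_obj:
                best, best_obj = (l1, grid2[j]), objs[j]
        assert np.allclose(m.lambdas, best, atol=2e-2)
        # the solver's objective must match or beat the grid optimum
        solver_obj = (p_bar @ m.lambdas - logsumexp(F_bg @ m.lambdas)
                      - m.betas @ np.abs(m.lambdas))
        assert solver_obj >= best_obj - 1e-6

    def test_no_signal_gives_near_zero_gain(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(500, 3))
        pres = bg[rng.choice(500, size=100, replace=False)]
        m = nc.fit_maxent(pres, bg, ["a", "b", "c"], rm=1.0, fc="l")
        assert m.regularized_gain == pytest.approx(0.0, abs=0.05)
        assert np.all(np.abs(m.lambdas) < 1.0)

    def test_kkt_contract(self, demo_fit):
        m = demo_fit["model"]
        assert m.converged
        assert m.kkt_violation() < 1e-4

    def test_kkt_across_feature_classes(self, demo_fit):
        bg, pres = demo_fit["background"], demo_fit["presences"]
        names = [f"v{i}" for i in range(bg.shape[1])]
        for fc in ("l", "lq", "lqp", "lqpt", "lqpth"):
            m = nc.fit_maxent(pres, bg, names, rm=1.0, fc=fc,
                              n_hinges=6, n_thresholds=6)
            if m.converged:
                assert m.kkt_violation() < 1e-4, fc

    def test_raw_sums_to_one_over_background(self, demo_fit):
        m, bg = demo_fit["model"], demo_fit["background"]
        assert m.raw_at(bg, clamp=False).sum() == pytest.approx(1.0, abs=1e-9)

    def test_gain_non_increasing_in_rm(self, demo_fit):
        bg, pres = demo_fit["background"], demo_fit["presences"]
        names = [f"v{i}" for i in range(bg.shape[1])]
        gains = [
            nc.fit_maxent(pres, bg, names, rm=rm, fc="lq").regularized_gain
            for rm in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(gains, gains[1:]))

    def test_input_validation(self):
        bg = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError):
            nc.fit_maxent(bg[:1], bg, ["a", "b"])       # too few presences
        with pytest.raises(ValueError):
            nc.fit_maxent(bg[:5], bg[:5], ["a", "b"])   # too few background
        with pytest.raises(ValueError):
            nc.fit_maxent(bg[:5], bg, ["a", "b"], rm=0.0)

    def test_model_json_roundtrip(self, demo_fit):
        m = demo_fit["model"]
        back = nc.MaxEntModel.from_json(m.to_json())
        X = demo_fit["background"][:50]
        assert np.allclose(back.logistic_at(X), m.logistic_at(X))
        assert back.k == m.k


class TestLogisticOutput:
    def test_uniform_model_scores_half_everywhere(self):
        # uniform q on n cells: H = ln n, raw = 1/n, p = 0.5
        rng = np.random.default_rng(5)
        bg = rng.normal(size=(64, 2))
        pres = rng.normal(size=(10, 2))
        m = nc.fit_maxent(pres, bg, ["a", "b"], rm=1e9, fc="l")
        assert m.entropy == pytest.approx(np.log(64), abs=1e-9)
        assert np.allclose(m.logistic_at(bg, clamp=False), 0.5)

    def test_fixed_point_of_transform(self, demo_fit):
        m = demo_fit["model"]
        raw = np.exp(-m.entropy)
        assert nc.logistic_output(m, raw) == pytest.approx(0.5)

    def test_monotone_in_raw_density(self, demo_fit):
        m = demo_fit["model"]
        raw = np.sort(np.random.default_rng(6).uniform(1e-9, 1e-2, 50))
        p = nc.logistic_output(m, raw)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))


class TestProject:
    def test_self_projection_is_deterministic_and_consistent(self, demo, demo_fit):
        m = demo_fit["model"]
        raster = nc.project(m, demo["stack"])
        again = nc.project(m, demo["stack"])
        valid = raster.valid_mask
        assert np.array_equal(raster.values[valid], again.values[valid])  # bit-for-bit
        brow, bcol = demo_fit["bg_cells"]
        direct = m.logistic_at(demo_fit["background"])
        np.testing.assert_allclose(raster.values[brow, bcol], direct, rtol=1e-10)

    def test_clamping_pins_features_at_training_max(self, demo, demo_fit):
        m = demo_fit["model"]
        hot = nc.generate_future_stack(demo["stack"], 100.0, 0.0, 0.0)
        # +10 degC everywhere: clamped features equal the training maximum
        X_hot = np.full((1, len(m.expansion.variables)), np.inf)
        X_max = m.expansion.maxs[None, :]
        assert np.allclose(
            m.expansion.transform(X_hot, clamp=True),
            m.expansion.transform(X_max, clamp=False),
        )
        raster = nc.project(m, hot, clamp=True)
        assert np.isfinite(raster.valid_values()).all()

    def test_clamp_only_changes_out_of_range_cells(self, demo, demo_fit):
        m = demo_fit["model"]
        future = nc.generate_future_stack(demo["stack"], 10.0, 0.2, 0.03)
        on = nc.project(m, future, clamp=True)
        off = nc.project(m, future, clamp=False)
        rows, cols = future.valid_indices()
        X = future.env_at_cells(rows, cols, m.expansion.variables)
        out_of_range = ((X < m.expansion.mins) | (X > m.expansion.maxs)).any(axis=1)
        differ = on.values[rows, cols] != off.values[rows, cols]
        assert not differ[~out_of_range].any()
        assert differ.sum() <= out_of_range.sum()

    def test_missing_variable_named(self, demo_fit):
        m = demo_fit["model"]
        stack = nc.generate_climate_stack(seed=0, n_rows=10, n_cols=10,
                                          layer_spec=[("bio01", 0, 1)])
        with pytest.raises(KeyError, match="bio"):
            nc.project(m, stack)


def test_true_niche_recovery(demo, demo_fit):
    """Rank correlation between true and predicted suitability >= 0.9 on
    the packaged synthetic world."""
    raster = nc.project(demo_fit["model"], demo["stack"])
    truth = demo["niche"].true_suitability(demo["stack"])
    valid = demo["stack"].valid_mask
    rho = spearmanr(truth[valid], raster.values[valid]).statistic
    assert rho >= 0.9
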