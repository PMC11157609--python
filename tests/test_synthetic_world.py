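"""Generator contracts: field correlation structure, scenario shifts,
presence sampling, determinism."""

import numpy as np
import pytest

import nichecast as nc
from nichecast.synthetic import LayerSpec


def empirical_corr(stack, a, b):
    """Independent oracle: direct Pearson correlation over valid cells."""
    va = stack.layers[a][stack.valid_mask]
    vb = stack.layers[b][stack.valid_mask]
    return np.corrcoef(va, vb)[0, 1]


class TestGenerateClimateStack:
    def test_zero_sd_layers_are_constant(self):
        stack = nc.generate_climate_stack(
            seed=0, n_rows=10, n_cols=10,
            layer_spec=[("a", 5.0, 0.0), ("b", -3.0, 0.0)],
        )
        assert np.all(stack.layers["a"] == 5.0)
        assert np.all(stack.layers["b"] == -3.0)

    def test_perfect_correlation_limit(self):
        target = np.array([[1.0, 1.0], [1.0, 1.0]])
        stack = nc.generate_climate_stack(
            seed=3, n_rows=100, n_cols=100,
            layer_spec=[("a", 0.0, 1.0), ("b", 0.0, 1.0)],
            target_correlation=target,
        )
        assert abs(empirical_corr(stack, "a", "b")) > 0.99

    def test_targeted_correlations_recovered(self):
        # 3 layers, r(1,2)=0.9, r(1,3)=0 on a 200x200 grid
        target = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        stack = nc.generate_climate_stack(
            seed=42, n_rows=200, n_cols=200,
            layer_spec=[("a", 0, 1), ("b", 0, 1), ("c", 0, 1)],
            target_correlation=target, smoothing_length=3.0,
        )
        assert empirical_corr(stack, "a", "b") == pytest.approx(0.9, abs=0.05)
        assert empirical_corr(stack, "a", "c") == pytest.approx(0.0, abs=0.05)

    def test_correlation_converges_with_grid_size(self):
        # valid-cell correlation within a shrinking tolerance at two sizes;
        # a masked sea border makes the valid subset a proper subsample, and
        # its sampling error scales like smoothing_length / grid_size
        target = np.array([[1.0, 0.7], [0.7, 1.0]])
        for n, tol in ((48, 0.12), (192, 0.04)):
            stack = nc.generate_climate_stack(
                seed=5, n_rows=n, n_cols=n,
                layer_spec=[("a", 0, 1), ("b", 0, 1)],
                target_correlation=target, smoothing_length=2.0,
                sea_border_fraction=0.1,
            )
            assert abs(empirical_corr(stack, "a", "b") - 0.7) < tol

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            nc.generate_climate_stack(seed=0, n_rows=10, n_cols=10,
                                      layer_spec=[("a", 0, 1), ("b", 0, 1), ("c", 0, 1)],
                                      target_correlation=bad)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            nc.generate_climate_stack(seed=0, n_rows=4, n_cols=4,
                                      layer_spec=[("a", 0, 1)])

    def test_sea_border_masked(self):
        stack = nc.generate_climate_stack(
            seed=0, n_rows=20, n_cols=20, layer_spec=[("a", 0, 1)],
            sea_border_fraction=0.1,
        )
        assert stack.nodata_mask[0, :].all() and stack.nodata_mask[:, -1].all()
        assert not stack.nodata_mask[10, 10]

    def test_same_seed_bit_identical(self):
        kw = dict(n_rows=30, n_cols=30,
                  layer_spec=[("a", 10, 2), ("b", 0, 1)],
                  sea_border_fraction=0.1)
        s1 = nc.generate_climate_stack(seed=9, **kw)
        s2 = nc.generate_climate_stack(seed=9, **kw)
        for name in s1.layers:
            assert np.array_equal(s1.layers[name], s2.layers[name])
        assert np.array_equal(s1.nodata_mask, s2.nodata_mask)


class TestGenerateFutureStack:
    def test_identity_scenario(self, small_stack):
        fut = nc.generate_future_stack(small_stack, 0.0, 0.0, 0.0)
        for name in small_stack.layers:
            assert np.array_equal(fut.layers[name], small_stack.layers[name])

    def test_precipitation_increase_is_multiplicative(self, small_stack):
        # a 5.2% precipitation increase scales every precipitation cell
        fut = nc.generate_future_stack(small_stack, 0.0, 0.0, 0.052)
        np.testing.assert_allclose(
            fut.layers["prec_ann"], 1.052 * small_stack.layers["prec_ann"], rtol=1e-12
        )
        assert np.array_equal(fut.layers["t_mean"], small_stack.layers["t_mean"])

    def test_warming_shift_closed_form(self, small_stack):
        # shift at |lat| = warming + gradient * |lat|, checked cell-by-cell
        fut = nc.generate_future_stack(small_stack, 2.0, 0.05, 0.0)
        lat = np.abs(small_stack.grid.lat_centers())
        expected = small_stack.layers["t_mean"] + (2.0 + 0.05 * lat)[:, None]
        np.testing.assert_allclose(fut.layers["t_mean"], expected, rtol=1e-12)

    def test_geometry_and_mask_preserved(self):
        stack = nc.generate_climate_stack(seed=1, n_rows=20, n_cols=20,
                                          layer_spec=[("t", 0, 1)],
                                          sea_border_fraction=0.1)
        fut = nc.generate_future_stack(stack, 1.0, 0.1, 0.0)
        assert fut.grid == stack.grid
        assert np.array_equal(fut.nodata_mask, stack.nodata_mask)

    def test_negative_precip_fraction_rejected(self, small_stack):
        with pytest.raises(ValueError):
            nc.generate_future_stack(small_stack, 0.0, 0.0, -1.0)


class TestSampleOccurrences:
    def test_point_mass_niche(self):
        stack = nc.generate_climate_stack(seed=0, n_rows=10, n_cols=10,
                                          layer_spec=[("a", 0.0, 0.0)])
        stack.layers["a"][3, 4] = 100.0  # only this cell is suitable
        niche = nc.NicheFunction(["a"], linear=[1.0], quadratic=[0.0],
                                 intercept=-50.0)
        occ = nc.sample_occurrences(stack, niche, n=50, seed=1)
        row, col = stack.grid.cell_index(occ.lon, occ.lat)
        assert np.all(row == 3) and np.all(col == 4)

    def test_multinomial_frequencies(self):
        # 4 valid cells with suitabilities (0.8, 0.2, 0, 0): selection
        # frequencies must match the multinomial law
        stack = nc.generate_climate_stack(seed=0, n_rows=8, n_cols=8,
                                          layer_spec=[("a", 0.0, 0.0)])
        stack.nodata_mask[:] = True
        stack.nodata_mask[0, :4] = False
        suits = np.array([0.8, 0.2, 0.0, 0.0])
        stack.layers["a"][0, :4] = np.log(np.maximum(suits, 1e-300))

        class RawNiche(nc.NicheFunction):
            def suitability(self, env):
                return np.exp(env[:, 0])

        niche = RawNiche(["a"], [0.0], [0.0], 0.0)
        occ = nc.sample_occurrences(stack, niche, n=5000, seed=7, jitter=False)
        _, col = stack.grid.cell_index(occ.lon, occ.lat)
        freqs = np.array([(col == j).mean() for j in range(4)])
        assert np.all(np.abs(freqs - np.array([0.8, 0.2, 0.0, 0.0])) <= 0.02)

    def test_uniform_niche_uniform_cells(self):
        from scipy.stats import chisquare
        stack = nc.generate_climate_stack(seed=0, n_rows=8, n_cols=8,
                                          layer_spec=[("a", 0.0, 0.0)])
        niche = nc.NicheFunction(["a"], [0.0], [0.0], 50.0)  # suitability 1
        occ = nc.sample_occurrences(stack, niche, n=10000, seed=3, jitter=False)
        row, col = stack.grid.cell_index(occ.lon, occ.lat)
        counts = np.bincount(row * 8 + col, minlength=64)
        assert chisquare(counts).pvalue > 0.001

    def test_all_zero_suitability_rejected(self, small_stack):
        niche = nc.NicheFunction(["t_mean"], [0.0], [0.0], -1e6)
        # expit underflows to exactly 0 at -1e6
        with pytest.raises(ValueError, match="zero"):
            nc.sample_occurrences(small_stack, niche, n=5, seed=0)

    def test_deterministic_given_seed(self, small_stack):
        niche = nc.NicheFunction(["t_mean"], [0.01], [0.0], 0.0)
        a = nc.sample_occurrences(small_stack, niche, n=100, seed=11)
        b = nc.sample_occurrences(small_stack, niche, n=100, seed=11)
        assert a.records.equals(b.records)

    def test_points_fall_inside_their_cells(self, small_stack):
        niche = nc.NicheFunction(["t_mean"], [0.01], [0.0], 0.0)
        occ = nc.sample_occurrences(small_stack, niche, n=500, seed=2)
        row, col = small_stack.grid.cell_index(occ.lon, occ.lat)
        assert np.all(row >= 0)
        assert not small_stack.nodata_mask[row, col].any()


def test_niche_function_bounded():
    niche = nc.NicheFunction.from_optima(["x"], [10.0], [5.0], [3.0], intercept=4.0)
    env = np.array([[-1e6], [10.0], [1e6]])
    s = niche.suitability(env)
    assert np.all((s >= 0) & (s <= 1))
    assert s[1] == pytest.approx(1 / (1 + np.exp(-4.0)))
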