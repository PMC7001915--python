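import numpy as np
import pytest
from scipy.signal import periodogram

from richworld import (
    FeatureDefinition,
    InvalidInputError,
    RasterLayer,
    RasterTimeSeries,
    SyntheticWorldConfig,
    build_feature_table,
    make_grid,
    morlet_power,
    rescale_unit,
    seasonal_intensity,
    simulate_driver_fields,
    summarize_series,
    truncate_quantiles,
)


@pytest.fixture(scope="module")
def tiny_grid():
    return make_grid((-20, 20, -20, 20), cell_km=400.0)


def _series(grid, per_cell_fn, months=120, name="s"):
    t = np.arange(months, dtype=float)
    vals = np.empty((months,) + grid.shape)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            vals[:, r, c] = per_cell_fn(t, r, c)
    return RasterTimeSeries(grid, vals, name)


class TestSummaries:
    def test_constant_series_summaries(self, tiny_grid):
        s = _series(tiny_grid, lambda t, r, c: np.full_like(t, 4.0))
        assert np.allclose(summarize_series(s, "mean").values, 4.0)
        assert np.allclose(summarize_series(s, "sd").values, 0.0)
        assert np.allclose(summarize_series(s, "range").values, 0.0)

    def test_annual_sinusoid_intra_range_near_twice_amplitude(self, tiny_grid):
        a = 1.7
        s = _series(tiny_grid, lambda t, r, c: a * np.cos(2 * np.pi * t / 12 + 0.3 * r))
        rng_layer = summarize_series(s, "range", "intra-annual")
        # monthly sampling sees between 2a*cos(pi/12) and 2a depending on phase
        assert np.all(rng_layer.values <= 2 * a + 1e-9)
        assert np.all(rng_layer.values >= 2 * a * np.cos(np.pi / 12) - 1e-9)

    def test_identical_years_have_zero_interannual_sd(self, tiny_grid):
        year = np.arange(12, dtype=float)
        s = _series(tiny_grid, lambda t, r, c: np.tile(year + r, t.size // 12)[: t.size])
        assert np.allclose(summarize_series(s, "sd", "inter-annual").values, 0.0)

    def test_intra_annual_stats_ignore_year_order(self, tiny_grid):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(120,) + tiny_grid.shape)
        s1 = RasterTimeSeries(tiny_grid, base, "s")
        perm = rng.permutation(10)
        shuffled = base.reshape(10, 12, *tiny_grid.shape)[perm].reshape(base.shape)
        s2 = RasterTimeSeries(tiny_grid, shuffled, "s")
        for stat in ("mean", "sd", "range", "cv"):
            assert np.allclose(
                summarize_series(s1, stat).values, summarize_series(s2, stat).values
            )

    def test_non_multiple_of_twelve_rejected(self, tiny_grid):
        s = RasterTimeSeries(tiny_grid, np.zeros((100,) + tiny_grid.shape), "s")
        with pytest.raises(InvalidInputError):
            summarize_series(s, "mean")


class TestTruncateRescale:
    def test_truncation_to_percentile_oracle(self, tiny_grid):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, tiny_grid.shape)
        layer = RasterLayer(tiny_grid, vals, "x")
        out = truncate_quantiles(layer, 0.01, 0.99)
        qlo, qhi = np.quantile(vals, [0.01, 0.99])
        assert out.values.min() == pytest.approx(qlo)
        assert out.values.max() == pytest.approx(qhi)

    def test_identity_quantiles_are_noop(self, tiny_grid):
        vals = np.random.default_rng(2).normal(size=tiny_grid.shape)
        layer = RasterLayer(tiny_grid, vals, "x")
        assert np.allclose(truncate_quantiles(layer, 0.0, 1.0).values, vals)

    def test_output_within_quantile_interval(self, tiny_grid):
        vals = np.random.default_rng(3).standard_cauchy(tiny_grid.shape)
        out = truncate_quantiles(RasterLayer(tiny_grid, vals, "x"))
        qlo, qhi = np.quantile(vals, [0.01, 0.99])
        assert out.values.min() >= qlo - 1e-12
        assert out.values.max() <= qhi + 1e-12

    def test_rescale_affine_and_roundtrip(self, tiny_grid):
        vals = np.resize([2.0, 4.0, 6.0], tiny_grid.shape)
        layer = RasterLayer(tiny_grid, vals, "x")
        scaled, (lo, hi) = rescale_unit(layer)
        assert (lo, hi) == (2.0, 6.0)
        assert np.allclose(np.unique(scaled.values), [0.0, 0.5, 1.0])
        assert np.allclose(scaled.values * (hi - lo) + lo, vals)

    def test_constant_layer_rescale_rejected(self, tiny_grid):
        layer = RasterLayer(tiny_grid, np.full(tiny_grid.shape, 3.0), "x")
        with pytest.raises(InvalidInputError):
            rescale_unit(layer)


class TestMorletPower:
    T = np.arange(180.0)

    def test_constant_series_has_negligible_power(self):
        ref = morlet_power(np.cos(2 * np.pi * self.T / 12), (12.0,))[12.0]
        flat = morlet_power(np.full(180, 7.0), (6.0, 12.0))
        assert flat[6.0] < 1e-6 * ref
        assert flat[12.0] < 1e-6 * ref

    def test_annual_tone_dominates_semiannual_band(self):
        p = morlet_power(np.cos(2 * np.pi * self.T / 12), (6.0, 12.0))
        assert p[12.0] >= 10 * p[6.0]
        p = morlet_power(np.cos(2 * np.pi * self.T / 6), (6.0, 12.0))
        assert p[6.0] >= 10 * p[12.0]

    def test_two_tone_band_powers_balanced_and_dominant(self):
        x = np.cos(2 * np.pi * self.T / 12) + np.cos(2 * np.pi * self.T / 6)
        p = morlet_power(x, (4.0, 6.0, 9.0, 12.0, 18.0))
        on = [p[6.0], p[12.0]]
        off = [p[4.0], p[9.0], p[18.0]]
        assert max(on) <= 2.0 * min(on)
        assert min(on) >= 5.0 * max(off)

    def test_dominant_period_ordering_matches_fft_oracle(self):
        rng = np.random.default_rng(4)
        t = np.arange(240.0)
        periods = [6.0, 12.0]
        for _ in range(5):
            a6, a12 = rng.uniform(0.5, 2.0, 2)
            while abs(np.log(a6 / a12)) < 0.3:  # keep a clear dominant tone
                a6, a12 = rng.uniform(0.5, 2.0, 2)
            x = a6 * np.cos(2 * np.pi * t / 6) + a12 * np.cos(2 * np.pi * t / 12)
            x += rng.normal(0, 0.05, t.size)
            p = morlet_power(x, periods)
            freqs, pxx = periodogram(x - x.mean())
            fft_power = {pp: pxx[np.argmin(np.abs(freqs - 1 / pp))] for pp in periods}
            assert (p[6.0] > p[12.0]) == (fft_power[6.0] > fft_power[12.0])

    def test_short_series_rejected_or_flagged(self):
        with pytest.raises(InvalidInputError):
            morlet_power(np.zeros(24), (12.0,))
        with pytest.warns(UserWarning):
            _, flags = morlet_power(
                np.cos(2 * np.pi * np.arange(48.0) / 12), (18.0,), return_flags=True
            )
        assert flags[18.0]


class TestSeasonalIntensity:
    @pytest.fixture(scope="class")
    def worlds(self):
        grid12 = make_grid((-20, 20, -20, 20), cell_km=500.0)
        cfg12 = SyntheticWorldConfig(
            seed=3, seasonal_amplitudes={"temperature": (1.0, 0.0)}, series_noise_sd=0.0
        )
        d12 = simulate_driver_fields(grid12, cfg12)
        grid6 = make_grid((-20, 20, -20, 20), cell_km=500.0)
        cfg6 = SyntheticWorldConfig(
            seed=3, seasonal_amplitudes={"temperature": (0.0, 1.0)}, series_noise_sd=0.0
        )
        d6 = simulate_driver_fields(grid6, cfg6)
        return d12.monthly_series["temperature"], d6.monthly_series["temperature"]

    def test_annual_world_dominates_12month_band_everywhere(self, worlds):
        s12, _ = worlds
        i12 = seasonal_intensity(s12, 12.0).values
        i6 = seasonal_intensity(s12, 6.0).values
        assert np.all(i12 > i6)

    def test_swapped_amplitudes_reverse_dominance(self, worlds):
        _, s6 = worlds
        assert np.all(seasonal_intensity(s6, 6.0).values > seasonal_intensity(s6, 12.0).values)

    def test_offset_invariance(self, worlds):
        s12, _ = worlds
        shifted = RasterTimeSeries(s12.grid, s12.values + 42.0, "t")
        assert np.allclose(
            seasonal_intensity(s12, 12.0).values, seasonal_intensity(shifted, 12.0).values
        )

    def test_power_scales_with_amplitude_squared(self, worlds):
        s12, _ = worlds
        doubled = RasterTimeSeries(s12.grid, 2.0 * s12.values, "t")
        ratio = seasonal_intensity(doubled, 12.0).values / seasonal_intensity(s12, 12.0).values
        assert np.allclose(ratio, 4.0, rtol=0.05)

    def test_matches_single_cell_morlet_power(self, worlds):
        s12, _ = worlds
        layer = seasonal_intensity(s12, 12.0)
        cell = morlet_power(s12.cell_series(1, 2), (12.0,))[12.0]
        assert layer.values[1, 2] == pytest.approx(cell, rel=1e-10)


class TestFeatureTable:
    def _layers(self, grid, k=3, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f"f{i}": RasterLayer(grid, rng.uniform(0, 10, grid.shape), f"f{i}")
            for i in range(k)
        }

    def test_row_count_equals_masked_cells(self, tiny_grid):
        rng = np.random.default_rng(5)
        richness = RasterLayer(tiny_grid, rng.poisson(20, tiny_grid.shape).astype(float), "r")
        mask = rng.random(tiny_grid.shape) < 0.6
        table = build_feature_table(self._layers(tiny_grid), richness, mask=mask)
        assert table.n_rows == int(mask.sum())

    def test_features_scaled_to_unit_interval(self, tiny_grid):
        richness = RasterLayer(tiny_grid, np.abs(np.random.default_rng(6).normal(5, 2, tiny_grid.shape)), "r")
        table = build_feature_table(self._layers(tiny_grid), richness)
        X = table.X
        assert X.min() >= 0.0 and X.max() <= 1.0

    def test_log_transform_arithmetic(self, tiny_grid):
        vals = np.zeros(tiny_grid.shape)
        vals[0, 0] = np.e - 1.0
        richness = RasterLayer(tiny_grid, vals, "r")
        table = build_feature_table(self._layers(tiny_grid), richness)
        resp = table.data.set_index("cell_id")["response"]
        assert resp.loc[0] == pytest.approx(1.0)
        assert resp.drop(0).abs().max() == pytest.approx(0.0)

    def test_zero_richness_everywhere_yields_zero_response(self, tiny_grid, caplog):
        richness = RasterLayer(tiny_grid, np.zeros(tiny_grid.shape), "r")
        table = build_feature_table(self._layers(tiny_grid), richness)
        assert np.allclose(table.y, 0.0)

    def test_provenance_inverts_response(self, tiny_grid):
        rng = np.random.default_rng(7)
        richness = RasterLayer(tiny_grid, rng.poisson(30, tiny_grid.shape).astype(float), "r")
        table = build_feature_table(self._layers(tiny_grid), richness)
        back = table.inverse_response(table.y)
        assert np.allclose(np.sort(back), np.sort(richness.values.ravel()), atol=1e-9)

    def test_mismatched_grid_rejected(self, tiny_grid):
        other = make_grid((-20, 20, -20, 20), cell_km=300.0)
        richness = RasterLayer(other, np.ones(other.shape), "r")
        with pytest.raises(InvalidInputError):
            build_feature_table(self._layers(tiny_grid), richness)

    def test_feature_definition_contracts(self):
        with pytest.raises(InvalidInputError):
            FeatureDefinition("elevation", "mean", "static")
        with pytest.raises(InvalidInputError):
            FeatureDefinition("temperature", "wavelet_intensity_6", "static")
        d = FeatureDefinition("temperature", "wavelet_intensity_12", "intra-annual")
        assert d.name == "temperature_amp12"
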