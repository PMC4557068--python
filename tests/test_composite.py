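"""Standardisation chain (CHAR, minmax, Box-Cox, Z-score), binning,
smoothing and the bootstrap composite."""

import numpy as np
import pytest
from scipy import stats

from sedfire import (
    AgeDepthModel,
    CharcoalRecord,
    DegenerateSeriesError,
    SiteMeta,
    TransformParams,
    ValidationError,
    composite_from_series,
)
from sedfire.composite import (
    bin_centers,
    bin_series,
    boxcox_transform,
    composite_bootstrap,
    compute_char,
    lowess_smooth,
    minmax_rescale,
    standardize_char,
    transform_record,
    zscore,
)
from tests.conftest import random_record


class TestChar:
    def test_unit_arithmetic(self, simple_record):
        # 10 particles/cm^3 in a 1-cm slice deposited over 10 yr -> 1 cm^-2 yr^-1
        ages, char = compute_char(simple_record)
        np.testing.assert_allclose(char, [1.0, 0.0, 3.0])
        np.testing.assert_allclose(ages, [5.0, 15.0, 25.0])

    def test_zero_duration_interval_raises(self):
        # a stalled age model (possible with externally supplied ages)
        # must be reported with the offending sample, not divide by zero
        class _Flat:
            def age_at_depth(self, depth):
                return np.zeros_like(np.asarray(depth, dtype=float))

        meta = SiteMeta(site_id="z", lat=45.0, lon=-70.0, zone="temperate")
        rec = CharcoalRecord(
            meta=meta, depth_top=[0.0], depth_bottom=[1.0], concentration=[5.0],
            age_model=AgeDepthModel(depths=[0.0, 1.0], ages=[0.0, 10.0]),
        )
        rec.age_model = _Flat()
        with pytest.raises(ValidationError, match="zero duration"):
            compute_char(rec)

    def test_matches_per_sample_hand_computation(self, rng):
        rec = random_record(rng, n=25)
        ages, char = compute_char(rec)
        for i in range(rec.n_samples):
            a0 = rec.age_model.age_at_depth(rec.depth_top[i])
            a1 = rec.age_model.age_at_depth(rec.depth_bottom[i])
            expected = rec.concentration[i] * (rec.depth_bottom[i] - rec.depth_top[i]) / (a1 - a0)
            assert char[i] == pytest.approx(expected, abs=1e-9)
            assert ages[i] == pytest.approx(0.5 * (a0 + a1), abs=1e-9)


class TestStandardisation:
    def test_minmax_example(self):
        np.testing.assert_allclose(minmax_rescale([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    def test_minmax_constant_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            minmax_rescale([5.0, 5.0, 5.0])

    def test_minmax_bounds(self, rng):
        out = minmax_rescale(rng.gamma(2.0, 3.0, size=50))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_boxcox_lambda_one_is_shifted_identity(self):
        x = np.array([0.0, 0.25, 1.0])
        y, lam = boxcox_transform(x, TransformParams(minmax_epsilon=0.01), lam=1.0)
        np.testing.assert_allclose(y, x + 0.01 - 1.0, atol=1e-12)

    def test_boxcox_lambda_zero_is_log(self):
        y, _ = boxcox_transform([1.0, np.e], TransformParams(minmax_epsilon=0.0), lam=0.0)
        np.testing.assert_allclose(y, [0.0, 1.0], atol=1e-12)

    def test_boxcox_grid_mle_matches_scipy_oracle_and_recovers_lognormal(self, rng):
        """lambda-hat on lognormal data is near 0 and identical to a
        brute-force scipy.stats.boxcox_llf grid scan."""
        params = TransformParams(minmax_epsilon=0.0)
        lam_hats = []
        for _ in range(5):
            x = np.exp(rng.normal(size=400))  # already positive: no offset needed
            _, lam = boxcox_transform(x, params)
            grid = np.arange(-2.0, 2.005, 0.01)
            ll = [stats.boxcox_llf(g, x) for g in grid]
            lam_oracle = grid[int(np.argmax(ll))]
            assert lam == pytest.approx(lam_oracle, abs=1e-12)
            lam_hats.append(lam)
        assert abs(np.mean(lam_hats)) < 0.15

    def test_zscore_example_and_idempotence(self, rng):
        np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])
        x = rng.normal(size=60)
        z = zscore(x)
        assert abs(z.mean()) < 1e-12 and z.std(ddof=1) == pytest.approx(1.0)
        np.testing.assert_allclose(zscore(z), z, atol=1e-12)

    def test_chain_is_scale_invariant(self, rng):
        """Multiplying a record's concentrations by any positive constant
        leaves the standardised series unchanged — the purpose of the
        minmax/Box-Cox/Z-score chain."""
        rec = random_record(rng, n=30)
        scaled = CharcoalRecord(
            meta=rec.meta, depth_top=rec.depth_top, depth_bottom=rec.depth_bottom,
            concentration=rec.concentration * 137.5, age_model=rec.age_model,
        )
        _, z1 = transform_record(rec)
        _, z2 = transform_record(scaled)
        np.testing.assert_allclose(z1, z2, atol=1e-9)


class TestBinning:
    def test_example(self):
        idx, vals = bin_series([3.0, 7.0, 12.0], [1.0, 3.0, 5.0], 10.0)
        np.testing.assert_array_equal(idx, [0, 1])
        np.testing.assert_allclose(vals, [2.0, 5.0])

    def test_single_sample_per_bin_identity(self):
        idx, vals = bin_series([5.0, 15.0, 25.0], [1.0, 2.0, 3.0], 10.0)
        np.testing.assert_allclose(vals, [1.0, 2.0, 3.0])

    def test_negative_ages_allowed(self):
        idx, vals = bin_series([-25.0, -5.0, 5.0], [1.0, 2.0, 3.0], 10.0)
        np.testing.assert_array_equal(idx, [-3, -1, 0])

    def test_matches_bruteforce_grouping(self, rng):
        ages = rng.uniform(-100, 900, size=200)
        vals = rng.normal(size=200)
        idx, means = bin_series(ages, vals, 10.0)
        for b, m in zip(idx, means):
            sel = np.floor(ages / 10.0).astype(int) == b
            assert m == pytest.approx(vals[sel].mean(), abs=1e-9)


class TestLowess:
    def test_constant_reproduced(self):
        x = np.arange(0.0, 1000.0, 10.0)
        out = lowess_smooth(x, np.full(x.size, 3.5), 200.0)
        np.testing.assert_allclose(out, 3.5, atol=1e-9)

    def test_linear_reproduced_exactly(self):
        x = np.arange(0.0, 1000.0, 10.0)
        y = 0.3 * x - 12.0
        out = lowess_smooth(x, y, 150.0)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_matches_direct_weighted_least_squares(self, rng):
        """Each evaluated point equals an independently computed tricube
        WLS linear fit (np.polyfit with weights)."""
        x = np.sort(rng.uniform(0, 2000, size=120))
        y = np.sin(x / 300.0) + rng.normal(scale=0.2, size=x.size)
        h = 250.0
        eval_x = rng.uniform(200, 1800, size=20)
        out = lowess_smooth(x, y, h, eval_x=eval_x)
        for t, got in zip(eval_x, out):
            u = np.abs(x - t) / h
            w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
            sel = w > 0
            coef = np.polyfit(x[sel], y[sel], 1, w=np.sqrt(w[sel]))
            assert got == pytest.approx(np.polyval(coef, t), abs=1e-8)

    def test_sparse_window_propagates_gap(self):
        x = np.array([0.0, 10.0, 20.0, 5000.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = lowess_smooth(x, y, 100.0, eval_x=np.array([2500.0]))
        assert np.isnan(out[0])


class TestCompositeBootstrap:
    def _identical_records(self, rng, n=4):
        rec = random_record(rng, "base", n=60)
        return [
            CharcoalRecord(meta=SiteMeta(f"c{i}", 45.0, -70.0, "temperate"),
                           depth_top=rec.depth_top, depth_bottom=rec.depth_bottom,
                           concentration=rec.concentration, age_model=rec.age_model)
            for i in range(n)
        ]

    def test_identical_records_zero_width_ci(self, rng):
        records = self._identical_records(rng)
        params = TransformParams(n_boot=49)
        series = composite_bootstrap(records, params, rng=np.random.default_rng(0))
        ok = np.isfinite(series.mean)
        assert ok.any()
        np.testing.assert_allclose(series.ci_low[ok], series.mean[ok], atol=1e-9)
        np.testing.assert_allclose(series.ci_high[ok], series.mean[ok], atol=1e-9)
        # and the mean equals the single smoothed record
        ages, z = transform_record(records[0], params)
        idx, vals = bin_series(ages, z, params.bin_width)
        dense_idx = np.arange(idx[0], idx[-1] + 1)
        dense = np.full(dense_idx.size, np.nan)
        dense[idx - idx[0]] = vals
        smoothed = lowess_smooth(bin_centers(dense_idx, 10.0), dense, 500.0)
        np.testing.assert_allclose(series.mean[ok], smoothed[ok], atol=1e-9)

    def test_fewer_than_two_records_rejected(self, rng):
        with pytest.raises(ValidationError):
            composite_bootstrap([random_record(rng)], TransformParams(n_boot=5))

    def test_ci_nesting_95_contains_90(self, rng):
        records = [random_record(rng, f"s{i}", n=60) for i in range(6)]
        s90 = composite_bootstrap(records, TransformParams(n_boot=199, ci_level=0.90),
                                  rng=np.random.default_rng(11))
        s95 = composite_bootstrap(records, TransformParams(n_boot=199, ci_level=0.95),
                                  rng=np.random.default_rng(11))
        ok = np.isfinite(s90.mean) & np.isfinite(s95.mean)
        assert np.all(s95.ci_low[ok] <= s90.ci_low[ok] + 1e-12)
        assert np.all(s95.ci_high[ok] >= s90.ci_high[ok] - 1e-12)

    def test_single_draw_equals_pooled_then_smoothed(self, rng):
        """With n_boot = 1 the composite mean is exactly the pooled
        (per-bin mean over the drawn multiset) then smoothed series."""
        records = [random_record(rng, f"s{i}", n=50) for i in range(5)]
        params = TransformParams(n_boot=1)
        seed_rng = np.random.default_rng(99)
        series = composite_bootstrap(records, params, rng=seed_rng)

        # replay the identical multinomial draw
        replay = np.random.default_rng(99)
        mult = replay.multinomial(5, np.full(5, 0.2), size=1)[0]
        from sedfire.composite import _binned_matrix, _pooled
        binned = [transform_record(r, params) for r in records]
        grid, sums, counts = _binned_matrix(binned, params)
        pooled = _pooled(sums, counts, mult)
        expected = lowess_smooth(bin_centers(grid, 10.0), pooled, 500.0)
        both = np.isfinite(series.mean) & np.isfinite(expected)
        np.testing.assert_allclose(series.mean[both], expected[both], atol=1e-9)

    def test_doubling_n_boot_stays_within_ci(self, rng):
        records = [random_record(rng, f"s{i}", n=50) for i in range(8)]
        a = composite_bootstrap(records, TransformParams(n_boot=99), rng=np.random.default_rng(1))
        b = composite_bootstrap(records, TransformParams(n_boot=198), rng=np.random.default_rng(2))
        ok = np.isfinite(a.mean) & np.isfinite(b.mean)
        inside = (b.mean[ok] >= a.ci_low[ok] - 1e-9) & (b.mean[ok] <= a.ci_high[ok] + 1e-9)
        assert inside.mean() > 0.95

    def test_composite_from_plain_series(self, rng):
        """The same machinery composites non-charcoal (biomass) series."""
        series = [(np.arange(0.0, 3000.0, 40.0), rng.normal(size=75)) for _ in range(4)]
        comp = composite_from_series(series, TransformParams(n_boot=29),
                                     bandwidth=200.0, rng=rng)
        ok = np.isfinite(comp.mean)
        assert ok.any()
        assert np.all(comp.ci_low[ok] <= comp.mean[ok] + 1e-9)
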