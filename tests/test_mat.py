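"""Modern analogue technique: dissimilarities, k-NN prediction, radius
optimisation, k selection and the conifer/broadleaf ratio."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from sedfire import GENERA, PollenAssemblage, SedfireError, TAXA, ValidationError
from sedfire.mat import (
    CalibrationSet,
    TransferFunction,
    conifer_broadleaf_ratio,
    dissimilarity_matrix,
    loo_predictions,
    mat_predict,
    optimize_radius,
    predictive_r2,
    radius_average_biomass,
    rmsep,
    select_k,
    squared_chord_dissimilarity,
)


def _grid(rng, value=None, res=0.1, lat0=45.0, lon0=-72.0, n=30):
    lats = lat0 + res * np.arange(n) + res / 2
    lons = lon0 + res * np.arange(n) + res / 2
    if value is None:
        data = rng.gamma(2.0, 10.0, size=(n, n))
    else:
        data = np.full((n, n), float(value))
    return xr.Dataset({"Picea": (("lat", "lon"), data)}, coords={"lat": lats, "lon": lons})


def _assemblage(i, lat, lon, counts):
    return PollenAssemblage(sample_id=f"s{i:03d}", lat=lat, lon=lon, counts=counts)


class TestRadiusAverage:
    def test_uniform_grid_any_radius(self, rng):
        grid = _grid(rng, value=7.5)
        lat = float(grid["lat"].values[15])
        lon = float(grid["lon"].values[15])
        for r in (3.0, 30.0, 120.0):
            means, n = radius_average_biomass(grid, lat, lon, r)
            assert means["Picea"] == pytest.approx(7.5)

    def test_tiny_radius_hits_single_cell(self, rng):
        grid = _grid(rng)
        lat = float(grid["lat"].values[10])
        lon = float(grid["lon"].values[12])
        means, n = radius_average_biomass(grid, lat, lon, 2.0)
        assert n == 1
        assert means["Picea"] == pytest.approx(float(grid["Picea"].values[10, 12]))

    def test_no_cells_in_radius_is_error(self, rng):
        grid = _grid(rng)
        with pytest.raises(SedfireError):
            radius_average_biomass(grid, 10.0, 100.0, 5.0)

    def test_matches_bruteforce_mask_and_mean(self, rng):
        from sedfire import haversine_km

        grid = _grid(rng)
        lat, lon, r = 46.1, -70.9, 55.0
        means, n = radius_average_biomass(grid, lat, lon, r)
        acc, cnt = 0.0, 0
        for i, la in enumerate(grid["lat"].values):
            for j, lo in enumerate(grid["lon"].values):
                if haversine_km(lat, lon, la, lo) <= r:
                    acc += float(grid["Picea"].values[i, j])
                    cnt += 1
        assert cnt == n
        assert means["Picea"] == pytest.approx(acc / cnt, abs=1e-9)


class TestDissimilarity:
    def test_self_distance_zero(self, rng):
        p = rng.dirichlet(np.ones(7))
        assert squared_chord_dissimilarity(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_vectors_reach_maximum_two(self):
        assert squared_chord_dissimilarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_symmetry(self, rng):
        for _ in range(100):
            p, q = rng.dirichlet(np.ones(7)), rng.dirichlet(np.ones(7))
            assert squared_chord_dissimilarity(p, q) == pytest.approx(
                squared_chord_dissimilarity(q, p), abs=1e-12
            )

    def test_mismatched_taxon_lists_error(self):
        with pytest.raises(ValidationError):
            squared_chord_dissimilarity([0.5, 0.5], [0.3, 0.3, 0.4])

    def test_matrix_matches_pairwise(self, rng):
        P, Q = rng.dirichlet(np.ones(5), size=4), rng.dirichlet(np.ones(5), size=6)
        D = dissimilarity_matrix(P, Q)
        for i in range(4):
            for j in range(6):
                assert D[i, j] == pytest.approx(squared_chord_dissimilarity(P[i], Q[j]), abs=1e-12)


class TestMatPredict:
    def _tf(self, rng, n=15, k=3):
        P = rng.dirichlet(np.ones(7), size=n)
        y = rng.gamma(2.0, 15.0, size=n)
        return TransferFunction(genus="Picea", k=k, metric="squared_chord",
                                train_proportions=P, train_biomass=y)

    def test_query_equal_to_training_sample_k1(self, rng):
        tf = self._tf(rng, k=1)
        assert mat_predict(tf, tf.train_proportions[4]) == pytest.approx(tf.train_biomass[4])

    def test_k_equals_n_gives_grand_mean(self, rng):
        tf = self._tf(rng, n=12, k=12)
        q = rng.dirichlet(np.ones(7))
        assert mat_predict(tf, q) == pytest.approx(tf.train_biomass.mean())

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValidationError):
            self._tf(rng, n=5, k=6)

    def test_matches_bruteforce_full_sort(self, rng):
        tf = self._tf(rng, n=30, k=4)
        for _ in range(20):
            q = rng.dirichlet(np.ones(7))
            d = np.array([squared_chord_dissimilarity(q, t) for t in tf.train_proportions])
            expected = tf.train_biomass[np.argsort(d, kind="stable")[:4]].mean()
            assert mat_predict(tf, q) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_count_scaling(self, rng):
        tf = self._tf(rng)
        counts = rng.integers(1, 50, size=7).astype(float)
        p1 = counts / counts.sum()
        p2 = (counts * 13.0) / (counts * 13.0).sum()
        assert mat_predict(tf, p1) == pytest.approx(mat_predict(tf, p2), abs=1e-12)


class TestSkillMetrics:
    def test_r2_at_most_one_and_one_only_if_perfect(self, rng):
        obs = rng.normal(size=40)
        assert predictive_r2(obs, obs) == pytest.approx(1.0)
        assert predictive_r2(obs, obs + rng.normal(scale=0.1, size=40)) < 1.0

    def test_rmsep_examples(self):
        assert rmsep([1.0, 2.0], [0.0, 0.0]) == pytest.approx(np.sqrt(2.5))
        assert rmsep([3.0, 4.0], [3.0, 4.0]) == 0.0


class TestSelectK:
    def test_noiseless_mapping_prefers_small_k(self, rng):
        # pollen uniquely indexes biomass: clusters of identical spectra
        # with identical biomass, so the nearest analogue is exact while
        # wide averaging crosses clusters and pays for it
        centers = np.linspace(0.05, 0.95, 10)
        P = np.repeat(np.column_stack([centers, 1.0 - centers]), 4, axis=0)
        y = np.repeat(rng.permutation(10) * 10.0, 4).astype(float)
        k, table = select_k(P, y, (1, 5, 9), n_boot=30, rng=np.random.default_rng(5))
        assert k == 1
        assert table["rmsep"].idxmin() == 0

    def test_k_candidates_bounded(self, rng):
        P = rng.dirichlet(np.ones(3), size=10)
        with pytest.raises(ValidationError):
            select_k(P, np.arange(10.0), (10,), n_boot=5)


class TestOptimizeRadius:
    def test_table_covers_radius_list_and_single_radius(self, rng):
        grid = _grid(rng)
        modern = []
        for i in range(22):
            lat = rng.uniform(45.3, 47.6)
            lon = rng.uniform(-71.8, -69.5)
            b = radius_average_biomass(grid, lat, lon, 20.0)[0]["Picea"]
            w = np.array([b, 10.0])
            p = w / w.sum()
            counts = rng.multinomial(200, [p[0], 0, 0, 0, 0, 0, p[1]])
            modern.append(_assemblage(i, lat, lon, {t: int(c) for t, c in zip(TAXA, counts)}))
        best, table = optimize_radius(grid, modern, (10.0, 20.0, 40.0), "Picea", k=3)
        assert len(table) == 3
        assert best in {10.0, 20.0, 40.0}
        best1, table1 = optimize_radius(grid, modern, (30.0,), "Picea", k=3)
        assert best1 == 30.0 and len(table1) == 1

    def test_needs_enough_modern_samples(self, rng):
        grid = _grid(rng)
        modern = [_assemblage(0, 46.0, -71.0, {"Picea": 10, "other": 10})]
        with pytest.raises(ValidationError):
            optimize_radius(grid, modern, (10.0, 20.0), "Picea")


class TestReconstruction:
    def test_distant_fossil_site_excluded(self, rng):
        from sedfire.mat import filter_fossil_sites
        from tests.conftest import random_record

        records = [random_record(rng, "c0")]  # at (45, -72)
        near = PollenAssemblage(sample_id="near", lat=45.2, lon=-72.1, age=500.0,
                                counts={"Picea": 50, "other": 50})
        far = PollenAssemblage(sample_id="far", lat=47.0, lon=-65.0, age=500.0,
                               counts={"Picea": 50, "other": 50})
        kept = filter_fossil_sites([near, far], records, max_km=100.0)
        assert [a.sample_id for a, _zone in kept] == ["near"]
        assert kept[0][1] == "temperate"


class TestConiferBroadleafRatio:
    def test_examples(self):
        df = pd.DataFrame(
            {"Picea": [10.0, 5.0], "Pinus": [5.0, 0.0], "Abies": [5.0, 0.0],
             "Betula": [3.0, 5.0], "Acer": [1.0, 0.0], "Populus": [1.0, 0.0]},
            index=[100.0, 200.0],
        )
        out = conifer_broadleaf_ratio(df)
        assert out["ratio"].iloc[0] == pytest.approx(4.0)
        assert out["ratio"].iloc[1] == pytest.approx(1.0)

    def test_above_mean_flag(self):
        ages = np.arange(0.0, 7000.0, 500.0)
        con = np.full(ages.size, 10.0)
        con[3] = 12.0
        df = pd.DataFrame({"Picea": con, "Betula": np.ones(ages.size)}, index=ages)
        out = conifer_broadleaf_ratio(df)
        assert bool(out["above_mean"].iloc[3])
        assert not bool(out["above_mean"].iloc[0])

    def test_denominator_floor_capped(self):
        df = pd.DataFrame({"Picea": [10.0], "Betula": [0.01]}, index=[0.0])
        out = conifer_broadleaf_ratio(df, denominator_floor=0.1)
        assert out["ratio"].iloc[0] == pytest.approx(100.0)
        assert bool(out["capped"].iloc[0])

    def test_all_zero_step_missing(self):
        df = pd.DataFrame({"Picea": [0.0], "Betula": [0.0]}, index=[0.0])
        out = conifer_broadleaf_ratio(df)
        assert np.isnan(out["ratio"].iloc[0])

    def test_all_conifer_prescription_keeps_ratio_at_cap(self):
        df = pd.DataFrame({"Picea": [20.0, 30.0], "Betula": [0.0, 0.0]}, index=[0.0, 1000.0])
        out = conifer_broadleaf_ratio(df)
        assert (out["capped"]).all()
        assert np.all(out["ratio"] > 100.0)
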