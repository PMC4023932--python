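"""Moran's I, Gi*, density surfaces, quantile classes and the pipeline.

The statistics are checked against independent brute-force double-loop
implementations written here from the defining formulas, against frozen
micro-examples computed by those oracles, and against a permutation null.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from morphmap import (
    HotspotConfig,
    RecordSet,
    SpecimenRecord,
    aggregate_localities,
    build_weights,
    filter_geocoded,
    generate_csr,
    gi_star,
    hotspot_pipeline,
    incremental_moran,
    morans_i,
    point_density,
    project,
    quantile_classes,
)
from morphmap.spatial import locality_arrays


def random_localities(rng, n=200, extent=1e6):
    xy = rng.uniform(0, extent, size=(n, 2))
    values = (1 + rng.poisson(2.0, n)).astype(float)
    return xy, values

# ---------------------------------------------------------------------------
# independent oracles: naive double-sum implementations of the statistics


def moran_brute(values, w_dense):
    n = len(values)
    z = values - values.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * z[i] * z[j]
    return (n / w_dense.sum()) * num / np.sum(z**2)


def gi_star_brute(values, w_dense):
    n = len(values)
    xbar = values.mean()
    s = np.sqrt(np.sum(values**2) / n - xbar**2)
    out = np.zeros(n)
    for i in range(n):
        wi = w_dense[i].sum()
        wi2 = np.sum(w_dense[i] ** 2)
        denom = s * np.sqrt((n * wi2 - wi**2) / (n - 1))
        if denom > 0:
            out[i] = (np.dot(w_dense[i], values) - xbar * wi) / denom
    return out


def line_points(n):
    return np.column_stack([np.arange(n, dtype=float), np.zeros(n)])


class TestMoransI:
    def test_four_point_line_micro_example(self):
        # values (1,1,0,0) on a unit-spaced line, band 1: I = 1/3, E[I] = -1/3
        w = build_weights(line_points(4), 1.0)
        res = morans_i(np.array([1.0, 1.0, 0.0, 0.0]), w)
        assert res.I == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert res.expected_I == pytest.approx(-1.0 / 3.0, abs=1e-12)
        assert res.z == pytest.approx((res.I - res.expected_I) / np.sqrt(res.variance))
        oracle = moran_brute(np.array([1.0, 1.0, 0.0, 0.0]), w.matrix.toarray())
        assert res.I == pytest.approx(oracle, abs=1e-14)

    def test_constant_values_rejected(self):
        w = build_weights(line_points(5), 1.0)
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(5), w)

    def test_no_neighbours_rejected(self):
        w = build_weights(line_points(5), 0.5)
        with pytest.raises(ValueError, match="empty weights"):
            morans_i(np.arange(5.0), w)

    def test_self_inclusive_weights_rejected(self):
        w = build_weights(line_points(5), 1.0, include_self=True)
        with pytest.raises(ValueError, match="self"):
            morans_i(np.arange(5.0), w)

    def test_matches_brute_force_on_random_localities(self, rng):
        xy, values = random_localities(rng, n=200)
        w = build_weights(xy, 1.5e5)
        res = morans_i(values, w)
        oracle = moran_brute(values, w.matrix.toarray())
        assert abs(res.I - oracle) <= 1e-10 * abs(oracle)

    def test_affine_invariance(self, rng):
        xy, values = random_localities(rng, n=60)
        w = build_weights(xy, 2e5)
        base = morans_i(values, w)
        scaled = morans_i(3.7 * values - 11.0, w)
        assert scaled.I == pytest.approx(base.I, rel=1e-12)
        assert scaled.z == pytest.approx(base.z, rel=1e-9)

    def test_analytic_z_close_to_permutation_null(self, rng):
        # randomisation-assumption z should match a 999-shuffle permutation z
        for _ in range(5):
            xy = rng.uniform(0, 1e6, (100, 2))
            values = rng.poisson(3.0, 100).astype(float) + 1
            # plant mild structure so z is not trivially tiny
            values[xy[:, 0] < 3e5] += rng.poisson(2.0, int((xy[:, 0] < 3e5).sum()))
            w = build_weights(xy, 2e5)
            res = morans_i(values, w)
            dense = w.matrix.toarray()
            n, W = 100, dense.sum()
            z0 = values - values.mean()
            perm = np.array([rng.permutation(values) for _ in range(999)])
            zc = perm - perm.mean(axis=1, keepdims=True)
            i_perm = (n / W) * np.einsum("pi,ij,pj->p", zc, dense, zc) / np.sum(
                zc**2, axis=1
            )
            z_perm = (res.I - i_perm.mean()) / i_perm.std(ddof=0)
            assert abs(res.z - z_perm) < 0.3


class TestGiStar:
    def test_three_point_line_micro_example(self):
        # values (0,0,9), band 1: Gi* at the end point = 3/sqrt(18) ~ 0.7071
        w = build_weights(line_points(3), 1.0, include_self=True)
        with pytest.warns(UserWarning, match="entire data set"):
            res = gi_star(np.array([0.0, 0.0, 9.0]), w)
        assert res.z_scores[2] == pytest.approx(3.0 / np.sqrt(18.0), abs=1e-12)
        assert res.z_scores[1] == 0.0  # neighbourhood is the whole set

    def test_moran_weights_rejected(self):
        w = build_weights(line_points(4), 1.0)
        with pytest.raises(ValueError, match="self"):
            gi_star(np.arange(4.0), w)

    def test_constant_values_rejected(self):
        w = build_weights(line_points(4), 1.0, include_self=True)
        with pytest.raises(ValueError, match="zero variance"):
            gi_star(np.ones(4), w)

    def test_matches_brute_force_on_random_localities(self, rng):
        xy, values = random_localities(rng, n=200)
        w = build_weights(xy, 1.5e5, include_self=True)
        res = gi_star(values, w)
        oracle = gi_star_brute(values, w.matrix.toarray())
        scale = np.abs(oracle).max()
        assert np.max(np.abs(res.z_scores - oracle)) <= 1e-10 * scale

    def test_shift_invariance(self, rng):
        xy, values = random_localities(rng, n=80)
        w = build_weights(xy, 2e5, include_self=True)
        a = gi_star(values, w)
        b = gi_star(values + 100.0, w)
        np.testing.assert_allclose(a.z_scores, b.z_scores, rtol=1e-8, atol=1e-8)

    def test_labels_follow_threshold(self, rng):
        xy, values = random_localities(rng, n=100)
        w = build_weights(xy, 2e5, include_self=True)
        res = gi_star(values, w, threshold_sd=1.0)
        assert np.array_equal(res.labels == "hot", res.z_scores > 1.0)
        assert np.array_equal(res.labels == "cold", res.z_scores < -1.0)


class TestAggregation:
    def _records(self, coords):
        recs = [
            SpecimenRecord(
                voucher_id=f"V{i}", latitude=la, longitude=lo, geocode_error_km=1.0
            )
            for i, (la, lo) in enumerate(coords)
        ]
        return RecordSet(recs)

    def test_counts_per_unique_site(self):
        coords = [(0.0, 25.0)] * 3 + [(1.0, 26.0)] * 2
        rs = self._records(coords)
        pp = project([c[0] for c in coords], [c[1] for c in coords])
        locs = aggregate_localities(rs, pp)
        assert sorted(loc.value for loc in locs) == [2, 3]
        assert sum(loc.value for loc in locs) == 5

    def test_distinct_sites_all_singletons(self, rng):
        coords = [(float(la), float(lo)) for la, lo in rng.uniform(-5, 5, (30, 2))]
        rs = self._records(coords)
        pp = project([c[0] for c in coords], [c[1] for c in coords])
        locs = aggregate_localities(rs, pp)
        assert len(locs) == 30
        assert all(loc.value == 1 for loc in locs)
        assert sum(loc.value for loc in locs) == len(rs)


class TestDensityAndQuantiles:
    def test_radius_covering_everything(self, rng):
        xy, values = random_localities(rng, n=30)
        d = point_density((xy, values), radius_m=1e9, k=3)
        assert np.all(d.counts == values.sum())

    def test_radius_below_min_spacing(self):
        xy = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        values = np.array([2.0, 3.0, 4.0])
        d = point_density((xy, values), radius_m=10.0, k=3)
        np.testing.assert_array_equal(d.counts, values)

    def test_matches_brute_force_scan(self, rng):
        xy, values = random_localities(rng, n=500)
        r = 1.2e5
        d = point_density((xy, values), radius_m=r)
        dist = cdist(xy, xy)
        expected = ((dist <= r) * values[None, :]).sum(axis=1)
        np.testing.assert_allclose(d.counts, expected)

    def test_presence_only_flag(self, rng):
        xy, values = random_localities(rng, n=50)
        d = point_density((xy, values), radius_m=1e9, weight_by_count=False)
        assert np.all(d.counts == 50)

    def test_quantile_classes_equal_frequency(self, rng):
        values = rng.permutation(700).astype(float)
        classes, share = quantile_classes(values, k=7)
        assert np.array_equal(np.bincount(classes)[1:], np.full(7, 100))
        assert share.sum() == pytest.approx(1.0)

    def test_quantile_share_is_value_weighted(self):
        classes, share = quantile_classes(np.arange(1.0, 8.0), k=7)
        np.testing.assert_allclose(share, np.arange(1.0, 8.0) / 28.0)

    def test_all_equal_collapses_to_one_class(self):
        with pytest.warns(UserWarning, match="merged"):
            classes, share = quantile_classes(np.full(20, 5.0), k=7)
        assert np.all(classes == 1)
        assert share[0] == pytest.approx(1.0)

    def test_ties_assigned_to_lower_class(self):
        values = np.array([1.0, 2.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="merged"):
            classes, _ = quantile_classes(values, k=4)
        assert classes[1] == classes[2] == min(classes[1], classes[2])

    def test_class_populations_differ_by_at_most_one(self, rng):
        values = rng.permutation(103).astype(float)
        classes, _ = quantile_classes(values, k=7)
        pops = np.bincount(classes)[1:]
        assert pops.max() - pops.min() <= 1


class TestIncrementalMoran:
    def test_single_band(self, rng):
        xy, values = random_localities(rng, n=50)
        results, best = incremental_moran((xy, values), bands=[2e5])
        assert len(results) == 1 and best == 2e5

    def test_consistent_with_independent_calls(self, rng):
        xy, values = random_localities(rng, n=80)
        bands = [1e5, 2e5, 3e5]
        results, best = incremental_moran((xy, values), bands=bands)
        for res in results:
            solo = morans_i(values, build_weights(xy, res.band_m))
            assert res.z == pytest.approx(solo.z)
        assert best == max(results, key=lambda r: r.z).band_m

    def test_empty_band_skipped_with_warning(self):
        xy = np.vstack([line_points(6) * 1000.0])
        values = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="skipped"):
            results, _ = incremental_moran((xy, values), bands=[10.0, 1500.0])
        assert len(results) == 1

    def test_recovers_planted_cluster_scale(self, reference_records):
        # the reference scenario plants clusters of 150 km radius (300 km
        # diameter); the best band must land within one sweep step of it
        scenario, geo, pp = reference_records
        locs = aggregate_localities(geo, pp)
        results, best = incremental_moran(locs)
        step = results[1].band_m - results[0].band_m
        planted = 2 * scenario.clusters[0].radius_m
        assert abs(best - planted) <= step


class TestHotspotPipeline:
    def test_planted_clusters_recovered(self, reference_records):
        scenario, geo, pp = reference_records
        analysis = hotspot_pipeline(geo, pp)
        xy, _ = locality_arrays(analysis.localities)
        centres = np.array([c.centre_xy for c in scenario.clusters])
        radii = np.array([c.radius_m for c in scenario.clusters])
        dist = np.linalg.norm(xy[:, None, :] - centres[None], axis=2)
        in_cluster = (dist <= radii[None]).any(axis=1)
        sensitivity = analysis.gi.hot[in_cluster].mean()
        background_fpr = analysis.gi.hot[~in_cluster].mean()
        assert sensitivity >= 0.8
        assert background_fpr <= 0.05

    def test_uniform_data_mostly_unlabelled(self, rng):
        # CSR sites revisited at random: no spatial structure in the counts.
        # The raw per-site counts are scored (the calibrated attribute; the
        # smoothed density layer is anti-conservative under CSR), averaging
        # the none-rate over replicates at continental scale.
        from morphmap import AFRICA_ALBERS

        rates = []
        for _ in range(5):
            sites = generate_csr(300, (0, 0, 7e6, 7e6), rng) - 3.5e6
            xy = sites[rng.integers(0, 300, size=450)]
            lat, lon = AFRICA_ALBERS.inverse(xy[:, 0], xy[:, 1])
            rs = RecordSet(
                [
                    SpecimenRecord(
                        voucher_id=f"V{i}",
                        latitude=float(lat[i]),
                        longitude=float(lon[i]),
                        geocode_error_km=1.0,
                    )
                    for i in range(450)
                ]
            )
            pp = project(lat, lon)
            analysis = hotspot_pipeline(rs, pp, HotspotConfig(gi_on="counts"))
            rates.append(np.mean(analysis.gi.labels == "none"))
        assert np.mean(rates) >= 0.97

    def test_empty_input_rejected(self):
        rs = RecordSet([])
        with pytest.raises(ValueError, match="no geocoded records"):
            hotspot_pipeline(rs, project([], []))
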