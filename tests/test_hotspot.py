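"""Distance-band weights, the Gi* statistic, significance, and binning."""

import math

import numpy as np
import pytest

import toxpimap as tm
from toxpimap.errors import StatisticalError, ValidationError
from toxpimap.hotspot import METERS_PER_MILE


def gi_star_bruteforce(x, w):
    """Independent, loop-based evaluation of the Gi* formula (the oracle)."""
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar ** 2)
    out = []
    for i in range(n):
        wi = sum(w[i])
        num = sum(w[i][j] * x[j] for j in range(n)) - xbar * wi
        sq = sum(w[i][j] ** 2 for j in range(n))
        bracket = (n * sq - wi ** 2) / (n - 1)
        out.append(0.0 if bracket <= 0 else num / (s * math.sqrt(bracket)))
    return out


class TestDistanceBandWeights:
    def test_collinear_points(self):
        pts = [(0.0, 0.0), (10_000.0, 0.0), (20_000.0, 0.0)]
        W = tm.distance_band_weights(pts, band=15_000.0)
        assert W.neighbor_counts().tolist() == [2.0, 3.0, 2.0]
        np.testing.assert_array_equal(W.w, W.w.T)
        assert np.diag(W.w).tolist() == [1.0, 1.0, 1.0]

    def test_band_below_spacing_gives_identity(self):
        pts = [(0.0, 0.0), (10_000.0, 0.0), (20_000.0, 0.0)]
        W = tm.distance_band_weights(pts, band=5_000.0)
        np.testing.assert_array_equal(W.w, np.eye(3))

    def test_fifty_mile_band_in_meters(self):
        # two points exactly 50 miles apart are neighbors; 50 mi + 1 m are not
        d = 50 * METERS_PER_MILE
        assert tm.DEFAULT_BAND_M == pytest.approx(80467.2)
        W = tm.distance_band_weights([(0, 0), (d, 0)], tm.DEFAULT_BAND_M)
        assert W.w[0, 1] == 1.0
        W2 = tm.distance_band_weights([(0, 0), (d + 1, 0)], tm.DEFAULT_BAND_M)
        assert W2.w[0, 1] == 0.0

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            tm.distance_band_weights([(0, 0)], 10.0)
        with pytest.raises(ValidationError):
            tm.distance_band_weights([(0, 0), (np.nan, 1)], 10.0)
        with pytest.raises(ValidationError):
            tm.distance_band_weights([(0, 0), (1, 1)], 0.0)


class TestGiStar:
    def test_constant_field_is_error(self):
        W = tm.distance_band_weights([(0, 0), (1, 0), (2, 0)], 1.5)
        with pytest.raises(StatisticalError, match="variance"):
            tm.gi_star([2.0, 2.0, 2.0], W)

    def test_saturated_neighborhood_zero_by_convention(self):
        W = tm.WeightsMatrix(n=4, w=np.ones((4, 4)), band=1e9)
        np.testing.assert_array_equal(tm.gi_star([1, 2, 3, 10], W),
                                      np.zeros(4))

    def test_line_example_matches_bruteforce(self):
        x = [1.0, 2.0, 3.0, 10.0]
        pts = [(i * 1000.0, 0.0) for i in range(4)]
        W = tm.distance_band_weights(pts, band=1500.0)  # adjacent pairs only
        np.testing.assert_allclose(tm.gi_star(x, W),
                                   gi_star_bruteforce(x, W.w), atol=1e-10)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 31))
            pts = rng.uniform(0, 50_000, size=(n, 2))
            x = rng.standard_normal(n)
            W = tm.distance_band_weights(pts, band=float(rng.uniform(5e3, 4e4)))
            np.testing.assert_allclose(tm.gi_star(x, W),
                                       gi_star_bruteforce(x.tolist(), W.w),
                                       atol=1e-10)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10_000, size=(20, 2))
        W = tm.distance_band_weights(pts, 3000.0)
        x = rng.standard_normal(20)
        np.testing.assert_allclose(tm.gi_star(7.5 * x + 42.0, W),
                                   tm.gi_star(x, W), atol=1e-9)


class TestSignificanceAndFdr:
    def test_pvalue_examples(self):
        np.testing.assert_allclose(tm.significance([0.0]), [1.0])
        assert tm.significance([1.959964])[0] == pytest.approx(0.05, abs=1e-6)

    def test_p_monotone_in_abs_z(self):
        z = np.array([-3.0, -1.0, 0.0, 0.5, 2.0, 4.0])
        p = tm.significance(z)
        order = np.argsort(np.abs(z))
        assert (np.diff(p[order]) <= 0).all()

    def test_bh_hand_example(self):
        # step-up: p_(k) * n / k = (.04, .04, .04, .04) after monotonization
        np.testing.assert_allclose(tm.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_bh_properties(self):
        assert tm.fdr_adjust([0.3]).tolist() == [0.3]  # n = 1 unchanged
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        adj = tm.fdr_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # monotone: sorting by p sorts adj
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()


class TestClassifyBins:
    @pytest.mark.parametrize("z,p,expected", [
        (3.1, 0.0019, 3),    # 99% confidence hotspot
        (-1.7, 0.089, -1),   # 90% confidence coldspot
        (0.5, 0.62, 0),      # not significant
        (-2.3, 0.03, -2),    # 95% coldspot
        (2.0, 0.05, 2),      # boundary inclusive
    ])
    def test_examples(self, z, p, expected):
        assert tm.classify_bins([z], [p]).tolist() == [expected]

    def test_attainable_label_set_is_seven(self):
        z = np.array([3, 2.5, 1.8, 0.1, -1.8, -2.5, -3.0])
        p = np.array([0.005, 0.03, 0.08, 0.9, 0.08, 0.03, 0.005])
        assert set(tm.classify_bins(z, p).tolist()) == set(range(-3, 4))

    def test_sign_follows_z(self):
        rng = np.random.default_rng(17)
        z = rng.standard_normal(200) * 3
        bins = tm.classify_bins(z, tm.significance(z))
        nz = bins != 0
        assert (np.sign(bins[nz]) == np.sign(z[nz])).all()


class TestOptimizedHotspot:
    def test_planted_cluster_recovered(self, model, lattice_spec, lattice):
        boundaries, anchors = lattice
        cluster = tm.block_keys(lattice_spec, 4, 4, 3, 3)
        table = tm.simulate_components(boundaries.keys, model, seed=13,
                                       cluster=(cluster, 3.0),
                                       anchors=anchors)
        scored = tm.score_table(table, model)
        result = tm.optimized_hotspot(scored, crs=5070)
        assert result.bin_lookup()["R5C5"] == 3  # block interior

    def test_slice_selector_runs_same_pipeline(self, scored):
        name = scored.slice_names[0]
        res = tm.optimized_hotspot(scored, crs=5070, value=f"slice:{name}")
        W = tm.distance_band_weights(
            tm.project_points(np.column_stack([scored.lon, scored.lat]), 5070),
            tm.DEFAULT_BAND_M)
        np.testing.assert_allclose(
            res.z, tm.gi_star(scored.slice_column(name), W), atol=1e-12)

    def test_permutation_invariance_per_id(self, scored):
        r1 = tm.optimized_hotspot(scored, crs=5070)
        perm = np.random.default_rng(2).permutation(len(scored))
        shuffled = tm.ScoredTable(
            ids=[scored.ids[i] for i in perm],
            slice_names=scored.slice_names,
            slice_scores=scored.slice_scores[perm],
            overall=scored.overall[perm], weights=scored.weights,
            lon=scored.lon[perm], lat=scored.lat[perm])
        r2 = tm.optimized_hotspot(shuffled, crs=5070)
        lut1, lut2 = r1.bin_lookup(), r2.bin_lookup()
        assert lut1 == lut2
        z2 = dict(zip(r2.ids, r2.z))
        np.testing.assert_allclose([z2[i] for i in r1.ids], r1.z, atol=1e-12)

    def test_fdr_off_uses_raw_p(self, scored):
        raw = tm.optimized_hotspot(scored, crs=5070, use_fdr=False)
        adj = tm.optimized_hotspot(scored, crs=5070, use_fdr=True)
        assert raw.p_adj is None and adj.p_adj is not None
        # FDR can only weaken significance
        assert (np.abs(adj.bin) <= np.abs(raw.bin)).all()

    def test_too_few_records(self, small_scored):
        two = tm.ScoredTable(
            ids=["a", "b"], slice_names=["s1"],
            slice_scores=np.array([[0.1], [0.9]]),
            overall=np.array([0.1, 1.0]), weights=np.array([1.0]),
            lon=np.array([-100.0, -101.0]), lat=np.array([35.0, 36.0]))
        with pytest.raises(ValidationError):
            tm.optimized_hotspot(two)

    def test_csv_output(self, tmp_path, scored):
        res = tm.optimized_hotspot(scored, crs=5070)
        p = tmp_path / "hs.csv"
        tm.write_hotspot_csv(res, p)
        header = p.read_text().splitlines()[0]
        assert header == "id,z,p,p_adj,gi_bin"
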