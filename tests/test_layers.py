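"""Feature-layer assembly, region aggregation, and vector-file round trips."""

import json

import numpy as np
import pytest
from shapely.geometry import Polygon

import toxpimap as tm
from toxpimap.errors import DataIOError, ValidationError
from toxpimap.layers import dense_ranks


class TestProfileLayer:
    def test_feature_count_product(self, scored, model):
        layer = tm.build_profile_layer(scored, model, crs=5070)
        assert len(layer) == 100 * 14

    def test_top_record_has_rank_one(self, scored, model):
        layer = tm.build_profile_layer(scored, model, crs=5070)
        top = [a for _, a in layer.features if a["overall_score"] == 1.0]
        assert top and all(a["rank"] == 1 for a in top)

    def test_attribute_schema_complete(self, scored, model):
        layer = tm.build_profile_layer(scored, model, crs=5070)
        required = {"id", "label", "slice_name", "slice_score", "slice_weight",
                    "slice_color", "overall_score", "rank", "components"}
        _, attrs = layer.features[0]
        assert required <= set(attrs)

    def test_wedge_exposes_raw_component_values(self, scored, model):
        layer = tm.build_profile_layer(scored, model, crs=5070)
        slice0 = model.slices[0]
        geom, attrs = next(
            f for f in layer.features
            if f[1]["id"] == "R3C7" and f[1]["slice_name"] == slice0.name)
        comps = json.loads(attrs["components"])
        for comp in slice0.components:
            assert comps[comp.column] == pytest.approx(
                float(scored.raw.loc["R3C7", comp.column]))

    def test_unresolvable_anchor_reports_ids(self, scored, model):
        broken = tm.ScoredTable(
            ids=scored.ids, slice_names=scored.slice_names,
            slice_scores=scored.slice_scores, overall=scored.overall,
            weights=scored.weights,
            lon=np.full(len(scored), np.nan), lat=np.full(len(scored), np.nan),
            join_key=[None] * len(scored))
        with pytest.raises(ValidationError, match="R0C0"):
            tm.build_profile_layer(broken, model, crs=5070)


class TestRingsLayer:
    def test_one_ring_per_record_and_containment(self, scored, model):
        rings = tm.build_rings_layer(scored, R=5000.0, crs=5070)
        glyphs = tm.build_profile_layer(scored, model, R=5000.0, crs=5070)
        assert len(rings) == 100
        by_id = {a["id"]: g.buffer(5000.0 * 1e-3) for g, a in rings.features}
        assert all(by_id[a["id"]].covers(g) for g, a in glyphs.features)


class TestBoundaryLayer:
    def test_join_and_labels(self, scored, lattice):
        boundaries, _ = lattice
        layer = tm.build_boundary_layer(boundaries, scored)
        assert len(layer) == 100
        lut = {a["join_key"]: a for _, a in layer.features}
        assert lut["R0C0"]["label"] == "Cell R0C0"
        i = scored.ids.index("R0C0")
        assert lut["R0C0"]["overall_score"] == pytest.approx(scored.overall[i])

    def test_unmatched_boundary_kept_with_null(self, small_scored):
        b = tm.BoundaryLayer(
            keys=["a", "b", "c", "extra"], labels=["A", "B", "C", "X"],
            geometries=[Polygon([(i, 0), (i + 1, 0), (i + 1, 1), (i, 1)])
                        for i in range(4)])
        layer = tm.build_boundary_layer(b, small_scored)
        scores = {a["join_key"]: a["overall_score"] for _, a in layer.features}
        assert scores["extra"] is None
        assert scores["a"] == 1.0

    def test_scrambled_key_order_joins_by_key(self, small_scored):
        b = tm.BoundaryLayer(
            keys=["c", "a", "b"], labels=["C", "A", "B"],
            geometries=[Polygon([(i, 0), (i + 1, 0), (i + 1, 1), (i, 1)])
                        for i in range(3)])
        layer = tm.build_boundary_layer(b, small_scored)
        scores = {a["join_key"]: a["overall_score"] for _, a in layer.features}
        assert scores == {"a": 1.0, "b": 0.2, "c": 0.9}

    def test_zero_matches_is_error(self, small_scored):
        b = tm.BoundaryLayer(keys=["zz"], labels=["Z"],
                             geometries=[Polygon([(0, 0), (1, 0), (1, 1)])])
        with pytest.raises(ValidationError, match="key"):
            tm.build_boundary_layer(b, small_scored)


class TestChoropleth:
    def test_value_attribute(self, scored, lattice):
        boundaries, _ = lattice
        vals = dict(zip(scored.ids, map(float, scored.overall)))
        layer = tm.make_choropleth(boundaries, vals, "overall_score")
        assert len(layer) == 100
        assert all("overall_score" in a for _, a in layer.features)

    def test_gi_bin_choropleth(self, scored, lattice):
        boundaries, _ = lattice
        result = tm.optimized_hotspot(scored, crs=5070)
        layer = tm.make_choropleth(
            boundaries, {k: float(v) for k, v in result.bin_lookup().items()},
            "gi_bin")
        bins = {a["gi_bin"] for _, a in layer.features}
        assert bins <= {float(b) for b in range(-3, 4)}

    def test_empty_values_error(self, lattice):
        boundaries, _ = lattice
        with pytest.raises(ValidationError, match="empty"):
            tm.make_choropleth(boundaries, {}, "x")


class TestAggregateRegions:
    def test_median_policies(self):
        s = tm.ScoredTable(
            ids=["a", "b", "c", "d", "e"],
            slice_names=["s1"],
            slice_scores=np.array([[0.2], [0.4], [0.6], [0.2], [0.4]]),
            overall=np.array([0.2, 0.4, 0.6, 0.2, 0.4]),
            weights=np.array([1.0]),
            lon=np.arange(5, dtype=float), lat=np.zeros(5))
        region_of = {"a": "odd", "b": "odd", "c": "odd",
                     "d": "even", "e": "even"}
        agg = tm.aggregate_regions(s, region_of)
        med = dict(zip(agg.ids, agg.slice_scores[:, 0]))
        assert med["odd"] == pytest.approx(0.4)   # odd-count median
        assert med["even"] == pytest.approx(0.3)  # mean of middle two

    def test_single_region_anchor_and_overall(self, small_scored):
        agg = tm.aggregate_regions(small_scored,
                                   {i: "only" for i in small_scored.ids})
        assert agg.ids == ["only"]
        assert agg.overall[0] == 1.0  # renormalization anchor
        assert agg.lon[0] == pytest.approx(np.mean(small_scored.lon))

    def test_permutation_invariance_and_identity(self, scored):
        region_of = {rid: f"band{int(rid[1:rid.index('C')]) // 2}"
                     for rid in scored.ids}
        a1 = tm.aggregate_regions(scored, region_of)
        perm = np.random.default_rng(5).permutation(len(scored))
        shuffled = tm.ScoredTable(
            ids=[scored.ids[i] for i in perm],
            slice_names=scored.slice_names,
            slice_scores=scored.slice_scores[perm],
            overall=scored.overall[perm], weights=scored.weights,
            lon=scored.lon[perm], lat=scored.lat[perm],
            join_key=[scored.join_key[i] for i in perm])
        a2 = tm.aggregate_regions(shuffled, region_of)
        order = [a2.ids.index(r) for r in a1.ids]
        np.testing.assert_allclose(a2.slice_scores[order], a1.slice_scores)
        # identity: one member per region leaves medians untouched
        solo = tm.aggregate_regions(scored, {rid: rid for rid in scored.ids})
        order = [solo.ids.index(r) for r in scored.ids]
        np.testing.assert_allclose(solo.slice_scores[order],
                                   scored.slice_scores)

    def test_empty_mapping_error(self, scored):
        with pytest.raises(ValidationError):
            tm.aggregate_regions(scored, {})


class TestVectorRoundTrips:
    def test_geojson_lossless(self, tmp_path, scored, model):
        layer = tm.build_profile_layer(scored, model, crs=5070)
        p = tmp_path / "glyph.geojson"
        tm.write_layer(layer, p)
        back = tm.read_layer(p)
        assert len(back) == len(layer)
        for (g0, a0), (g1, a1) in zip(layer.features[:50], back.features[:50]):
            assert a0 == a1
            expected = tm.geometry.transform_geometry(g0, 5070, 4326)
            np.testing.assert_allclose(np.asarray(g1.exterior.coords),
                                       np.asarray(expected.exterior.coords),
                                       atol=1e-9)

    def test_gpkg_lossless_native_crs(self, tmp_path, scored, model):
        layer = tm.build_profile_layer(scored, model, crs=5070)
        p = tmp_path / "out.gpkg"
        tm.write_layer(layer, p)
        back = tm.read_layer(p, "glyph")
        assert back.crs == 5070
        for (g0, a0), (g1, a1) in zip(layer.features, back.features):
            assert a0 == a1
            np.testing.assert_allclose(np.asarray(g1.exterior.coords),
                                       np.asarray(g0.exterior.coords),
                                       atol=1e-9)

    def test_gpkg_holds_multiple_layers(self, tmp_path, scored, model,
                                        lattice):
        boundaries, _ = lattice
        p = tmp_path / "multi.gpkg"
        tm.write_layer(tm.build_profile_layer(scored, model, crs=5070), p)
        tm.write_layer(tm.build_rings_layer(scored, crs=5070), p,
                       layer_name="ring")
        tm.write_layer(tm.build_boundary_layer(boundaries, scored), p,
                       layer_name="boundary")
        from toxpimap._vecio import list_gpkg_layers
        assert sorted(list_gpkg_layers(p)) == ["boundary", "glyph", "ring"]
        assert len(tm.read_layer(p, "ring")) == 100

    def test_shapefile_truncation_warning(self, tmp_path, scored, lattice):
        boundaries, _ = lattice
        layer = tm.build_boundary_layer(boundaries, scored)
        with pytest.warns(UserWarning, match="truncated"):
            tm.write_layer(layer, tmp_path / "b.shp")
        back = tm.read_layer(tmp_path / "b.shp")
        assert len(back) == 100
        assert "overall_sc" in back.features[0][1]  # 10-char dBASE limit

    def test_unsupported_extension(self, tmp_path, scored, model):
        layer = tm.build_profile_layer(scored, model, crs=5070)
        with pytest.raises(ValidationError, match="format"):
            tm.write_layer(layer, tmp_path / "out.kml")


def test_dense_ranks_share_ties():
    ranks = dense_ranks(np.array([1.0, 0.5, 1.0, 0.2]))
    assert ranks.tolist() == [1, 2, 1, 3]


def test_multiscale_bundle_roles(scored, model, lattice):
    boundaries, _ = lattice
    region_of = {rid: f"S{int(rid[1:rid.index('C')]) // 5}"
                 for rid in scored.ids}
    bundle = tm.build_multiscale(scored, model, region_of, boundaries,
                                 crs=5070)
    roles = [layer.role for layer in bundle]
    assert roles == ["glyph", "glyph_coarse", "choropleth",
                     "choropleth_coarse"]
    assert len(bundle[1]) == 2 * 14  # two regions x slices
    assert bundle[0].zoom_hint != bundle[1].zoom_hint
    assert all("zoom_min" in a for _, a in bundle[1].features)
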