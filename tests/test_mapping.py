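"""Grids, probability surfaces, verbal classes, prevalence tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from shapely.geometry import Point, Polygon

import sekrige as sk
from sekrige.mapping import IPCC_SCALE
from sekrige.variogram import VariogramModel


def brute_force_nodes(polygon, spacing_km):
    """Independent candidate-lattice + point-in-polygon containment oracle."""
    minx, miny, maxx, maxy = polygon.bounds
    nodes = []
    ny = int(np.floor((maxy - miny) / spacing_km + 0.5)) + 1
    nx = int(np.floor((maxx - minx) / spacing_km + 0.5)) + 1
    for j in range(ny):
        for i in range(nx):
            p = Point(minx + i * spacing_km, miny + j * spacing_km)
            if polygon.contains(p) or polygon.boundary.distance(p) < 1e-12:
                nodes.append((p.x, p.y))
    return np.array(nodes)


class TestBuildGrid:
    def test_square_km_at_250m_matches_containment_oracle(self):
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        grid = sk.build_grid(square, spacing_m=250.0)
        oracle = brute_force_nodes(square, 0.25)
        assert len(grid.nodes) == len(oracle) == 25  # 5x5 incl. boundary
        assert set(map(tuple, np.round(grid.nodes, 9))) == \
            set(map(tuple, np.round(oracle, 9)))

    def test_irregular_polygon_matches_containment_oracle(self):
        poly = Polygon([(0, 0), (4, 0), (4, 1), (1, 1), (1, 3), (0, 3)])
        grid = sk.build_grid(poly, spacing_m=300.0)
        oracle = brute_force_nodes(poly, 0.3)
        assert set(map(tuple, np.round(grid.nodes, 9))) == \
            set(map(tuple, np.round(oracle, 9)))

    def test_spacing_larger_than_polygon_errors(self):
        # a triangle avoiding its bounding-box anchor corner: a 2 km lattice
        # on a ~1 km shape retains nothing
        tri = Polygon([(0.9, 0.0), (1.0, 1.0), (0.0, 1.0)])
        with pytest.raises(ValueError):
            sk.build_grid(tri, spacing_m=2000.0)
        # the anchored corner node survives any spacing on a square
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert len(sk.build_grid(square, spacing_m=900.0).nodes) >= 1

    def test_c_shaped_polygon_excludes_notch(self):
        c_shape = Polygon([(0, 0), (3, 0), (3, 1), (1, 1), (1, 2), (3, 2),
                           (3, 3), (0, 3)])
        grid = sk.build_grid(c_shape, spacing_m=500.0)
        # (2, 1.5) sits in the notch
        assert not any(np.allclose(n, (2.0, 1.5)) for n in grid.nodes)

    def test_node_count_scales_inversely_with_spacing_squared(self):
        square = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        n1 = len(sk.build_grid(square, spacing_m=250.0).nodes)
        n2 = len(sk.build_grid(square, spacing_m=500.0).nodes)
        assert n1 / n2 == pytest.approx(4.0, rel=0.11)


class TestPredictSurface:
    def test_nugget_model_gives_flat_mean_surface(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (20, 2))
        z = rng.normal(40, 5, 20)
        m = VariogramModel(family="nugget", c0=25.0, c1=0.0)
        grid = sk.build_grid(Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
                             spacing_m=2000.0)
        pred, var = sk.predict_surface(m, coords, z, grid)
        assert np.allclose(pred.values, z.mean(), atol=1e-8)
        assert np.all(var.values > 25.0)  # nugget + mean uncertainty

    def test_surface_hits_datum_when_node_coincides(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 2.0]])
        z = np.array([3.0, 7.0, 5.0])
        m = VariogramModel(family="exponential", c0=0.0, c1=10.0, a=1.0)
        grid = sk.build_grid(Polygon([(0, 0), (2, 0), (2, 2), (0, 2)]),
                             spacing_m=1000.0)
        pred, var = sk.predict_surface(m, coords, z, grid)
        at_origin = np.all(grid.nodes == 0, axis=1)
        assert pred.values[at_origin][0] == pytest.approx(3.0, abs=1e-8)
        assert var.values[at_origin][0] == pytest.approx(0.0, abs=1e-8)

    def test_variance_drops_when_data_density_doubles(self, district_polygon):
        m = VariogramModel(family="exponential", c0=40.0, c1=120.0, a=5.0)
        grid = sk.build_grid(district_polygon, spacing_m=5000.0)
        drops = 0
        for seed in range(10):
            ss1 = sk.SamplingSpec(polygon=district_polygon, n_clusters=12,
                                  per_cluster=10, seed=seed)
            ss2 = sk.SamplingSpec(polygon=district_polygon, n_clusters=24,
                                  per_cluster=10, seed=seed + 500)
            rng = np.random.default_rng(seed)
            c1 = sk.sample_locations(ss1)
            c2 = sk.sample_locations(ss2)
            z1 = rng.normal(40, 10, len(c1))
            z2 = rng.normal(40, 10, len(c2))
            _, v1 = sk.predict_surface(m, c1, z1, grid)
            _, v2 = sk.predict_surface(m, c2, z2, grid)
            drops += v2.values.mean() < v1.values.mean()
        assert drops >= 9


class TestDeficiencyProbability:
    def test_prediction_at_threshold_is_half(self):
        assert sk.deficiency_probability(70.0, 25.0, 70.0) == 0.5

    def test_gaussian_quantile(self):
        # zhat = T - 1.645 sigma -> P ~ 0.95
        assert sk.deficiency_probability(70 - 1.645 * 4.0, 16.0, 70.0) == \
            pytest.approx(norm.cdf(1.645), abs=1e-12)

    @pytest.mark.parametrize("zhat,expected", [(60.0, 1.0), (80.0, 0.0),
                                               (70.0, 0.5)])
    def test_zero_variance_degenerates_to_indicator(self, zhat, expected):
        assert sk.deficiency_probability(zhat, 0.0, 70.0) == expected

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            sk.deficiency_probability(50.0, -1.0, 70.0)

    def test_monotone_in_threshold_nodewise(self):
        rng = np.random.default_rng(3)
        zhat = rng.normal(60, 15, 500)
        var = rng.uniform(0, 300, 500)
        thr = sk.ThresholdSet()
        p_idi = sk.deficiency_probability(zhat, var, thr.idi)
        p_gen = sk.deficiency_probability(zhat, var, thr.generic)
        p_gpx = sk.deficiency_probability(zhat, var, thr.gpx3)
        p_sel = sk.deficiency_probability(zhat, var, thr.selenop)
        assert np.all(p_idi <= p_gen)
        assert np.all(p_gen <= p_gpx)
        assert np.all(p_gpx <= p_sel)


class TestVerbalClassify:
    def test_ipcc_examples(self):
        assert sk.verbal_classify(0.98) == "very likely"
        assert sk.verbal_classify(0.5) == "about as likely as not"
        assert sk.verbal_classify(1.0) == "virtually certain"
        assert sk.verbal_classify(0.0) == "exceptionally unlikely"

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_classes_partition_unit_interval(self, p):
        """Every probability gets exactly one label, and the label's range
        contains it."""
        label = sk.verbal_classify(p)
        matches = [(name, lo, hi) for name, lo, hi in IPCC_SCALE
                   if name == label]
        assert len(matches) == 1
        _, lo, hi = matches[0]
        assert (p > lo or (lo == 0.0 and p >= 0.0)) and p <= hi

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sk.verbal_classify(1.5)

    def test_composition_monotone_in_standardized_margin(self):
        """verbal class of P(<T) never decreases as (T - zhat)/sigma grows."""
        order = {name: i for i, (name, _, _) in enumerate(IPCC_SCALE)}
        margins = np.linspace(-4, 4, 60)
        labels = [sk.verbal_classify(sk.deficiency_probability(-m, 1.0, 0.0))
                  for m in margins]
        ranks = [order[l] for l in labels]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))


class TestPrevalence:
    def _recs(self, values, district="D", group="child"):
        return [sk.SurveyRecord(id=f"{district}{i}", group=group,
                                district=district, x=0.0, y=0.0,
                                se=float(v))
                for i, v in enumerate(values)]

    def test_half_below_simple(self):
        table = sk.prevalence_table(self._recs([60.0, 80.0]))
        row = table[table["district"] == "D"].iloc[0]
        assert row["pct_below_plasma_se_70"] == 50.0

    def test_all_below_everything(self):
        table = sk.prevalence_table(self._recs([10.0, 20.0, 30.0]))
        cols = [c for c in table.columns if c.startswith("pct_below")]
        assert (table[cols] == 100.0).all().all()

    def test_value_exactly_at_threshold_is_not_deficient(self):
        table = sk.prevalence_table(self._recs([70.0, 70.0]))
        assert table.iloc[0]["pct_below_plasma_se_70"] == 0.0

    def test_gaussian_closed_form(self):
        """Large Gaussian sample (mean/SD of the pooled child stratum) vs
        the 64.8 ug/L threshold: prevalence matches the normal tail."""
        rng = np.random.default_rng(99)
        table = sk.prevalence_table(self._recs(rng.normal(41.6, 15.0, 100_000)))
        expected = 100 * norm.cdf((64.8 - 41.6) / 15.0)  # 93.9%
        assert table.iloc[0]["pct_below_idi_64.8"] == \
            pytest.approx(expected, abs=0.5)

    def test_pooled_row_is_weighted_mean_of_districts(self):
        rng = np.random.default_rng(7)
        recs = (self._recs(rng.normal(40, 10, 30), "A")
                + self._recs(rng.normal(60, 10, 70), "B"))
        table = sk.prevalence_table(recs)
        cols = [c for c in table.columns if c.startswith("pct_below")]
        by = {r["district"]: r for _, r in table.iterrows()}
        for c in cols:
            pooled = (30 * by["A"][c] + 70 * by["B"][c]) / 100
            assert by["Overall"][c] == pytest.approx(pooled, abs=1e-12)


class TestAverageProbability:
    def test_constant_and_two_node_surfaces(self):
        g = sk.GridSurface(1.0, np.zeros((4, 2)), np.full(4, 0.7))
        assert sk.average_district_probability(g) == pytest.approx(0.7)
        g2 = sk.GridSurface(1.0, np.zeros((2, 2)), np.array([0.0, 1.0]))
        assert sk.average_district_probability(g2) == 0.5

    def test_low_mean_field_gives_high_average_probability(self, district_polygon):
        """A field far below the threshold maps to near-certain deficiency."""
        ss = sk.SamplingSpec(polygon=district_polygon, n_clusters=20,
                             per_cluster=10, seed=1)
        coords = sk.sample_locations(ss)
        z = sk.simulate_grf(coords, sk.FieldSpec(mean=37.0, c0=40, c1=117,
                                                 a=6.0, seed=2))
        m = VariogramModel(family="exponential", c0=40.0, c1=117.0, a=6.0)
        grid = sk.build_grid(district_polygon, spacing_m=2500.0)
        pred, var = sk.predict_surface(m, coords, z, grid)
        prob = sk.probability_surface(pred, var, 64.8)
        assert sk.average_district_probability(prob) > 0.9
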