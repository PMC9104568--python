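import logging

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from pilespot.geometry import cross_section_outline
from pilespot.interpolation import (
    FieldGrid,
    assemble_boundary,
    cross_section_field,
    longitudinal_field,
    natural_neighbor_interpolate,
    rbf_interpolate,
    sibson_weights,
)
from pilespot.measurements_io import AmbientConditions, MeasurementRecord

from _oracles import rbf_dense_oracle, sibson_weights_oracle
from conftest import interior_queries


def random_sites(rng, n):
    return rng.uniform(0.0, 10.0, (n, 2))


class TestSibsonWeights:
    def test_square_center_splits_evenly(self):
        sites = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        w = sibson_weights(sites, np.array([0.5, 0.5]))
        assert w == pytest.approx([0.25, 0.25, 0.25, 0.25], abs=1e-12)
        assert w @ np.array([0.0, 0.0, 10.0, 10.0]) == pytest.approx(5.0)

    def test_partition_of_unity_and_nonnegativity(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            sites = random_sites(rng, rng.integers(5, 13))
            for q in interior_queries(rng, sites, 3):
                w = sibson_weights(sites, q)
                assert abs(w.sum() - 1.0) < 1e-9
                assert (w >= -1e-12).all()

    def test_matches_voronoi_area_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            sites = random_sites(rng, rng.integers(5, 13))
            for q in interior_queries(rng, sites, 2):
                mine = sibson_weights(sites, q)
                ref = sibson_weights_oracle(sites, q)
                assert np.abs(mine - ref).max() < 1e-8

    def test_query_at_site_gets_unit_weight(self):
        rng = np.random.default_rng(13)
        sites = random_sites(rng, 8)
        w = sibson_weights(sites, sites[3])
        assert w[3] == 1.0 and w.sum() == 1.0


class TestNaturalNeighbor:
    def test_constant_field_reproduced(self):
        rng = np.random.default_rng(21)
        sites = random_sites(rng, 9)
        out = natural_neighbor_interpolate(sites, np.full(9, 4.2),
                                           interior_queries(rng, sites, 10))
        assert out == pytest.approx(np.full(10, 4.2), abs=1e-9)

    def test_exact_at_sites(self):
        rng = np.random.default_rng(22)
        sites = random_sites(rng, 10)
        values = rng.uniform(-5, 90, 10)
        assert natural_neighbor_interpolate(sites, values, sites) == pytest.approx(values)

    def test_min_max_bounded(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            sites = random_sites(rng, rng.integers(5, 13))
            values = rng.uniform(0, 100, len(sites))
            out = natural_neighbor_interpolate(sites, values,
                                               interior_queries(rng, sites, 8))
            assert out.min() >= values.min() - 1e-9
            assert out.max() <= values.max() + 1e-9

    def test_too_few_or_collinear_sites_raise(self):
        with pytest.raises(ValueError, match="boundary"):
            natural_neighbor_interpolate([[0, 0], [1, 1]], [1, 2], [[0.5, 0.5]])
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            natural_neighbor_interpolate(line, np.arange(5.0), [[1.0, 1.1]])

    def test_duplicate_site_with_same_value_is_harmless(self):
        rng = np.random.default_rng(24)
        sites = random_sites(rng, 8)
        values = rng.uniform(0, 50, 8)
        queries = interior_queries(rng, sites, 6)
        base = natural_neighbor_interpolate(sites, values, queries)
        dup = natural_neighbor_interpolate(
            np.vstack([sites, sites[2]]), np.append(values, values[2]), queries
        )
        assert dup == pytest.approx(base, abs=1e-6)

    def test_duplicate_site_with_conflicting_value_raises(self):
        sites = np.array([[0, 0], [1, 0], [0, 1], [0, 0]], float)
        with pytest.raises(ValueError, match="conflicting"):
            natural_neighbor_interpolate(sites, [1.0, 2.0, 3.0, 9.0], [[0.3, 0.3]])


class TestRBF:
    def test_exact_at_sites(self):
        rng = np.random.default_rng(31)
        sites = random_sites(rng, 9)
        values = rng.uniform(-10, 80, 9)
        pred = rbf_interpolate(sites, values, sites)
        assert np.abs(pred - values).max() < 1e-8 * max(1.0, np.abs(values).max())

    def test_constant_and_affine_reproduction(self):
        rng = np.random.default_rng(32)
        sites = random_sites(rng, 10)
        queries = rng.uniform(0, 10, (15, 2))
        const = rbf_interpolate(sites, np.full(10, 3.3), queries)
        assert const == pytest.approx(np.full(15, 3.3), abs=1e-9)
        affine = 2.0 * sites[:, 0] - 0.5 * sites[:, 1] + 1.0
        pred = rbf_interpolate(sites, affine, queries)
        assert pred == pytest.approx(2.0 * queries[:, 0] - 0.5 * queries[:, 1] + 1.0, abs=1e-8)

    def test_single_site_query_at_site(self):
        assert rbf_interpolate([[1.0, 2.0]], [5.0], [[1.0, 2.0]]) == pytest.approx([5.0])

    @pytest.mark.parametrize("kernel", ["multiquadric", "thin-plate", "gaussian"])
    def test_matches_dense_solve_oracle(self, kernel):
        rng = np.random.default_rng(33)
        for _ in range(10):
            sites = random_sites(rng, 5)
            values = rng.uniform(0, 60, 5)
            queries = rng.uniform(0, 10, (20, 2))
            shape = 1.5
            mine = rbf_interpolate(sites, values, queries, kernel=kernel, shape_param=shape)
            ref = rbf_dense_oracle(sites, values, queries, kernel, shape)
            assert np.abs(mine - ref).max() < 1e-8 * max(1.0, np.abs(values).max())

    @pytest.mark.parametrize("kernel,scipy_kernel", [
        ("multiquadric", "multiquadric"),
        ("thin-plate", "thin_plate_spline"),
        ("gaussian", "gaussian"),
    ])
    def test_matches_scipy_rbfinterpolator(self, kernel, scipy_kernel):
        rng = np.random.default_rng(34)
        sites = random_sites(rng, 12)
        values = rng.uniform(0, 60, 12)
        queries = rng.uniform(0, 10, (25, 2))
        shape = 1.7
        mine = rbf_interpolate(sites, values, queries, kernel=kernel, shape_param=shape)
        ref = RBFInterpolator(sites, values, kernel=scipy_kernel,
                              epsilon=1.0 / shape, degree=1)(queries)
        assert np.abs(mine - ref).max() < 1e-7 * max(1.0, np.abs(values).max())

    def test_duplicate_sites_raise(self):
        pts = np.array([[0, 0], [0, 0], [1, 1]], float)
        with pytest.raises(ValueError, match="duplicate"):
            rbf_interpolate(pts, [1.0, 1.0, 2.0], [[0.5, 0.5]])

    def test_kernel_matrix_symmetry_implied_by_agreement(self):
        # interchanging two sites leaves predictions unchanged
        rng = np.random.default_rng(35)
        sites = random_sites(rng, 7)
        values = rng.uniform(0, 10, 7)
        queries = rng.uniform(0, 10, (5, 2))
        perm = np.array([1, 0, 2, 3, 4, 5, 6])
        assert rbf_interpolate(sites, values, queries) == pytest.approx(
            rbf_interpolate(sites[perm], values[perm], queries)
        )


class TestBoundary:
    def test_default_is_all_ambient(self, a1):
        outline = cross_section_outline(a1)
        ambient = AmbientConditions(day=1, temp_C=20.0)
        bs = assemble_boundary(outline, ambient)
        assert len(bs) == 24 + 3
        assert np.all(bs.values["o2_pct"] == 20.9)
        assert np.all(bs.values["temp_C"] == 20.0)

    def test_channel_records_override_channel_points(self, a1):
        outline = cross_section_outline(a1)
        ambient = AmbientConditions(day=1, temp_C=20.0)
        chan = [MeasurementRecord("A1", 1, 2.5, "channel", "n/a", 18.0, None, None, None)
                for _ in range(3)]
        bs = assemble_boundary(outline, ambient, channel_records=chan)
        temps = bs.values["temp_C"]
        assert np.sum(temps == 18.0) == 3
        # a missing channel gas falls back to ambient
        assert np.all(bs.values["o2_pct"] == 20.9)

    def test_boundary_points_never_strictly_interior(self, a1):
        outline = cross_section_outline(a1)
        bs = assemble_boundary(outline, AmbientConditions(day=1, temp_C=15.0))
        shrunk = outline.polygon.buffer(-1e-6)
        from shapely.geometry import Point

        assert not any(shrunk.contains(Point(*p)) for p in bs.points)


def _section_records(pile, distance, temp, o2, co2):
    recs = []
    for side in ("left", "right"):
        for level in ("H1", "H2", "H3"):
            recs.append(MeasurementRecord(pile.pile_id, 22, distance, side, level,
                                          temp, o2, co2, 100.0))
    recs.append(MeasurementRecord(pile.pile_id, 22, distance, "deep", "mid-deep",
                                  temp, o2, co2, 100.0))
    return recs


class TestSectionFields:
    AMBIENT = AmbientConditions(day=22, temp_C=20.0)

    def test_uniform_records_at_ambient_give_uniform_field(self, a1):
        recs = _section_records(a1, 2.5, 20.0, 20.9, 0.04)
        grid = cross_section_field(recs, a1, "temp_C", self.AMBIENT, cell_size_m=0.25)
        assert np.allclose(grid.values[grid.mask], 20.0, atol=1e-6)

    def test_single_hot_probe_is_field_maximum(self, a1):
        recs = _section_records(a1, 2.5, 20.0, 20.9, 0.04)
        hot = MeasurementRecord("A1", 22, 2.5, "deep", "mid-deep", 70.0, 8.0, 9.0, 900.0)
        recs = [r for r in recs if r.side != "deep"] + [hot]
        grid = cross_section_field(recs, a1, "temp_C", self.AMBIENT, cell_size_m=0.1)
        r, c = np.unravel_index(np.nanargmax(np.where(grid.mask, grid.values, -np.inf)),
                                grid.values.shape)
        y, z = grid.node_position(r, c)
        assert abs(y - 0.0) <= 0.1 and abs(z - a1.probing_heights_m[1]) <= 0.1
        assert np.nanmax(grid.values) == pytest.approx(70.0, abs=1e-6)

    def test_field_extremes_within_input_range(self, a1):
        rng = np.random.default_rng(41)
        for _ in range(3):
            temps = rng.uniform(15, 75, 7)
            recs = _section_records(a1, 17.5, 0, 18, 2)
            recs = [
                MeasurementRecord(r.pile_id, r.day, r.distance_m, r.side, r.level,
                                  float(t), r.o2_pct, r.co2_pct, r.co_ppm)
                for r, t in zip(recs, temps)
            ]
            grid = cross_section_field(recs, a1, "temp_C", self.AMBIENT, cell_size_m=0.25)
            vals = grid.values[grid.mask]
            lo = min(temps.min(), self.AMBIENT.temp_C)
            hi = max(temps.max(), self.AMBIENT.temp_C)
            assert vals.min() >= lo - 1e-6 and vals.max() <= hi + 1e-6

    def test_no_interior_records_skips_with_warning(self, a1, caplog):
        with caplog.at_level(logging.WARNING):
            grid = cross_section_field([], a1, "temp_C", self.AMBIENT)
        assert grid is None
        assert any("skipped" in r.message for r in caplog.records)

    def test_longitudinal_constant_and_exactness(self, a1):
        recs = []
        for d in (2.5, 17.5, 32.5, 47.5):
            for level in ("H1", "H2", "H3"):
                recs.append(MeasurementRecord("A1", 22, d, "left", level, 20.0, 20.9, 0.04, 0.0))
        grid = longitudinal_field(recs, a1, "left", "temp_C", self.AMBIENT, cell_size_m=0.5)
        assert np.allclose(grid.values, 20.0, atol=1e-6)

    def test_longitudinal_reproduces_probe_values(self, a1):
        temps = {2.5: 30.0, 17.5: 45.0, 32.5: 55.0, 47.5: 65.0}
        recs = [MeasurementRecord("A1", 22, d, "left", "H2", t, 15.0, 4.0, 0.0)
                for d, t in temps.items()]
        grid = longitudinal_field(recs, a1, "left", "temp_C", self.AMBIENT, cell_size_m=0.1)
        # the interpolant is exact at probe positions; the nearest grid node
        # is within half a cell, so the node value tracks the probe closely
        for d, t in temps.items():
            col, row = int(d / 0.1), int(a1.probing_heights_m[1] / 0.1)
            assert grid.values[row, col] == pytest.approx(t, abs=1.0)

    def test_longitudinal_single_distance_raises(self, a1):
        recs = [MeasurementRecord("A1", 22, 17.5, "left", "H2", 40.0, 15.0, 4.0, 0.0)]
        with pytest.raises(ValueError, match="2 distances"):
            longitudinal_field(recs, a1, "left", "temp_C", self.AMBIENT)

    def test_gas_fields_clamped_to_physical_bounds(self, a1):
        # steep gradients make the RBF overshoot below 0
        recs = [MeasurementRecord("A1", 22, d, "left", lv, 40.0,
                                  0.2 if d < 20 else 20.7, 1.0, 0.0)
                for d in (2.5, 17.5, 32.5, 47.5) for lv in ("H1", "H2", "H3")]
        grid = longitudinal_field(recs, a1, "left", "o2_pct", self.AMBIENT, cell_size_m=0.5)
        assert grid.values.min() >= 0.0 and grid.values.max() <= 21.0
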