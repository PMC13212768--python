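"""Feature tensor, nearest-neighbor WSS mapping, normalization and the
hybrid vessel graph."""

import numpy as np
import pytest

from stenoshear.encoding import (
    DEFAULT_MAX_SPATIAL_DEGREE,
    WSSNormalizer,
    build_feature_tensor,
    build_graph,
    crop_slice,
    crop_wss_field,
    edge_weight,
    grid_edge_list,
    map_wss_to_grid,
)
from stenoshear.errors import DegenerateStatisticsError, ValidationError
from stenoshear.geometry import resample_centerline, template_centerline
from stenoshear.oracle import oracle_wss_field, FlowParams
from stenoshear.stenosis import apply_stenosis, build_surface


@pytest.fixture(scope="module")
def straight_lattice():
    cl = resample_centerline(template_centerline("straight"), 640, 80.0)
    return build_surface(cl, apply_stenosis(cl, []), 40)


class TestFeatureTensor:
    def test_flattened_feature_count(self, concentric_lattice):
        lat, _ = concentric_lattice
        tensor = build_feature_tensor(lat)
        assert tensor.grid.shape == (560, 40, 8)
        assert tensor.n_features_flat == 179_200

    def test_crop_span(self, concentric_lattice):
        lat, _ = concentric_lattice
        tensor = build_feature_tensor(lat)
        assert tensor.n_axial == 560
        assert tensor.station_s[0] == pytest.approx(5.0, abs=0.01)
        assert tensor.station_s[-1] < 75.01

    def test_angle_channel_values(self, concentric_lattice):
        lat, _ = concentric_lattice
        tensor = build_feature_tensor(lat)
        expected = 2 * np.pi * np.arange(40) / 40
        assert np.array_equal(tensor.grid[0, :, 4], expected)
        assert tensor.grid[0, 0, 4] == 0.0
        assert tensor.grid[0, 20, 4] == pytest.approx(np.pi)

    def test_straight_tube_curvature_and_offset_zero(self, straight_lattice):
        tensor = build_feature_tensor(straight_lattice)
        assert np.allclose(tensor.grid[:, :, 3], 0.0, atol=1e-9)
        assert np.allclose(tensor.grid[:, :, 5], 0.0)
        assert np.allclose(tensor.grid[:, :, 6], 1.5)

    def test_per_station_channels_constant(self, concentric_lattice):
        lat, _ = concentric_lattice
        tensor = build_feature_tensor(lat)
        for ch in (5, 6, 7):
            assert np.all(tensor.grid[:, :, ch] ==
                          tensor.grid[:, [0], ch])


class TestCrop:
    @pytest.mark.parametrize("n_axial,expected", [(640, 560), (160, 140),
                                                  (32, 28)])
    def test_kept_station_counts(self, n_axial, expected):
        sl = crop_slice(n_axial)
        assert sl.stop - sl.start == expected


class TestMapWSS:
    def test_identity_when_samples_coincide(self, straight_lattice):
        keep = crop_slice(640)
        xyz = straight_lattice.node_xyz[keep]
        field = oracle_wss_field(straight_lattice,
                                 FlowParams(newtonian_mu=0.0035))
        vals = field.values[keep]
        mapped = map_wss_to_grid(xyz.reshape(-1, 3), vals.ravel(), xyz)
        assert np.array_equal(mapped.values, vals)
        assert mapped.values.size == 22_400

    def test_tie_breaks_to_lowest_index(self):
        # two sample points equidistant from every grid node on their
        # bisector plane; brute-force scan fixes the expectation
        grid = np.zeros((1, 3, 3))
        grid[0, :, 0] = [0.0, 1.0, 2.0]
        lattice_xyz = grid.transpose(1, 0, 2).reshape(1, 3, 3)
        samples = np.array([[1.0, 1.0, 0.0], [1.0, -1.0, 0.0]])
        wss = np.array([10.0, 20.0])
        mapped = map_wss_to_grid(samples, wss, lattice_xyz)
        dists = np.linalg.norm(
            lattice_xyz.reshape(-1, 3)[:, None] - samples[None], axis=2
        )
        expected = np.where(dists[:, 0] <= dists[:, 1], 10.0, 20.0)
        assert np.array_equal(mapped.values.ravel(), expected)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValidationError):
            map_wss_to_grid(np.empty((0, 3)), np.empty(0), np.zeros((2, 2, 3)))

    def test_scattered_matches_bruteforce(self, rng):
        lattice_xyz = rng.normal(size=(6, 5, 3))
        samples = rng.normal(size=(40, 3))
        wss = rng.uniform(1, 10, size=40)
        mapped = map_wss_to_grid(samples, wss, lattice_xyz)
        nodes = lattice_xyz.reshape(-1, 3)
        d = np.linalg.norm(nodes[:, None] - samples[None], axis=2)
        assert np.array_equal(mapped.values.ravel(), wss[d.argmin(axis=1)])


class TestNormalizer:
    def test_roundtrip_identity(self, rng):
        train = rng.uniform(0.1, 50.0, size=(4, 10, 10))
        norm = WSSNormalizer.fit(train)
        x = rng.uniform(0.0, 80.0, size=(10, 10))
        back = norm.inverse(norm.transform(x))
        assert np.allclose(back, x, rtol=1e-9, atol=1e-9)

    def test_training_set_standardized(self, rng):
        train = rng.uniform(0.1, 50.0, size=(6, 20))
        norm = WSSNormalizer.fit(train)
        z = norm.transform(train)
        assert abs(z.mean()) < 1e-6
        assert abs(z.var() - 1.0) < 1e-6

    def test_zero_wss_finite(self):
        norm = WSSNormalizer.fit(np.array([[0.5, 1.0, 2.0]]))
        assert np.isfinite(norm.transform(np.array([0.0]))).all()

    def test_constant_targets_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            WSSNormalizer.fit(np.full((3, 5), 2.0))


class TestGraph:
    def test_grid_degrees(self):
        edges = grid_edge_list(10, 40)
        deg = np.zeros(400, int)
        np.add.at(deg, edges.ravel(), 1)
        interior = deg.reshape(10, 40)[1:-1]
        ends = deg.reshape(10, 40)[[0, -1]]
        assert np.all(interior == 8)
        assert np.all(ends == 5)

    def test_edge_weight_reference_values(self):
        assert edge_weight(0.0) == 1.0
        assert edge_weight(0.1) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_weight_monotone_decreasing(self):
        d = np.linspace(0, 1, 50)
        w = np.array([edge_weight(x) for x in d])
        assert np.all(np.diff(w) < 0)
        assert np.all((w > 0) & (w <= 1))

    def test_graph_symmetry_and_weights(self, rng):
        # small curved lattice with spatial edges
        from stenoshear.cohort import generate_case
        from stenoshear.cohort import DESK_PRESET

        sample = generate_case(7, DESK_PRESET)
        g = sample.graph
        adj = g.adjacency()
        assert (adj != adj.T).nnz == 0
        if len(g.spatial_edges):
            d = np.linalg.norm(
                g.node_xyz[g.spatial_edges[:, 0]]
                - g.node_xyz[g.spatial_edges[:, 1]], axis=1)
            w = g.edge_weights[len(g.grid_edges):]
            assert np.allclose(w, np.exp(-d / g.length_scale_mm), atol=1e-12)
        assert np.all(g.edge_weights > 0) and np.all(g.edge_weights <= 1)

    def test_spatial_edges_match_bruteforce(self, rng):
        # lattice small enough for an O(N^2) scan
        pts = rng.normal(size=(10, 8, 3)) * 0.4
        g = build_graph(pts, spatial_radius_mm=0.3,
                        max_spatial_degree=10_000)
        nodes = pts.reshape(-1, 3)
        n = len(nodes)
        grid = set(map(tuple, grid_edge_list(10, 8)))
        expected = {
            (i, j)
            for i in range(n) for j in range(i + 1, n)
            if np.linalg.norm(nodes[i] - nodes[j]) <= 0.3
            and (i, j) not in grid
        }
        got = set(map(tuple, g.spatial_edges))
        assert got == expected

    def test_spatial_degree_cap(self):
        pts = np.random.default_rng(3).normal(size=(6, 6, 3)) * 0.1
        g = build_graph(pts, spatial_radius_mm=1.0, max_spatial_degree=6)
        deg = np.zeros(36, int)
        np.add.at(deg, g.spatial_edges.ravel(), 1)
        assert deg.max() <= 6

    def test_invalid_radius(self):
        with pytest.raises(ValidationError):
            build_graph(np.zeros((4, 4, 3)), spatial_radius_mm=0.0)
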