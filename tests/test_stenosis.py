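"""Lesion specs, cross-section blending, surface lattice and mesh export."""

import numpy as np
import pytest

from stenoshear.errors import LesionOverlapError, ValidationError
from stenoshear.geometry import resample_centerline, template_centerline
from stenoshear.stenosis import (
    SEVERITY_AR,
    apply_stenosis,
    build_surface,
    export_geometry,
    lattice_faces,
    make_stenosis_spec,
    read_node_csv,
)

A0 = np.pi * 1.5**2


class TestSpec:
    def test_reference_throat_diameter(self):
        # AR = 16% with D0 = 3 mm gives a 1.2 mm post-stenotic diameter
        spec = make_stenosis_spec("concentric_round", 0.16, 40.0)
        assert 2 * spec.semi_major_mm == pytest.approx(1.2, abs=1e-12)
        assert spec.semi_major_mm == spec.semi_minor_mm

    def test_concentric_offset_forced_to_zero(self):
        spec = make_stenosis_spec("concentric_oval", 0.3, 30.0,
                                  eccentric_distance_mm=0.4, seed=0)
        assert spec.eccentric_distance_mm == 0.0

    def test_oval_area_identity(self):
        spec = make_stenosis_spec("eccentric_oval", 0.1, 30.0, seed=7)
        ar = np.pi * spec.semi_major_mm * spec.semi_minor_mm / A0
        assert ar == pytest.approx(0.1, rel=1e-12)
        assert spec.semi_major_mm > spec.semi_minor_mm > 0

    def test_severity_presets(self):
        assert SEVERITY_AR == {"mild": 0.50, "moderate": 0.30, "severe": 0.10}

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(area_ratio=0.05), "area_ratio"),
        (dict(area_ratio=0.95), "area_ratio"),
        (dict(area_ratio=0.3, position_mm=5.0), "position"),
        (dict(area_ratio=0.3, position_mm=75.0), "position"),
    ])
    def test_range_violations_named(self, kwargs, msg):
        with pytest.raises(ValidationError, match=msg):
            make_stenosis_spec("concentric_round", **kwargs)

    def test_eccentric_distance_cap(self):
        with pytest.raises(ValidationError, match="eccentric"):
            make_stenosis_spec("eccentric_round", 0.3, 30.0,
                               eccentric_distance_mm=0.9)

    def test_random_draws_deterministic(self):
        a = make_stenosis_spec("eccentric_oval", seed=11)
        b = make_stenosis_spec("eccentric_oval", seed=11)
        assert a == b


class TestProfile:
    def test_no_lesion_all_nominal(self, straight_cl):
        prof = apply_stenosis(straight_cl, [])
        assert np.allclose(prof.semi_major, 1.5)
        assert np.allclose(prof.semi_minor, 1.5)
        assert np.allclose(prof.center_offset, 0.0)

    def test_station_aligned_throat_area_exact(self, straight_cl,
                                               throat_station):
        pos = float(straight_cl.arc_coord[throat_station])
        spec = make_stenosis_spec("concentric_round", 0.16, pos)
        prof = apply_stenosis(straight_cl, [spec])
        assert prof.area.min() / A0 == pytest.approx(0.16, abs=1e-6)

    @pytest.mark.parametrize("ar", [0.1, 0.33, 0.9])
    @pytest.mark.parametrize("morph", ["concentric_round", "eccentric_oval"])
    def test_area_ratio_exactness_any_morphology(self, straight_cl,
                                                 throat_station, ar, morph):
        pos = float(straight_cl.arc_coord[throat_station])
        spec = make_stenosis_spec(morph, ar, pos, seed=3)
        prof = apply_stenosis(straight_cl, [spec])
        assert prof.area.min() / A0 == pytest.approx(ar, abs=1e-6)

    def test_eccentric_throat_centroid_offset(self, straight_cl,
                                              throat_station):
        pos = float(straight_cl.arc_coord[throat_station])
        spec = make_stenosis_spec("eccentric_round", 0.3, pos,
                                  eccentric_distance_mm=0.6,
                                  orientation_rad=1.0)
        prof = apply_stenosis(straight_cl, [spec])
        ring = prof.boundary_points(throat_station, 400)
        centroid = ring.mean(axis=0)
        assert np.linalg.norm(centroid) == pytest.approx(0.6, abs=1e-6)

    def test_overlapping_lesions_rejected(self, straight_cl):
        s1 = make_stenosis_spec("concentric_round", 0.3, 40.0)
        s2 = make_stenosis_spec("concentric_round", 0.5, 44.0)
        with pytest.raises(LesionOverlapError):
            apply_stenosis(straight_cl, [s1, s2])

    def test_dual_lesions_separated_ok(self, straight_cl):
        s1 = make_stenosis_spec("concentric_round", 0.3, 25.0)
        s2 = make_stenosis_spec("eccentric_oval", 0.5, 55.0, seed=0)
        prof = apply_stenosis(straight_cl, [s1, s2])
        assert len(prof.specs) == 2


class TestSurface:
    def test_straight_tube_node_distances(self, straight_cl):
        prof = apply_stenosis(straight_cl, [])
        lat = build_surface(straight_cl, prof, 40)
        dist = np.linalg.norm(lat.node_xyz - lat.centers[:, None, :], axis=2)
        assert np.allclose(dist, 1.5, atol=1e-9)

    def test_lattice_dimensions(self, concentric_lattice):
        lat, _ = concentric_lattice
        assert (lat.n_axial, lat.n_theta) == (640, 40)

    def test_throat_polygon_area_within_discretization(self,
                                                       concentric_lattice,
                                                       throat_station):
        lat, spec = concentric_lattice
        area = lat.ring_polygon_area(throat_station)
        assert area == pytest.approx(spec.area_ratio * A0, rel=5e-3)

    def test_nominal_polygon_area(self, concentric_lattice):
        lat, _ = concentric_lattice
        assert lat.ring_polygon_area(10) == pytest.approx(A0, rel=5e-3)

    def test_circumferential_wrap_adjacency(self, concentric_lattice):
        lat, _ = concentric_lattice
        # node (i, n_theta-1) is adjacent to (i, 0): their distance matches
        # the typical in-ring neighbor spacing
        ring = lat.node_xyz[100]
        gap_wrap = np.linalg.norm(ring[-1] - ring[0])
        gap_inner = np.linalg.norm(ring[1] - ring[0])
        assert gap_wrap == pytest.approx(gap_inner, rel=1e-9)

    def test_platform_independent_determinism(self, straight_cl):
        prof = apply_stenosis(
            straight_cl, [make_stenosis_spec("eccentric_oval", 0.2, 30.0,
                                             seed=5)]
        )
        a = build_surface(straight_cl, prof, 40)
        b = build_surface(straight_cl, prof, 40)
        assert np.array_equal(a.node_xyz, b.node_xyz)


class TestExport:
    def test_stl_triangle_count_and_manifold(self, tmp_path,
                                             concentric_lattice,
                                             straight_cl):
        import trimesh

        lat, _ = concentric_lattice
        stl = tmp_path / "wall.stl"
        export_geometry(lat, straight_cl, stl_path=stl)
        mesh = trimesh.load(str(stl))
        assert len(mesh.faces) == 2 * 639 * 40
        # edge audit: every interior edge shared by exactly 2 triangles;
        # boundary edges (open ends) by exactly 1
        faces = lattice_faces(lat.n_axial, lat.n_theta)
        edges = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                                        faces[:, [2, 0]]]), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        assert set(counts) <= {1, 2}
        assert (counts == 1).sum() == 2 * lat.n_theta  # the two open rims

    def test_capped_mesh_is_watertight(self, tmp_path, concentric_lattice,
                                       straight_cl):
        lat, _ = concentric_lattice
        mesh = export_geometry(lat, straight_cl, cap_ends=True)
        assert mesh.is_watertight

    def test_node_csv_roundtrip_bitwise(self, tmp_path, concentric_lattice,
                                        straight_cl):
        lat, _ = concentric_lattice
        path = tmp_path / "nodes.csv"
        export_geometry(lat, straight_cl, csv_path=path)
        back = read_node_csv(path)
        assert np.array_equal(back, lat.node_xyz)
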