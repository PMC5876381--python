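"""Bladder radii model, fixed-bottom placement and pelvic meshing."""

import math

import numpy as np
import pytest

from eitbladder.geometry import (GeometryError, Mesh, MeshDensity, MeshingError,
                                 PelvisBoundary, RadiiModel,
                                 bladder_radii_from_volume, build_pelvis_mesh,
                                 fixed_bottom_z, place_bladder)

PAPER_VOLUMES = [40, 80, 120, 160, 200, 240, 280, 300, 320, 340, 360, 380, 400, 420]


class TestRadiiModel:
    def test_volume_identity(self, radii_model):
        a, b, c = bladder_radii_from_volume(240.0, radii_model)
        vol = 4.0 / 3.0 * math.pi * a * b * c / 1000.0
        assert vol == pytest.approx(240.0, rel=0.01)

    @pytest.mark.parametrize("volume", PAPER_VOLUMES)
    def test_inversion_over_study_volumes(self, radii_model, volume):
        a, b, c = bladder_radii_from_volume(float(volume), radii_model)
        assert 4.0 / 3.0 * math.pi * a * b * c / 1000.0 == pytest.approx(volume, rel=0.01)

    def test_monotone_and_continuous_on_1ml_grid(self, radii_model):
        grid = np.arange(40.0, 421.0, 1.0)
        radii = np.array([bladder_radii_from_volume(v, radii_model) for v in grid])
        assert np.all(np.diff(radii, axis=0) > 0)
        # continuity: 1 ml steps never jump more than 1 mm
        assert np.max(np.abs(np.diff(radii, axis=0))) < 1.0

    def test_extremes_strictly_ordered(self, radii_model):
        r40 = bladder_radii_from_volume(40.0, radii_model)
        r420 = bladder_radii_from_volume(420.0, radii_model)
        assert all(lo < hi for lo, hi in zip(r40, r420))

    @pytest.mark.parametrize("volume", [-10.0, 0.0, 5.0, 1000.0])
    def test_out_of_range_volume_rejected(self, radii_model, volume):
        with pytest.raises(GeometryError):
            bladder_radii_from_volume(volume, radii_model)

    def test_custom_strategy_is_pluggable(self):
        model = RadiiModel(custom=lambda v: (30.0, 20.0, 10.0))
        assert bladder_radii_from_volume(100.0, model) == (30.0, 20.0, 10.0)


class TestPlacement:
    def test_reference_volume_sits_on_fixed_bottom(self, radii_model, male_pelvis):
        bl = place_bladder(bladder_radii_from_volume(240.0, radii_model),
                           male_pelvis, radii_model)
        assert bl.bottom_z == pytest.approx(fixed_bottom_z(radii_model), abs=1e-9)
        # by construction the 240 ml centre is at the domain centroid height
        assert bl.center[2] == pytest.approx(0.0, abs=1e-9)

    def test_ascension_tops_rise_bottoms_fixed(self, radii_model, male_pelvis):
        tops, bottoms = [], []
        for v in PAPER_VOLUMES:
            bl = place_bladder(bladder_radii_from_volume(float(v), radii_model),
                               male_pelvis, radii_model)
            tops.append(bl.top_z)
            bottoms.append(bl.bottom_z)
        assert np.all(np.diff(tops) > 0)
        assert np.allclose(bottoms, fixed_bottom_z(radii_model))

    def test_anterior_halfway_placement(self, radii_model, male_pelvis):
        bl = place_bladder(bladder_radii_from_volume(100.0, radii_model),
                           male_pelvis, radii_model)
        assert bl.center[1] == pytest.approx(male_pelvis.ap_semiaxis_scaled / 2)

    def test_degenerate_bladder_center_is_bottom(self, male_pelvis, radii_model):
        bl = place_bladder((0.0, 0.0, 0.0), male_pelvis, radii_model)
        assert bl.center[2] == pytest.approx(fixed_bottom_z(radii_model))

    def test_oversized_bladder_reports_volume(self, radii_model):
        small = PelvisBoundary(lateral_semiaxis=60.0, ap_semiaxis=50.0, height=120.0)
        with pytest.raises(GeometryError, match="420"):
            place_bladder(bladder_radii_from_volume(420.0, radii_model), small,
                          radii_model, volume_ml=420.0)


class TestBoundary:
    def test_ap_scaling(self):
        b = PelvisBoundary.standard("male", ap_scale=1.1)
        assert b.ap_semiaxis_scaled == pytest.approx(110.0 * 1.1)

    @pytest.mark.parametrize("bad", [0.7, 1.3])
    def test_ap_scale_range_enforced(self, bad):
        with pytest.raises(GeometryError):
            PelvisBoundary.standard("male", ap_scale=bad)


class TestMesh2D:
    def test_partition_and_conformity(self, mesh240):
        assert set(np.unique(mesh240.element_tags)) <= {0, 1}
        assert len(mesh240.element_tags) == len(mesh240.elements)
        # no orphan nodes
        used = np.unique(mesh240.elements)
        assert len(used) == len(mesh240.nodes)

    def test_electrode_ring(self, mesh240, male_pelvis):
        assert mesh240.n_electrodes == 32
        centers = np.array([mesh240.nodes[g[0]] for g in mesh240.electrode_nodes])
        ang = np.arctan2(centers[:, 1] / male_pelvis.ap_semiaxis_scaled,
                         centers[:, 0] / male_pelvis.lateral_semiaxis)
        # electrode 0 on the anterior midline, counter-clockwise order
        assert ang[0] == pytest.approx(math.pi / 2)
        steps = np.diff(np.unwrap(ang))
        assert np.allclose(steps, 2 * math.pi / 32, atol=1e-6)

    def test_inclusion_area_matches_slice(self, mesh240, bladder240):
        _, _, bx, by = bladder240.slice_at(0.0)
        assert mesh240.region_measure(1) == pytest.approx(math.pi * bx * by, rel=0.05)

    def test_total_area_scales_with_ap(self, radii_model):
        meshes = {}
        for scale in (1.0, 1.1):
            pel = PelvisBoundary.standard("male", ap_scale=scale)
            bl = place_bladder(bladder_radii_from_volume(240.0, radii_model),
                               pel, radii_model)
            m = build_pelvis_mesh(pel, bl)
            meshes[scale] = m.region_measure(0) + m.region_measure(1)
        assert meshes[1.1] / meshes[1.0] == pytest.approx(1.1, rel=0.01)

    def test_background_only_mesh(self, male_pelvis):
        mesh = build_pelvis_mesh(male_pelvis, None)
        assert np.all(mesh.element_tags == 0)

    def test_refinement_converges_inclusion_area(self, male_pelvis, bladder240):
        areas = [build_pelvis_mesh(male_pelvis, bladder240,
                                   MeshDensity(scale=s)).region_measure(1)
                 for s in (1.0, 0.5)]
        assert abs(areas[1] / areas[0] - 1.0) < 0.02

    def test_msh_export_roundtrippable_text(self, mesh240, tmp_path):
        path = tmp_path / "mesh.msh"
        mesh240.to_msh(path)
        text = path.read_text()
        assert text.startswith("$MeshFormat")
        assert f"{len(mesh240.nodes)}" in text


class TestMesh3D:
    @pytest.fixture(scope="class")
    def mesh3d(self, male_pelvis, bladder240):
        return build_pelvis_mesh(male_pelvis, bladder240, domain="3d")

    def test_tagged_volume_matches_bladder(self, mesh3d):
        assert mesh3d.bladder_volume_ml() == pytest.approx(240.0, rel=0.05)

    def test_total_volume_matches_cylinder(self, mesh3d, male_pelvis):
        total = (mesh3d.region_measure(0) + mesh3d.region_measure(1)) / 1000.0
        cyl = (math.pi * male_pelvis.lateral_semiaxis
               * male_pelvis.ap_semiaxis_scaled * male_pelvis.height) / 1000.0
        assert total == pytest.approx(cyl, rel=0.005)

    def test_conforming_faces(self, mesh3d):
        # every interior triangle must be shared by exactly two tets
        faces = {}
        for tet in mesh3d.elements[:4000]:
            for drop in range(4):
                f = tuple(sorted(np.delete(tet, drop)))
                faces[f] = faces.get(f, 0) + 1
        assert max(faces.values()) <= 2

    def test_electrode_ring_at_midplane(self, mesh3d):
        assert mesh3d.n_electrodes == 32
        z = np.array([mesh3d.nodes[g[0], 2] for g in mesh3d.electrode_nodes])
        assert np.allclose(z, 0.0)


def test_too_coarse_mesh_raises(male_pelvis, radii_model):
    tiny = place_bladder(bladder_radii_from_volume(40.0, radii_model),
                         male_pelvis, radii_model, volume_ml=40.0)
    with pytest.raises(MeshingError):
        build_pelvis_mesh(male_pelvis, tiny, MeshDensity(scale=12.0))
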