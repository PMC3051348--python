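"""Phantom geometry, analytic volumes, pixel sizes and voxelization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctvolumetry import (
    CONTAINER_MM,
    DEFAULT_DIAMETERS_MM,
    PhantomSpec,
    PlacementError,
    SphereSpec,
    build_phantom_spec,
    pixel_size,
    sphere_true_volume,
    voxelize,
)


class TestSphereTrueVolume:
    @pytest.mark.parametrize(
        "diameter, expected, sig",
        [
            (3.175, 16.8, 3),    # 1/8 in
            (6.35, 134.0, 3),    # 1/4 in
            (25.4, 8580.0, 3),   # 1 in
            (0.0, 0.0, 1),
        ],
    )
    def test_analytic_values(self, diameter, expected, sig):
        v = sphere_true_volume(diameter)
        if expected == 0:
            assert v == 0
        else:
            # agreement to the quoted significant figures
            assert v == pytest.approx(expected, rel=10 ** (1 - sig) / 2)

    def test_matches_formula(self):
        d = 7.25
        assert sphere_true_volume(d) == pytest.approx(
            4 / 3 * math.pi * (d / 2) ** 3)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            sphere_true_volume(-1.0)


class TestPixelSize:
    @pytest.mark.parametrize(
        "fov_cm, matrix, expected",
        [(20, 512, 0.391), (30, 512, 0.586), (40, 512, 0.781),
         (51.2, 512, 1.0)],
    )
    def test_reconstructed_pixel_sizes(self, fov_cm, matrix, expected):
        assert pixel_size(fov_cm, matrix) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("fov_cm, matrix", [(0, 512), (-1, 512), (20, 0)])
    def test_invalid_inputs(self, fov_cm, matrix):
        with pytest.raises(ValueError):
            pixel_size(fov_cm, matrix)


class TestBuildPhantomSpec:
    def test_default_layout_has_55_spheres(self):
        spec = build_phantom_spec(0)
        assert len(spec.spheres) == 55
        assert spec.n_sizes == 11
        assert spec.n_replicates == 5
        # every replicate layer holds one sphere of each diameter
        per_diameter = {}
        for s in spec.spheres:
            per_diameter[s.diameter] = per_diameter.get(s.diameter, 0) + 1
        assert set(per_diameter.values()) == {5}
        assert sorted(per_diameter) == sorted(DEFAULT_DIAMETERS_MM)

    def test_diameter_series_spans_paper_range(self):
        assert min(DEFAULT_DIAMETERS_MM) == pytest.approx(1.5875)
        assert max(DEFAULT_DIAMETERS_MM) == pytest.approx(25.4)

    def test_deterministic_for_fixed_seed(self):
        a = build_phantom_spec(7)
        b = build_phantom_spec(7)
        assert [s.center for s in a.spheres] == [s.center for s in b.spheres]

    def test_seeds_change_centers_not_diameters(self):
        a = build_phantom_spec(1)
        b = build_phantom_spec(2)
        assert sorted(s.diameter for s in a.spheres) == sorted(
            s.diameter for s in b.spheres)
        assert [s.center for s in a.spheres] != [s.center for s in b.spheres]

    def test_layers_differ_within_one_phantom(self):
        spec = build_phantom_spec(3)
        by_layer = {}
        for s in spec.spheres:
            rep = s.id.split("-")[0]
            by_layer.setdefault(rep, []).append(s.center[:2])
        layouts = list(by_layer.values())
        assert all(layouts[0] != other for other in layouts[1:])

    def test_degenerate_single_sphere_centered(self):
        spec = build_phantom_spec(0, diameters=[10.0], n_replicates=1,
                                  container=(50.0, 50.0, 50.0))
        assert len(spec.spheres) == 1
        assert spec.spheres[0].center == (25.0, 25.0, 25.0)

    def test_container_too_small_raises(self):
        with pytest.raises(PlacementError):
            build_phantom_spec(0, diameters=[30.0, 28.0], n_replicates=1,
                               container=(40.0, 40.0, 40.0))

    def test_overlapping_spec_rejected(self):
        s1 = SphereSpec("a", 10.0, (20.0, 20.0, 20.0), 118.2)
        s2 = SphereSpec("b", 10.0, (25.0, 20.0, 20.0), 118.2)
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(spheres=[s1, s2], container_dims=(60.0, 60.0, 60.0))

    def test_sphere_outside_container_rejected(self):
        s = SphereSpec("a", 10.0, (2.0, 30.0, 30.0), 118.2)
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec(spheres=[s], container_dims=(60.0, 60.0, 60.0))

    def test_manifest_round_trip(self, tmp_path):
        spec = build_phantom_spec(5, diameters=[6.35, 12.7], n_replicates=2,
                                  container=(80.0, 80.0, 120.0))
        path = tmp_path / "phantom.json"
        spec.to_json(path)
        back = PhantomSpec.from_json(path)
        assert [s.center for s in back.spheres] == [
            s.center for s in spec.spheres]
        assert back.background_hu == spec.background_hu


class TestVoxelize:
    def test_empty_phantom_uniform_background(self):
        spec = PhantomSpec(spheres=[], background_hu=37.6,
                           container_dims=(20.0, 20.0, 10.0))
        vol = voxelize(spec, 1.0, 1.0, supersample=2)
        assert np.all(vol.data == np.float32(37.6))

    def test_deep_interior_voxel_exact_sphere_hu(self):
        spec = build_phantom_spec(0, diameters=[12.0], n_replicates=1,
                                  container=(40.0, 40.0, 40.0))
        vol = voxelize(spec, 1.0, 1.0, supersample=4)
        zc, yc, xc = vol.voxel_centers()
        center = spec.spheres[0].center
        iz = np.argmin(np.abs(zc - center[2]))
        iy = np.argmin(np.abs(yc - center[1]))
        ix = np.argmin(np.abs(xc - center[0]))
        assert vol.data[iz, iy, ix] == np.float32(118.2)

    def test_partial_volume_mass_conservation(self):
        # occupancy-weighted volume within 1% of (4/3)pi r^3 at 0.2 mm
        spec = build_phantom_spec(0, diameters=[25.4], n_replicates=1,
                                  container=(32.0, 32.0, 32.0))
        vol = voxelize(spec, 0.2, 0.2, supersample=8)
        occ = (vol.data - 37.6) / (118.2 - 37.6)
        measured = float(occ.sum(dtype=np.float64)) * vol.voxel_volume
        assert measured == pytest.approx(sphere_true_volume(25.4), rel=0.01)

    def test_hu_bounded_by_materials(self):
        spec = build_phantom_spec(2, diameters=[4.0, 8.0], n_replicates=2,
                                  container=(50.0, 50.0, 60.0))
        vol = voxelize(spec, 0.8, 0.6, supersample=4)
        assert vol.data.min() >= np.float32(37.6)
        assert vol.data.max() <= np.float32(118.2)

    def test_reflection_symmetry(self):
        # mirroring sphere centers about the grid center mirrors the grid
        container = (24.0, 24.0, 24.0)
        s = SphereSpec("a", 9.0, (8.25, 10.5, 13.75), 118.2)
        mirrored = SphereSpec(
            "a", 9.0, tuple(c - v for c, v in zip(container, s.center)), 118.2)
        va = voxelize(PhantomSpec([s], container_dims=container), 1.0, 1.0,
                      supersample=4)
        vb = voxelize(PhantomSpec([mirrored], container_dims=container), 1.0,
                      1.0, supersample=4)
        np.testing.assert_allclose(va.data, vb.data[::-1, ::-1, ::-1],
                                   atol=1e-4)

    def test_matrix_grid_centered_on_container(self):
        spec = build_phantom_spec(0, diameters=[10.0], n_replicates=1,
                                  container=(50.0, 50.0, 50.0))
        vol = voxelize(spec, 1.0, 1.0, supersample=2, matrix=100)
        assert vol.shape == (50, 100, 100)
        # grid extends 25 mm beyond the container on each xy side
        assert vol.origin[0] == pytest.approx(-25.0)
        # the sphere is rendered identically regardless of the border
        hugged = voxelize(spec, 1.0, 1.0, supersample=2)
        occ_m = float((vol.data - 37.6).sum(dtype=np.float64))
        occ_h = float((hugged.data - 37.6).sum(dtype=np.float64))
        assert occ_m == pytest.approx(occ_h, rel=1e-6)

    @given(st.integers(min_value=1, max_value=4))
    @settings(max_examples=4, deadline=None)
    def test_supersample_refines_toward_analytic(self, ss):
        spec = build_phantom_spec(0, diameters=[10.0], n_replicates=1,
                                  container=(20.0, 20.0, 20.0))
        vol = voxelize(spec, 0.5, 0.5, supersample=2 * ss)
        occ = (vol.data - 37.6) / (118.2 - 37.6)
        measured = float(occ.sum(dtype=np.float64)) * vol.voxel_volume
        assert measured == pytest.approx(sphere_true_volume(10.0), rel=0.03)

    def test_invalid_supersample(self):
        spec = PhantomSpec(spheres=[], container_dims=(10.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            voxelize(spec, 1.0, 1.0, supersample=0)
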