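"""Parametric geometry: volume calibration, voxelization, region labels."""

import numpy as np
import pytest

from gastroflow import (
    GeometryParams,
    build_gut_geometry,
    label_regions,
    make_tube_fixture,
    voxelize,
)
from gastroflow.geometry import (
    GeometryError,
    ResolutionError,
    VolumeCalibrationError,
)


class TestBuildGutGeometry:
    def test_stomach_volume_within_5pct_of_target(self, geom):
        assert 617.5 <= geom.stomach_volume_analytic() <= 682.5

    def test_voxelized_volume_within_5pct(self, geom):
        grid = voxelize(geom, 1.5)
        assert abs(grid.stomach_volume - 650.0) / 650.0 <= 0.05

    def test_pyloric_radius_open(self, geom):
        assert geom.r0(0.0) == pytest.approx(4.5, abs=1e-6)

    def test_volume_calibration_failure_names_achieved_volume(self):
        with pytest.raises(VolumeCalibrationError, match="ml"):
            build_gut_geometry(GeometryParams(stomach_volume_target=6500.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(GeometryError):
            GeometryParams(antral_diameter_D=-1.0)
        with pytest.raises(GeometryError):
            GeometryParams(radius_knots=((0.0, 4.5), (0.0, 5.0)))

    def test_degenerate_cylinder_volume(self):
        # a plain cylinder voxelizes to its analytic volume within 2%
        cyl = make_tube_fixture(25.0, 100.0, 3)
        grid = voxelize(cyl, 1.5)
        v_ref = np.pi * 25.0**2 * 100.0 / 1000.0
        assert abs(grid.lumen_volume - v_ref) / v_ref <= 0.02


class TestTubeFixture:
    def test_volume_matches_analytic(self):
        tube = make_tube_fixture(4.5, 60.0, 3)
        grid = voxelize(tube, 0.5)
        v_ref = np.pi * 4.5**2 * 60.0 / 1000.0
        assert abs(grid.lumen_volume - v_ref) / v_ref <= 0.03

    def test_signed_distance_at_axis(self):
        tube = make_tube_fixture(4.5, 60.0, 3)
        sd = tube.signed_distance(np.array([[30.0, 0.0, 0.0]]))
        assert sd[0] == pytest.approx(-4.5, abs=1e-6)

    def test_planar_channel_halfwidth(self):
        chan = make_tube_fixture(25.0, 100.0, 2)
        grid = voxelize(chan, 1.0)
        assert grid.shape[1] == 1  # quasi-2-D slab
        # signed distance at mid-height is -halfwidth
        sd = chan.signed_distance(np.array([[50.0, 0.0, 0.0]]))
        assert sd[0] == pytest.approx(-25.0, abs=1e-6)

    def test_bad_arguments(self):
        with pytest.raises(GeometryError):
            make_tube_fixture(-1.0, 10.0)
        with pytest.raises(GeometryError):
            make_tube_fixture(1.0, 10.0, dimensionality=4)


class TestVoxelize:
    def test_refinement_convergence(self, geom):
        err = {}
        for sp in (3.0, 1.5):
            grid = voxelize(geom, sp, strict=False)
            err[sp] = abs(grid.stomach_volume - 650.0) / 650.0
        # error at 1.5 mm no worse than twice the 3 mm error (converging)
        assert err[1.5] <= max(2.0 * err[3.0], 0.01)

    def test_spacing_larger_than_lumen_rejected(self, geom):
        with pytest.raises(ResolutionError):
            voxelize(geom, 30.0)

    def test_strict_mode_requires_resolved_pylorus(self, geom):
        with pytest.raises(ResolutionError):
            voxelize(geom, 3.05, strict=True)
        with pytest.warns(UserWarning):
            voxelize(geom, 3.05, strict=False)

    def test_masks_partition_grid(self, grid3):
        total = grid3.lumen.sum() + grid3.wall.sum() + grid3.outside.sum()
        assert total == np.prod(grid3.shape)
        assert not (grid3.lumen & grid3.wall).any()


class TestRegionLabels:
    @pytest.mark.parametrize("n_regions", [1, 5, 13])
    def test_labels_partition_stomach(self, geom, grid3, n_regions):
        rl = label_regions(geom, grid3, n_regions)
        counts = rl.counts()
        assert counts.sum() == grid3.stomach.sum()
        assert (counts > 0).all()  # every region resolved and non-empty
        assert (rl.labels[~grid3.stomach] == 0).all()

    def test_single_region_is_whole_stomach(self, geom, grid3):
        rl = label_regions(geom, grid3, 1)
        assert set(np.unique(rl.labels[grid3.stomach])) == {1}

    def test_region_one_abuts_pylorus(self, geom, grid3):
        rl = label_regions(geom, grid3, 13)
        s_reg1 = grid3.s[rl.labels == 1]
        assert s_reg1.min() < geom.s_max / 13

    def test_too_many_regions_rejected(self, geom, grid3):
        with pytest.raises(ResolutionError):
            label_regions(geom, grid3, 10_000)
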