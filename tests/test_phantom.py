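"""Phantom generation: sampling, rasterization, shrinkage, satellites."""

import numpy as np
import pytest

from a0sim import (
    GeometryError,
    GridSpec,
    SimulationParams,
    add_satellite,
    apply_shrinkage,
    compute_mam,
    rasterize_case,
    sample_case,
)
from a0sim.phantom import CaseGeometry, Ellipsoid, min_grid_extent_mm

from conftest import sphere_mask


def sphere_volume(r):
    return 4.0 / 3.0 * np.pi * r**3


class TestSampleCase:
    def test_draws_stay_inside_configured_ranges(self, rng):
        p = SimulationParams()
        for _ in range(200):
            geom = sample_case(p, rng)
            assert 10.0 <= geom.d_tumor_mm <= 30.0
            assert -5.0 <= geom.margin_target_mm <= 10.0
            assert geom.shape_kind == "sphere"

    def test_degenerate_range_is_a_point_mass(self, rng):
        p = SimulationParams(tumor_range_mm=(20, 20), margin_range_mm=(5, 5))
        geom = sample_case(p, rng)
        assert geom.d_tumor_mm == 20.0
        assert geom.margin_target_mm == 5.0

    def test_empirical_means_match_uniform_laws(self):
        rng = np.random.default_rng(7)
        p = SimulationParams()
        draws = [sample_case(p, rng) for _ in range(10_000)]
        assert np.mean([g.d_tumor_mm for g in draws]) == pytest.approx(20.0, abs=0.3)
        assert np.mean([g.margin_target_mm for g in draws]) == pytest.approx(
            2.5, abs=0.2
        )

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ValueError):
            SimulationParams(tumor_range_mm=(30, 10))

    def test_ellipsoid_mode_draws_axis_ratios(self, rng):
        p = SimulationParams(shape_kind="ellipsoid")
        geom = sample_case(p, rng)
        assert geom.shape_kind == "ellipsoid"
        assert all(0.8 <= r <= 1.2 for r in geom.ellipsoid_axis_ratio)


class TestRasterizeCase:
    def test_voxel_counts_match_analytic_volumes(self):
        # odd shape puts a voxel centre at the sphere centre
        grid = GridSpec((41, 41, 41), (1.0, 1.0, 1.0))
        tumor, ablation = rasterize_case(CaseGeometry(10.0, 5.0), grid)
        assert tumor.volume_mm3 == pytest.approx(sphere_volume(5), rel=0.05)
        assert ablation.volume_mm3 == pytest.approx(sphere_volume(10), rel=0.05)

    def test_zero_margin_gives_identical_masks(self, grid40):
        tumor, ablation = rasterize_case(CaseGeometry(15.0, 0.0), grid40)
        assert np.array_equal(tumor.voxels, ablation.voxels)

    def test_fully_negative_margin_clamps_to_empty_ablation(self, grid40):
        tumor, ablation = rasterize_case(CaseGeometry(10.0, -5.0), grid40)
        assert not tumor.is_empty
        assert ablation.is_empty

    def test_solid_exceeding_grid_raises(self):
        small = GridSpec((10, 10, 10), (1.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            rasterize_case(CaseGeometry(30.0, 10.0), small)

    def test_resolution_refinement_halves_volume_error(self):
        geom = CaseGeometry(11.0, 0.0)
        errs = []
        for spacing in (1.0, 0.5):
            n = int(24 / spacing)
            grid = GridSpec((n, n, n), (spacing,) * 3)
            tumor, _ = rasterize_case(geom, grid)
            errs.append(abs(tumor.volume_mm3 - sphere_volume(5.5)) / sphere_volume(5.5))
        assert errs[1] <= errs[0] / 2.0 + 1e-12

    def test_concentric_margin_matches_target(self, grid40):
        geom = CaseGeometry(12.0, 4.0)
        tumor, ablation = rasterize_case(geom, grid40)
        diag = np.sqrt(3.0)
        assert compute_mam(tumor, ablation).mam_mm == pytest.approx(4.0, abs=diag)


class TestApplyShrinkage:
    def test_zero_shrinkage_is_identity(self, grid40):
        tumor = sphere_mask(grid40, 8.0)
        out = apply_shrinkage(tumor, 0.0)
        assert np.array_equal(out.voxels, tumor.voxels)

    def test_thirty_percent_shrinkage_matches_analytic_volume(self, grid40):
        tumor = sphere_mask(grid40, 10.0)
        out = apply_shrinkage(tumor, 0.3)
        assert out.volume_mm3 == pytest.approx(sphere_volume(7.0), rel=0.05)

    def test_extreme_shrinkage_degenerates_to_center(self, grid40):
        tumor = sphere_mask(grid40, 10.0)
        out = apply_shrinkage(tumor, 0.989)
        assert 1 <= out.n_voxels <= 8

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_out_of_range_fraction_rejected(self, grid40, bad):
        with pytest.raises(ValueError):
            apply_shrinkage(sphere_mask(grid40, 5.0), bad)

    def test_monotone_in_fraction(self, grid40):
        tumor = sphere_mask(grid40, 10.0)
        counts = [
            apply_shrinkage(tumor, f).n_voxels for f in (0.0, 0.1, 0.2, 0.3, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAddSatellite:
    def test_absent_satellite_is_identity(self, grid40, rng):
        tumor = sphere_mask(grid40, 8.0)
        out = add_satellite(tumor, False, 0.0, rng)
        assert np.array_equal(out.voxels, tumor.voxels)

    def test_tangent_satellite_extends_by_twice_its_radius(self, grid40):
        tumor = sphere_mask(grid40, 10.0)

        class _AlongX:
            def normal(self, size):
                return np.array([1.0, 1e-9, 1e-9])

        out = add_satellite(tumor, True, 1.0, _AlongX())
        x_extent = np.nonzero(out.voxels.any(axis=(1, 2)))[0].max()
        x_mm = (x_extent - (grid40.shape[0] - 1) / 2.0) * grid40.spacing[0]
        assert x_mm == pytest.approx(12.0, abs=1.0)

    def test_never_removes_voxels(self, grid40, rng):
        tumor = sphere_mask(grid40, 8.0)
        for _ in range(20):
            out = add_satellite(tumor, True, 2.0, rng)
            assert not (tumor.voxels & ~out.voxels).any()

    def test_direction_is_uniform_over_the_sphere(self):
        # resultant length test: mean direction of n uniform unit vectors
        # is Rayleigh-distributed; a strong drift rejects uniformity
        rng = np.random.default_rng(3)
        grid = GridSpec((30, 30, 30), (1.0, 1.0, 1.0))
        tumor = sphere_mask(grid, 6.0)
        dirs = []
        for _ in range(400):
            out = add_satellite(tumor, True, 1.5, rng)
            delta = out.centroid_mm() - tumor.centroid_mm()
            dirs.append(delta / np.linalg.norm(delta))
        resultant = np.linalg.norm(np.mean(dirs, axis=0))
        # under uniformity resultant ~ sqrt(pi/ (4 n)) * ...; 3 sigma bound
        assert resultant < 3.0 / np.sqrt(len(dirs))

    def test_satellite_outside_grid_raises(self, rng):
        grid = GridSpec((16, 16, 16), (1.0, 1.0, 1.0))
        tumor = sphere_mask(grid, 7.0)
        with pytest.raises(GeometryError):
            add_satellite(tumor, True, 2.5, rng)


class TestGridSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec((0, 10, 10))
        with pytest.raises(ValueError):
            GridSpec((10, 10, 10), (1.0, -1.0, 1.0))

    def test_min_extent_formula(self):
        # 30 mm tumor + 2*10 mm margin + 2*3sigma registration + padding
        assert min_grid_extent_mm(30, 10, 1.0) == pytest.approx(66.0)

    def test_axes_are_centred(self):
        ax = GridSpec((5, 5, 4), (1.0, 1.0, 2.0)).axes()
        assert ax[0].tolist() == [-2, -1, 0, 1, 2]
        assert ax[2].tolist() == [-3, -1, 1, 3]


def test_ellipsoid_rasterize_respects_anisotropic_spacing():
    grid = GridSpec((40, 40, 8), (1.0, 1.0, 5.0))
    mask = Ellipsoid.sphere((0, 0, 0), 10.0).rasterize(grid)
    # 20 mm diameter spans 4 slices of 5 mm
    assert mask.voxels.any(axis=(0, 1)).sum() == 4
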