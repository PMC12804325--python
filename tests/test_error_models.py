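"""Technical error models: draws, shifts, boundary noise, resampling."""

import numpy as np
import pytest

from a0sim import (
    SimulationParams,
    VolumeMask,
    apply_registration_shift,
    apply_segmentation_noise,
    compute_mam,
    draw_errors,
    resample_slice_thickness,
)
from a0sim.error_models import segmentation_offset_sd

from conftest import sphere_mask
from test_phantom import sphere_volume


class TestDrawErrors:
    def test_zero_sd_gives_zero_magnitude(self, rng):
        p = SimulationParams(registration_sd_mm=0.0)
        assert all(draw_errors(p, rng).e_mag_mm == 0.0 for _ in range(20))

    def test_distribution_moments(self):
        rng = np.random.default_rng(5)
        p = SimulationParams(registration_sd_mm=3.0)
        draws = [draw_errors(p, rng) for _ in range(10_000)]
        mags = np.array([d.e_mag_mm for d in draws])
        assert mags.std() == pytest.approx(3.0, abs=0.1)
        assert mags.mean() == pytest.approx(0.0, abs=0.1)
        axes = np.bincount([d.e_dir for d in draws], minlength=3) / len(draws)
        assert np.allclose(axes, 1 / 3, atol=0.02)

    def test_bernoulli_extremes_for_satellites(self, rng):
        always = SimulationParams(satellite_prob=1.0)
        never = SimulationParams(satellite_prob=0.0)
        for _ in range(20):
            d1 = draw_errors(always, rng)
            assert d1.satellite and 0.5 <= d1.d_satellite_mm <= 2.5
            d0 = draw_errors(never, rng)
            assert not d0.satellite and d0.d_satellite_mm == 0.0

    def test_shrinkage_draws_clamped_nonnegative(self):
        rng = np.random.default_rng(6)
        p = SimulationParams(shrinkage_mean=0.0)
        fracs = [draw_errors(p, rng).shrink_frac for _ in range(500)]
        assert min(fracs) == 0.0  # negative normal draws clamp to zero
        assert max(fracs) < 0.25

    def test_segmentation_offsets_use_calibrated_sd(self):
        rng = np.random.default_rng(7)
        p = SimulationParams(segmentation_sd_mm=4.0)
        offs = np.array(
            [draw_errors(p, rng).e_tumor_mm for _ in range(10_000)]
        )
        assert offs.std() == pytest.approx(segmentation_offset_sd(4.0), rel=0.05)

    def test_tumor_and_ablation_offsets_independent(self):
        rng = np.random.default_rng(8)
        p = SimulationParams(segmentation_sd_mm=2.0)
        d = np.array(
            [
                (e.e_tumor_mm, e.e_ablation_mm)
                for e in (draw_errors(p, rng) for _ in range(5_000))
            ]
        )
        assert abs(np.corrcoef(d.T)[0, 1]) < 0.05


class TestRegistrationShift:
    def test_zero_shift_is_identity(self, grid40):
        m = sphere_mask(grid40, 8.0)
        out = apply_registration_shift(m, 0.0, 0)
        assert np.array_equal(out.voxels, m.voxels)

    def test_centroid_moves_by_the_shift(self, grid40):
        from a0sim.phantom import Ellipsoid

        solid = Ellipsoid.sphere((0, 0, 0), 10.0)
        m = solid.rasterize(grid40)
        out = apply_registration_shift(m, 3.0, 0, solid=solid)
        delta = out.centroid_mm() - m.centroid_mm()
        assert delta[0] == pytest.approx(3.0, abs=0.2)
        assert abs(delta[1]) < 0.05 and abs(delta[2]) < 0.05

    def test_lattice_shift_equals_rolled_mask(self, grid40):
        m = sphere_mask(grid40, 6.0)
        out = apply_registration_shift(m, 1.0, 2)
        assert np.array_equal(out.voxels[:, :, 1:], m.voxels[:, :, :-1])

    def test_voxel_count_preserved_under_subvoxel_shift(self, grid40):
        from a0sim.phantom import Ellipsoid

        solid = Ellipsoid.sphere((0, 0, 0), 9.0)
        m = solid.rasterize(grid40)
        out = apply_registration_shift(m, 1.37, 1, solid=solid)
        assert out.n_voxels == pytest.approx(m.n_voxels, rel=0.02)


class TestSegmentationNoise:
    def test_zero_offset_is_identity(self, grid40):
        m = sphere_mask(grid40, 8.0)
        assert np.array_equal(apply_segmentation_noise(m, 0.0).voxels, m.voxels)

    def test_dilation_matches_analytic_volume(self, grid40):
        m = sphere_mask(grid40, 10.0)
        out = apply_segmentation_noise(m, 2.0)
        assert out.volume_mm3 == pytest.approx(sphere_volume(12.0), rel=0.05)

    def test_erosion_matches_analytic_volume(self, grid40):
        m = sphere_mask(grid40, 10.0)
        out = apply_segmentation_noise(m, -2.0)
        assert out.volume_mm3 == pytest.approx(sphere_volume(8.0), rel=0.07)

    def test_erosion_to_empty_is_permitted(self, grid40):
        m = sphere_mask(grid40, 3.0)
        assert apply_segmentation_noise(m, -5.0).is_empty

    def test_monotone_in_offset(self, grid40):
        m = sphere_mask(grid40, 6.0)
        prev = apply_segmentation_noise(m, -3.0)
        for off in (-1.5, 0.0, 1.5, 3.0):
            cur = apply_segmentation_noise(m, off)
            assert not (prev.voxels & ~cur.voxels).any()
            prev = cur

    def test_open_close_containment(self, grid40):
        m = sphere_mask(grid40, 6.0)
        opened = apply_segmentation_noise(apply_segmentation_noise(m, -2.0), 2.0)
        closed = apply_segmentation_noise(apply_segmentation_noise(m, 2.0), -2.0)
        assert not (opened.voxels & ~closed.voxels).any()

    def test_margin_shift_equals_offset_difference(self, grid40):
        t = sphere_mask(grid40, 5.0, label="tumor_imaged")
        a = sphere_mask(grid40, 10.0, label="ablation_imaged")
        base = compute_mam(t, a).mam_mm
        t2 = apply_segmentation_noise(t, 1.0)
        a2 = apply_segmentation_noise(a, 3.0)
        shifted = compute_mam(t2, a2).mam_mm
        assert shifted - base == pytest.approx(3.0 - 1.0, abs=np.sqrt(3.0))


class TestSliceResampling:
    def test_native_thickness_is_identity(self, grid40):
        m = sphere_mask(grid40, 8.0)
        out = resample_slice_thickness(m, 1.0)
        assert np.array_equal(out.voxels, m.voxels)
        assert out.grid == m.grid

    def test_sphere_slice_count_at_5mm(self, grid40):
        m = sphere_mask(grid40, 10.0)
        out = resample_slice_thickness(m, 5.0)
        assert out.grid.spacing == (1.0, 1.0, 5.0)
        n_slices = int(out.voxels.any(axis=(0, 1)).sum())
        assert 3 <= n_slices <= 5

    def test_empty_mask_stays_empty(self, grid40):
        empty = VolumeMask(grid40, np.zeros(grid40.shape, bool))
        assert resample_slice_thickness(empty, 3.0).is_empty

    def test_thickness_below_spacing_rejected(self, grid40):
        with pytest.raises(ValueError):
            resample_slice_thickness(sphere_mask(grid40, 5.0), 0.5)

    def test_inplane_axes_untouched(self, grid40):
        m = sphere_mask(grid40, 9.0)
        out = resample_slice_thickness(m, 4.0)
        assert out.voxels.shape[:2] == m.voxels.shape[:2]
        # each output slice is an exact copy of some input slice
        for k in range(out.voxels.shape[2]):
            sl = out.voxels[:, :, k]
            assert any(
                np.array_equal(sl, m.voxels[:, :, j])
                for j in range(m.voxels.shape[2])
            )
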