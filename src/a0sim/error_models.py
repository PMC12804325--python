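"""Technical measurement-error models for the imaged masks.

Three error sources act on the *imaged* tumor/ablation masks only (the
true masks are never touched by them):

* registration error — a rigid shift of the ablation zone along one
  randomly chosen axis, magnitude ~ Normal(0, registration_sd_mm);
* segmentation error — an independent global boundary offset for each
  mask (outward positive), realized by thresholding the signed distance
  field, i.e. dilation/erosion by a metric ball;
* slice thickness — nearest-neighbour resampling of the cranio-caudal
  (z) axis to the reconstructed slice spacing.

The composition order shift -> boundary noise -> resampling is fixed.

Calibration of the segmentation offsets
---------------------------------------
The segmentation error parameter is swept over 1-5 mm, but a global
per-mask offset with standard deviation equal to that parameter
overshoots the published A0 thresholds several-fold.  The realization
used here draws each mask's offset from Normal(0, sqrt(eps)) mm, the
single-parameter mapping that reproduces the published threshold sweep;
see docs/methods.md for the calibration argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .margins import bounding_box, mask_surface
from .phantom import Ellipsoid, GeometryError, GridSpec, VolumeMask

__all__ = [
    "ErrorDraws",
    "draw_errors",
    "segmentation_offset_sd",
    "apply_registration_shift",
    "apply_segmentation_noise",
    "resample_slice_thickness",
]

AXES = ("X", "Y", "Z")


@dataclass(frozen=True)
class ErrorDraws:
    """Per-simulation random error realizations."""

    shrink_frac: float
    satellite: bool
    d_satellite_mm: float  # satellite radius; 0 when absent
    e_mag_mm: float  # signed registration magnitude
    e_dir: int  # axis index 0/1/2 (X/Y/Z)
    e_tumor_mm: float  # tumor boundary offset
    e_ablation_mm: float  # ablation boundary offset

    @property
    def e_dir_name(self) -> str:
        return AXES[self.e_dir]


def segmentation_offset_sd(segmentation_sd_mm: float) -> float:
    """Standard deviation (mm) of the per-mask global boundary offset.

    The offset combines a fixed 1 mm contouring floor (independent
    draws ~ Normal(0, 1) for each mask) with an additional component
    whose spread is half the nominal error in excess of that floor:

        sd(eps) = sqrt(1^2 + ((eps - 1) / 2)^2)

    Identity at the 1 mm floor; calibrated against the published A0
    sweep at 3 and 5 mm (see docs/methods.md).  A literal sd = eps
    overshoots those thresholds several-fold.  Below the floor the sd
    falls linearly to zero so a zero error parameter disables the noise.
    """
    if segmentation_sd_mm <= 1.0:
        return float(segmentation_sd_mm)
    return math.sqrt(1.0 + ((segmentation_sd_mm - 1.0) / 2.0) ** 2)


def draw_errors(params, rng: np.random.Generator) -> ErrorDraws:
    """Draw one realization of all biological and technical errors."""
    shrink = float(
        np.clip(rng.normal(params.shrinkage_mean, params.shrinkage_sd), 0.0, 0.99)
    )
    satellite = bool(rng.random() < params.satellite_prob)
    d_sat = float(rng.uniform(0.5, 2.5)) if satellite else 0.0
    e_mag = float(rng.normal(0.0, params.registration_sd_mm))
    e_dir = int(rng.integers(3))
    seg_sd = segmentation_offset_sd(params.segmentation_sd_mm)
    e_tumor = float(rng.normal(0.0, seg_sd))
    e_ablation = float(rng.normal(0.0, seg_sd))
    return ErrorDraws(shrink, satellite, d_sat, e_mag, e_dir, e_tumor, e_ablation)


def apply_registration_shift(
    ablation: VolumeMask,
    e_mag_mm: float,
    e_dir: int,
    solid: Ellipsoid | None = None,
) -> VolumeMask:
    """Translate the ablation mask by ``e_mag_mm`` along axis ``e_dir``.

    When the analytic ``solid`` behind the mask is supplied, the shift
    is realized by re-rasterizing the solid at the displaced centre, so
    sub-voxel shifts are honoured.  Without it the raster mask is
    shifted to the nearest voxel.
    """
    if e_dir not in (0, 1, 2):
        raise ValueError(f"e_dir must be 0, 1 or 2, got {e_dir}")
    grid = ablation.grid
    if e_mag_mm == 0.0:
        return ablation.copy()
    if solid is not None:
        offset = [0.0, 0.0, 0.0]
        offset[e_dir] = e_mag_mm
        out = solid.shifted(offset).rasterize(grid, ablation.label)
        return out
    shift_vox = int(round(e_mag_mm / grid.spacing[e_dir]))
    out = np.zeros_like(ablation.voxels)
    if abs(shift_vox) >= grid.shape[e_dir]:
        raise GeometryError("registration shift moves the mask fully off-grid")
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift_vox >= 0:
        src[e_dir] = slice(0, grid.shape[e_dir] - shift_vox)
        dst[e_dir] = slice(shift_vox, None)
    else:
        src[e_dir] = slice(-shift_vox, None)
        dst[e_dir] = slice(0, grid.shape[e_dir] + shift_vox)
    out[tuple(dst)] = ablation.voxels[tuple(src)]
    return VolumeMask(grid, out, ablation.label)


def apply_segmentation_noise(mask: VolumeMask, offset_mm: float) -> VolumeMask:
    """Displace the mask boundary outward by ``offset_mm`` (inward if negative).

    Thresholds the signed Euclidean distance field of the mask at the
    (compensated) negative offset, i.e. dilation (erosion) by a metric
    ball of that radius.  Distances are measured to surface voxel
    centres, which sit inside the analytic boundary by a sub-voxel
    amount; a 0.35-voxel compensation, validated against the analytic
    offset-ball volume oracle, keeps the displaced boundary on the
    analytic offset surface while preserving the zero-offset identity
    (no neighbouring voxel centre is closer than one spacing).  Erosion
    to an empty mask is permitted and returns an empty mask.
    """
    if offset_mm == 0.0 or mask.is_empty:
        return mask.copy()
    grid = mask.grid
    compensation = 0.35 * min(grid.spacing)
    pad = int(np.ceil(abs(offset_mm) / min(grid.spacing))) + 2
    blo, bhi = bounding_box(mask.voxels)
    lo = np.maximum(blo - pad, 0)
    hi = np.minimum(bhi + pad, grid.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = mask.voxels[box]
    surf = mask_surface(sub)
    dist = ndimage.distance_transform_edt(~surf, sampling=grid.spacing)
    sdf = np.where(sub, dist, -dist)
    out = np.zeros(grid.shape, dtype=bool)
    out[box] = sdf >= -offset_mm - compensation
    return VolumeMask(grid, out, mask.label)


def resample_slice_thickness(mask: VolumeMask, thickness_mm: float) -> VolumeMask:
    """Resample the z axis to ``thickness_mm`` by nearest-neighbour slab sampling.

    The output grid keeps the in-plane spacing, has z spacing equal to
    the slice thickness, and preserves the physical grid centre; each
    output slice takes the voxel values of the input slice nearest to
    its slab centre.
    """
    grid = mask.grid
    sz = grid.spacing[2]
    if thickness_mm < sz:
        raise ValueError(
            f"slice thickness {thickness_mm} mm below grid z spacing {sz} mm"
        )
    if thickness_mm == sz:
        return mask.copy()
    nz = grid.shape[2]
    nz_out = max(1, int(math.floor(nz * sz / thickness_mm)))
    z_out = (np.arange(nz_out) - (nz_out - 1) / 2.0) * thickness_mm
    src = np.round(z_out / sz + (nz - 1) / 2.0).astype(int)
    src = np.clip(src, 0, nz - 1)
    new_grid = GridSpec(
        (grid.shape[0], grid.shape[1], nz_out),
        (grid.spacing[0], grid.spacing[1], float(thickness_mm)),
    )
    return VolumeMask(new_grid, mask.voxels[:, :, src], mask.label)
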