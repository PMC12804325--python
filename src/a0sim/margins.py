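"""Minimum ablative margin (MAM) between tumor and ablation masks.

The MAM is the signed 3D distance between the tumor boundary and the
ablation-zone boundary: positive when the whole tumor lies inside the
ablation zone (the smallest clearance anywhere on the tumor surface),
negative when tumor tissue protrudes (the deepest protrusion).  Both
surfaces are the sets of foreground voxels with at least one
6-connected background neighbour; distances are exact Euclidean
voxel-centre distances weighted by the (possibly anisotropic) voxel
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .phantom import VolumeMask

__all__ = ["MarginResult", "compute_mam", "signed_distance_field", "mask_surface"]


@dataclass(frozen=True)
class MarginResult:
    """Signed minimum ablative margin for one mask pair."""

    mam_mm: float
    covered: bool
    n_uncovered_voxels: int

    def to_dict(self) -> dict:
        return {
            "mam_mm": self.mam_mm,
            "covered": self.covered,
            "n_uncovered_voxels": self.n_uncovered_voxels,
        }


def mask_surface(voxels: np.ndarray) -> np.ndarray:
    """Boundary voxels: foreground with a 6-connected background neighbour.

    Voxels on the array edge count as surface (the outside of the grid
    is background).
    """
    if not voxels.any():
        return np.zeros_like(voxels)
    interior = np.ones_like(voxels)
    interior &= np.roll(voxels, 1, 0) & np.roll(voxels, -1, 0)
    interior &= np.roll(voxels, 1, 1) & np.roll(voxels, -1, 1)
    interior &= np.roll(voxels, 1, 2) & np.roll(voxels, -1, 2)
    # np.roll wraps; edge voxels must see the outside as background
    interior[0] = interior[-1] = False
    interior[:, 0] = interior[:, -1] = False
    interior[:, :, 0] = interior[:, :, -1] = False
    return voxels & ~interior


def _surface_points_mm(voxels: np.ndarray, spacing) -> np.ndarray:
    surf = mask_surface(voxels)
    idx = np.argwhere(surf)
    return idx * np.asarray(spacing, dtype=float)


def signed_distance_field(mask: VolumeMask) -> np.ndarray:
    """Spacing-aware signed distance (mm) to the mask surface.

    Positive inside the mask, negative outside, zero on the surface
    voxels themselves.  Distances are measured to the nearest surface
    voxel centre with an exact Euclidean distance transform.
    """
    surf = mask_surface(mask.voxels)
    if not surf.any():  # empty mask: everything is outside, infinitely far
        return np.full(mask.grid.shape, -np.inf)
    dist = ndimage.distance_transform_edt(~surf, sampling=mask.grid.spacing)
    return np.where(mask.voxels, dist, -dist)


def point_signed_distance(mask: VolumeMask, point_mm) -> float:
    """Signed distance (mm) from a physical point to the mask surface."""
    if mask.is_empty:
        return -np.inf
    pts = _surface_points_mm(mask.voxels, mask.grid.spacing)
    origin = -(np.array(mask.grid.shape) - 1) / 2.0 * mask.grid.spacing
    p = np.asarray(point_mm, dtype=float) - origin
    d = float(np.sqrt(((pts - p) ** 2).sum(axis=1)).min())
    inside = bool(mask.voxels[mask.grid.index_of(point_mm)])
    return d if inside else -d


def bounding_box(voxels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive-exclusive foreground bounding box via axis projections.

    Much cheaper than ``np.nonzero`` on large mostly-empty masks.
    """
    proj_xy = voxels.any(axis=2)
    x = np.flatnonzero(proj_xy.any(axis=1))
    y = np.flatnonzero(proj_xy.any(axis=0))
    z = np.flatnonzero(voxels.any(axis=(0, 1)))
    lo = np.array([x[0], y[0], z[0]])
    hi = np.array([x[-1], y[-1], z[-1]]) + 1
    return lo, hi


def _crop_slices(voxels_list, pad: int, shape) -> tuple[slice, slice, slice]:
    boxes = [bounding_box(v) for v in voxels_list]
    lo = np.maximum(np.min([b[0] for b in boxes], axis=0) - pad, 0)
    hi = np.minimum(np.max([b[1] for b in boxes], axis=0) + pad, shape)
    return tuple(slice(l, h) for l, h in zip(lo, hi))


def compute_mam(tumor: VolumeMask, ablation: VolumeMask) -> MarginResult:
    """Signed minimum ablative margin between a tumor and an ablation mask.

    For every tumor surface voxel the Euclidean distance to the nearest
    ablation surface voxel is computed (via a KD-tree over the ablation
    surface; identical to an exhaustive all-pairs search), signed
    positive when the tumor voxel lies inside the ablation mask.  The
    MAM is the minimum signed value.  An empty ablation mask yields
    ``-(maximum tumor surface distance from the tumor centroid)`` as a
    radius proxy for the fully missed tumor.
    """
    if tumor.grid != ablation.grid:
        raise ValueError("tumor and ablation masks must share one grid")
    if tumor.is_empty:
        raise ValueError("tumor mask is empty")
    spacing = np.asarray(tumor.grid.spacing, dtype=float)
    n_uncovered = int((tumor.voxels & ~ablation.voxels).sum())
    covered = n_uncovered == 0

    if ablation.is_empty:
        pts = _surface_points_mm(tumor.voxels, spacing)
        centroid = (np.argwhere(tumor.voxels) * spacing).mean(axis=0)
        proxy = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).max())
        return MarginResult(-proxy, False, n_uncovered)

    box = _crop_slices([tumor.voxels, ablation.voxels], 1, tumor.grid.shape)
    t_vox = tumor.voxels[box]
    a_vox = ablation.voxels[box]
    t_surf = np.argwhere(mask_surface(t_vox))
    a_pts = np.argwhere(mask_surface(a_vox)) * spacing
    dist = cKDTree(a_pts).query(t_surf * spacing, k=1)[0]
    inside = a_vox[tuple(t_surf.T)]
    signed = np.where(inside, dist, -dist)
    return MarginResult(float(signed.min()), covered, n_uncovered)
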