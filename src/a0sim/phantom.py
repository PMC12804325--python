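"""Synthetic voxel phantoms of a liver tumor and its ablation zone.

A simulated case is a pair of concentric solids on a regular voxel grid:
the tumor (diameter sampled from the configured range) and the ablation
zone (tumor diameter plus twice the sampled target margin).  Biological
effects that are invisible on imaging — thermal tissue shrinkage and
microscopic satellite lesions — are applied to the *true* tumor mask
only, so that the true and imaged tumor extents can disagree.

Coordinates are physical millimetres.  Voxel ``i`` along an axis with
``n`` voxels and spacing ``s`` sits at ``(i - (n - 1) / 2) * s``; the
grid centre is the origin and solids are rasterized by voxel-centre
inclusion (a voxel is foreground iff its centre lies inside the
analytic solid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "GridSpec",
    "VolumeMask",
    "Ellipsoid",
    "CaseGeometry",
    "sample_case",
    "case_solids",
    "rasterize_case",
    "apply_shrinkage",
    "add_satellite",
    "min_grid_extent_mm",
]


class GeometryError(ValueError):
    """A solid or mask does not fit the voxel grid."""


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D voxel grid with anisotropic spacing in mm.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z.
    spacing
        Voxel size in mm along x, y, z.
    """

    shape: tuple[int, int, int] = (80, 80, 80)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("shape and spacing must be length-3")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge length covered by the voxel centres plus one voxel."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical voxel-centre coordinates (mm), origin at centre."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing)
        )

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a physical point, clipped to the grid."""
        idx = []
        for p, n, s in zip(point_mm, self.shape, self.spacing):
            i = int(round(p / s + (n - 1) / 2.0))
            idx.append(min(max(i, 0), n - 1))
        return tuple(idx)


def min_grid_extent_mm(
    max_tumor_mm: float,
    max_margin_mm: float,
    registration_sd_mm: float,
    padding_mm: float = 10.0,
) -> float:
    """Smallest physical grid edge that holds the worst-case geometry.

    Accounts for the largest tumor, the largest concentric margin, a
    3-sigma registration excursion on each side, and padding.
    """
    return (
        max_tumor_mm + 2.0 * max_margin_mm + 2.0 * 3.0 * registration_sd_mm + padding_mm
    )


@dataclass
class VolumeMask:
    """A binary 3D mask on a :class:`GridSpec`.

    ``label`` records the mask's role: ``tumor_true``, ``tumor_imaged``,
    ``ablation_true`` or ``ablation_imaged``.
    """

    grid: GridSpec
    voxels: np.ndarray
    label: str = "mask"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"voxels shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.grid.spacing))

    def copy(self, label: str | None = None) -> "VolumeMask":
        return VolumeMask(self.grid, self.voxels.copy(), label or self.label)

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid of the foreground voxels."""
        if self.is_empty:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.nonzero(self.voxels)
        return np.array(
            [
                (i.mean() - (n - 1) / 2.0) * s
                for i, n, s in zip(idx, self.grid.shape, self.grid.spacing)
            ]
        )

    def touches_boundary(self) -> bool:
        """True if any foreground voxel lies on the outermost grid layer."""
        v = self.voxels
        return bool(
            v[0].any() or v[-1].any() or v[:, 0].any() or v[:, -1].any()
            or v[:, :, 0].any() or v[:, :, -1].any()
        )

    def to_nifti(self, path) -> None:
        """Write as NIfTI with the voxel spacing in the affine, for visual QA."""
        import nibabel as nib

        affine = np.diag(list(self.grid.spacing) + [1.0])
        img = nib.Nifti1Image(self.voxels.astype(np.uint8), affine)
        img.header.set_zooms(self.grid.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, label: str = "mask") -> "VolumeMask":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        data = np.asanyarray(img.dataobj) > 0
        return cls(GridSpec(data.shape, zooms), data, label)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned analytic ellipsoid (sphere when radii are equal).

    Keeping the analytic solid alongside its raster lets continuous
    operations (sub-voxel registration shifts, radial scaling) be
    realized by re-rasterization instead of lossy grid interpolation.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    @classmethod
    def sphere(cls, center, radius: float) -> "Ellipsoid":
        return cls(tuple(float(c) for c in center), (radius, radius, radius))

    @property
    def is_degenerate(self) -> bool:
        return any(r <= 0 for r in self.radii)

    def shifted(self, offset_mm) -> "Ellipsoid":
        return replace(
            self, center=tuple(c + o for c, o in zip(self.center, offset_mm))
        )

    def scaled(self, factor: float) -> "Ellipsoid":
        return replace(self, center=self.center, radii=tuple(r * factor for r in self.radii))

    def grown(self, delta_mm: float) -> "Ellipsoid":
        return replace(self, radii=tuple(r + delta_mm for r in self.radii))

    def rasterize(self, grid: GridSpec, label: str = "mask") -> VolumeMask:
        """Voxel-centre inclusion rasterization, filled inside the bounding box."""
        voxels = np.zeros(grid.shape, dtype=bool)
        if not self.is_degenerate:
            axes = grid.axes()
            slices = []
            sub = []
            for ax, c, r in zip(axes, self.center, self.radii):
                inside = np.abs(ax - c) <= r
                if not inside.any():
                    return VolumeMask(grid, voxels, label)
                lo, hi = np.nonzero(inside)[0][[0, -1]]
                slices.append(slice(lo, hi + 1))
                sub.append((ax[lo : hi + 1] - c) / r)
            q = (
                sub[0][:, None, None] ** 2
                + sub[1][None, :, None] ** 2
                + sub[2][None, None, :] ** 2
            )
            voxels[tuple(slices)] = q <= 1.0
        return VolumeMask(grid, voxels, label)


@dataclass(frozen=True)
class CaseGeometry:
    """Sampled geometry of one simulated case."""

    d_tumor_mm: float
    margin_target_mm: float
    shape_kind: str = "sphere"
    ellipsoid_axis_ratio: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.shape_kind not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.d_tumor_mm <= 0:
            raise ValueError("tumor diameter must be positive")


def sample_case(params, rng: np.random.Generator) -> CaseGeometry:
    """Sample tumor diameter and target margin uniformly from the configured ranges."""
    lo_t, hi_t = params.tumor_range_mm
    lo_m, hi_m = params.margin_range_mm
    if lo_t > hi_t or lo_m > hi_m:
        raise ValueError("invalid sampling range (lo > hi)")
    d_tumor = float(rng.uniform(lo_t, hi_t)) if hi_t > lo_t else float(lo_t)
    margin = float(rng.uniform(lo_m, hi_m)) if hi_m > lo_m else float(lo_m)
    if params.shape_kind == "ellipsoid":
        ratio = tuple(float(r) for r in rng.uniform(0.8, 1.2, size=3))
    else:
        ratio = (1.0, 1.0, 1.0)
    return CaseGeometry(d_tumor, margin, params.shape_kind, ratio)


def case_solids(geom: CaseGeometry) -> tuple[Ellipsoid, Ellipsoid]:
    """Analytic tumor and concentric ablation solids at the grid centre.

    The ablation radius is the tumor radius plus the target margin on
    every axis, so before any error the margin is exact everywhere on
    the surface.  Negative radii (deeply negative margins) yield a
    degenerate, empty ablation.
    """
    r = geom.d_tumor_mm / 2.0
    ratios = np.asarray(geom.ellipsoid_axis_ratio, dtype=float)
    # normalize ratios so the mean radius is preserved for ellipsoids
    ratios = ratios / ratios.mean()
    tumor = Ellipsoid((0.0, 0.0, 0.0), tuple(r * ratios))
    ablation = tumor.grown(geom.margin_target_mm)
    return tumor, ablation


def rasterize_case(
    geom: CaseGeometry, grid: GridSpec
) -> tuple[VolumeMask, VolumeMask]:
    """Rasterize the tumor and ablation solids of a case onto ``grid``."""
    tumor_solid, ablation_solid = case_solids(geom)
    max_r = max(tumor_solid.radii + ablation_solid.radii)
    if any(2.0 * max_r > e for e in grid.extent_mm):
        raise GeometryError(
            f"solid of radius {max_r:.1f} mm exceeds grid extent {grid.extent_mm}"
        )
    tumor = tumor_solid.rasterize(grid, "tumor_imaged")
    ablation = ablation_solid.rasterize(grid, "ablation_imaged")
    if tumor.is_empty:
        raise GeometryError("tumor rasterized to an empty mask")
    return tumor, ablation


def apply_shrinkage(tumor: VolumeMask, shrink_fraction: float) -> VolumeMask:
    """Radially contract a tumor mask about its centroid.

    Linear dimensions scale by ``1 - shrink_fraction``; the centre is
    unchanged.  The output is produced by nearest-neighbour sampling of
    the input at inverse-scaled coordinates, so it stays binary.
    """
    if not 0.0 <= shrink_fraction < 1.0:
        raise ValueError(f"shrink_fraction must be in [0, 1), got {shrink_fraction}")
    if shrink_fraction == 0.0 or tumor.is_empty:
        return tumor.copy("tumor_true")
    from .margins import bounding_box

    scale = 1.0 - shrink_fraction
    blo, bhi = bounding_box(tumor.voxels)
    lo = np.maximum(blo - 1, 0)
    hi = np.minimum(bhi + 1, tumor.grid.shape)
    idx = np.nonzero(tumor.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]])
    center = np.array([i.mean() + l for i, l in zip(idx, lo)])
    sub = tumor.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    grids = np.meshgrid(
        *[np.arange(l, h, dtype=float) for l, h in zip(lo, hi)], indexing="ij"
    )
    coords = [center[k] + (grids[k] - center[k]) / scale - lo[k] for k in range(3)]
    shrunk = ndimage.map_coordinates(
        sub.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)
    out = np.zeros(tumor.grid.shape, dtype=bool)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = shrunk
    if not out.any():  # extreme contraction: keep the centre voxel
        out[tuple(np.round(center).astype(int))] = True
    return VolumeMask(tumor.grid, out, "tumor_true")


def add_satellite(
    tumor: VolumeMask,
    present: bool,
    radius_mm: float,
    rng: np.random.Generator,
) -> VolumeMask:
    """Union a tangent satellite sphere onto the tumor mask.

    The satellite is placed along a direction drawn uniformly on the
    sphere, tangent to (touching) the tumor surface from outside, so the
    foreground extends ``2 * radius_mm`` beyond the tumor along that
    direction.
    """
    if not present:
        return tumor.copy()
    if radius_mm <= 0:
        raise ValueError("satellite radius must be positive")
    if tumor.is_empty:
        raise GeometryError("cannot attach a satellite to an empty tumor")
    grid = tumor.grid
    center = tumor.centroid_mm()
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    # march along u to find the raster surface of the tumor
    step = 0.1 * min(grid.spacing)
    max_extent = 0.5 * max(grid.extent_mm) * np.sqrt(3.0)
    ts = np.arange(0.0, max_extent, step)
    pts = center[None, :] + ts[:, None] * u[None, :]
    ijk = [
        pts[:, k] / grid.spacing[k] + (grid.shape[k] - 1) / 2.0 for k in range(3)
    ]
    inside = ndimage.map_coordinates(
        tumor.voxels.astype(np.uint8), ijk, order=0, mode="constant", cval=0
    ).astype(bool)
    r_surface = ts[inside][-1] if inside.any() else 0.0
    sat_center = center + (r_surface + radius_mm) * u
    half_extent = np.array(grid.extent_mm) / 2.0
    if np.any(np.abs(sat_center) + radius_mm > half_extent):
        raise GeometryError("satellite lesion falls outside the grid")
    sat = Ellipsoid.sphere(sat_center, radius_mm).rasterize(grid)
    if sat.is_empty:
        # sub-voxel lesion between voxel centres: keep it representable
        # rather than letting rasterization delete it from the true mask
        sat.voxels[grid.index_of(sat_center)] = True
    out = tumor.copy("tumor_true")
    out.voxels |= sat.voxels
    return out
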