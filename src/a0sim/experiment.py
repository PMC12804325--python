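"""Simulation orchestration: cases, sweeps and parameter grids.

One simulated case walks the eight-step pipeline:

1. sample tumor diameter and target margin;
2. rasterize concentric tumor and ablation solids;
3. apply tissue shrinkage and a possible satellite lesion to the *true*
   tumor;
4. measure the true MAM against the true ablation zone;
5. shift the imaged ablation zone by the registration error;
6. offset the imaged tumor and ablation boundaries by the segmentation
   errors;
7. resample both imaged masks to the reconstructed slice thickness;
8. measure the observed MAM.

Biological effects (steps 3) touch only the true tumor; technical
errors (steps 5-7) touch only the imaged masks.  Every case draws its
random stream from ``(seed, case_index)`` so runs are reproducible and
order-independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import error_models, phantom
from .error_models import ErrorDraws, draw_errors
from .margins import compute_mam, point_signed_distance
from .phantom import CaseGeometry, GeometryError, GridSpec

__all__ = [
    "SimulationParams",
    "SimulationRecord",
    "SweepResult",
    "run_simulation",
    "simulate_records",
    "run_sweep",
    "run_grid",
    "table1_permutations",
    "chunked",
    "RECORD_COLUMNS",
    "SWEEPABLE",
]

#: Table of swept parameter aliases -> SimulationParams field names.
SWEEPABLE = {
    "shrinkage": "shrinkage_mean",
    "satellite": "satellite_prob",
    "registration": "registration_sd_mm",
    "segmentation": "segmentation_sd_mm",
    "slice_thickness": "slice_thickness_mm",
}

RECORD_COLUMNS = [
    "d_tumor_mm",
    "margin_target_mm",
    "mam_true_mm",
    "mam_observed_mm",
    "covered_true",
    "e_mag_mm",
    "e_dir",
    "e_tumor_mm",
    "e_ablation_mm",
    "shrink_frac",
    "satellite",
    "d_satellite_mm",
]

#: Parameter sets of the reference study conditions.
TABLE1 = {
    "shrinkage_mean": (0.0, 0.1, 0.2, 0.3),
    "satellite_prob": (0.0, 0.25, 0.5, 0.75, 1.0),
    "registration_sd_mm": (1.0, 2.0, 3.0, 4.0, 5.0),
    "segmentation_sd_mm": (1.0, 2.0, 3.0, 4.0, 5.0),
    "slice_thickness_mm": (1.0, 2.0, 3.0, 4.0, 5.0),
}


@dataclass(frozen=True)
class SimulationParams:
    """One permutation of the error/biology parameters plus sampling setup.

    Defaults are the all-minimal baseline: no biology, 1 mm technical
    errors, 1 mm slices, tumors of 10-30 mm with target margins of
    -5 to 10 mm on an 80 mm cube at 1 mm isotropic resolution.
    """

    shrinkage_mean: float = 0.0
    shrinkage_sd: float = 0.05
    satellite_prob: float = 0.0
    registration_sd_mm: float = 1.0
    segmentation_sd_mm: float = 1.0
    slice_thickness_mm: float = 1.0
    tumor_range_mm: tuple[float, float] = (10.0, 30.0)
    margin_range_mm: tuple[float, float] = (-5.0, 10.0)
    shape_kind: str = "sphere"
    n_sims: int = 10_000
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if not 0.0 <= self.shrinkage_mean < 1.0:
            raise ValueError("shrinkage_mean must be in [0, 1)")
        if self.shrinkage_sd < 0.0:
            raise ValueError("shrinkage_sd must be non-negative")
        if not 0.0 <= self.satellite_prob <= 1.0:
            raise ValueError("satellite_prob must be in [0, 1]")
        if self.registration_sd_mm < 0 or self.segmentation_sd_mm < 0:
            raise ValueError("error standard deviations must be non-negative")
        if self.slice_thickness_mm < min(self.grid.spacing):
            raise ValueError("slice thickness below in-plane resolution")
        for lo, hi in (self.tumor_range_mm, self.margin_range_mm):
            if lo > hi:
                raise ValueError("invalid range (lo > hi)")

    def in_reference_sets(self) -> bool:
        """True when every error parameter sits in the reference value sets."""
        return all(
            getattr(self, name) in values for name, values in TABLE1.items()
        )

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {"shape": self.grid.shape, "spacing": self.grid.spacing}
        return d


@dataclass(frozen=True)
class SimulationRecord:
    """One simulated case with its true and observed margins."""

    case: CaseGeometry
    draws: ErrorDraws
    mam_true_mm: float
    mam_observed_mm: float

    @property
    def covered_true(self) -> bool:
        return self.mam_true_mm > 0.0

    def to_row(self) -> dict:
        return {
            "d_tumor_mm": self.case.d_tumor_mm,
            "margin_target_mm": self.case.margin_target_mm,
            "mam_true_mm": self.mam_true_mm,
            "mam_observed_mm": self.mam_observed_mm,
            "covered_true": self.covered_true,
            "e_mag_mm": self.draws.e_mag_mm,
            "e_dir": self.draws.e_dir_name,
            "e_tumor_mm": self.draws.e_tumor_mm,
            "e_ablation_mm": self.draws.e_ablation_mm,
            "shrink_frac": self.draws.shrink_frac,
            "satellite": self.draws.satellite,
            "d_satellite_mm": self.draws.d_satellite_mm,
        }


def _case_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def run_simulation(
    params: SimulationParams, rng: np.random.Generator
) -> SimulationRecord:
    """Run the eight-step pipeline for a single case.

    Geometry failures (a satellite or shift leaving the grid) redraw the
    whole case from the same stream; the caller's accounting sees one
    record either way.
    """
    for _attempt in range(100):
        try:
            return _run_once(params, rng)
        except GeometryError:
            continue
    raise GeometryError("repeated geometry failures; grid too small for params")


def _run_once(params: SimulationParams, rng) -> SimulationRecord:
    geom = phantom.sample_case(params, rng)
    draws = draw_errors(params, rng)
    grid = params.grid
    tumor_solid, ablation_solid = phantom.case_solids(geom)
    tumor_img = tumor_solid.rasterize(grid, "tumor_imaged")
    ablation_img = ablation_solid.rasterize(grid, "ablation_imaged")
    if tumor_img.is_empty:
        raise GeometryError("tumor rasterized empty")

    # true tumor: biology only
    tumor_true = phantom.apply_shrinkage(tumor_img, draws.shrink_frac)
    tumor_true = phantom.add_satellite(
        tumor_true, draws.satellite, draws.d_satellite_mm, rng
    )
    mam_true = compute_mam(tumor_true, ablation_img).mam_mm

    # imaged masks: technical errors only
    ablation_obs = error_models.apply_registration_shift(
        ablation_img, draws.e_mag_mm, draws.e_dir, solid=ablation_solid
    )
    tumor_obs = error_models.apply_segmentation_noise(tumor_img, draws.e_tumor_mm)
    ablation_obs = error_models.apply_segmentation_noise(
        ablation_obs, draws.e_ablation_mm
    )
    if params.slice_thickness_mm > grid.spacing[2]:
        tumor_obs = error_models.resample_slice_thickness(
            tumor_obs, params.slice_thickness_mm
        )
        ablation_obs = error_models.resample_slice_thickness(
            ablation_obs, params.slice_thickness_mm
        )

    if tumor_obs.is_empty:
        # tumor eroded/resampled away: point-tumor limit at the grid centre
        mam_obs = point_signed_distance(ablation_obs, (0.0, 0.0, 0.0))
        if not np.isfinite(mam_obs):
            mam_obs = 0.0
    else:
        mam_obs = compute_mam(tumor_obs, ablation_obs).mam_mm
    return SimulationRecord(geom, draws, mam_true, mam_obs)


def simulate_records(
    params: SimulationParams,
    n_sims: int | None = None,
    seed: int | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_sims`` independent cases and return the tidy record table."""
    n = params.n_sims if n_sims is None else int(n_sims)
    master = params.seed if seed is None else int(seed)
    it: Iterable[int] = range(n)
    if progress:
        from tqdm import tqdm  # soft dependency, only for interactive use

        it = tqdm(it, total=n, desc="simulating")
    rows = [
        run_simulation(params, _case_rng(master, i)).to_row() for i in it
    ]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df


@dataclass
class SweepResult:
    """A fitted A0 estimate for one parameter permutation."""

    params: SimulationParams
    varied: str | None
    value: float | None
    estimate: "a0sim.estimation.A0Estimate"  # noqa: F821 - forward ref
    records: pd.DataFrame | None = None

    @property
    def x_a0_mm(self) -> float:
        return self.estimate.x_a0_mm


def _fit(records: pd.DataFrame, **fit_kw):
    from .estimation import estimate_a0

    return estimate_a0(records, **fit_kw)


def run_sweep(
    base: SimulationParams,
    vary: str | None = None,
    values: Sequence[float] | None = None,
    n_sims: int | None = None,
    seed: int | None = None,
    keep_records: bool = True,
    progress: bool = False,
    **fit_kw,
) -> list[SweepResult]:
    """One-factor-at-a-time sweep with all other parameters at ``base``.

    With ``vary=None`` a single baseline permutation is run.
    """
    if vary is None:
        combos = [(None, None, base)]
    else:
        name = SWEEPABLE.get(vary, vary)
        if name not in SWEEPABLE.values():
            raise ValueError(
                f"unknown sweep parameter {vary!r}; choose from {sorted(SWEEPABLE)}"
            )
        if not values:
            raise ValueError("values required when vary is given")
        combos = [(vary, v, base.replace(**{name: float(v)})) for v in values]
    out = []
    for varied, value, params in combos:
        records = simulate_records(params, n_sims=n_sims, seed=seed, progress=progress)
        est = _fit(records, **fit_kw)
        out.append(
            SweepResult(params, varied, value, est, records if keep_records else None)
        )
    return out


def run_grid(
    base: SimulationParams,
    seg_values: Sequence[float],
    reg_values: Sequence[float],
    n_sims: int | None = None,
    seed: int | None = None,
    keep_records: bool = False,
    **fit_kw,
) -> tuple[pd.DataFrame, list[SweepResult]]:
    """Cartesian segmentation x registration grid of A0 thresholds.

    Returns the x_a0 matrix (rows: segmentation error, columns:
    registration error) and the per-cell results.
    """
    cells = []
    for seg in seg_values:
        for reg in reg_values:
            params = base.replace(
                segmentation_sd_mm=float(seg), registration_sd_mm=float(reg)
            )
            records = simulate_records(params, n_sims=n_sims, seed=seed)
            est = _fit(records, **fit_kw)
            cells.append(
                SweepResult(params, "segmentation x registration", (seg, reg),
                            est, records if keep_records else None)
            )
    matrix = pd.DataFrame(
        np.array([c.x_a0_mm for c in cells]).reshape(len(seg_values), len(reg_values)),
        index=pd.Index(seg_values, name="segmentation_sd_mm"),
        columns=pd.Index(reg_values, name="registration_sd_mm"),
    )
    return matrix, cells


def table1_permutations(
    base: SimulationParams | None = None, **overrides
) -> list[SimulationParams]:
    """Enumerate the full Cartesian product of the reference parameter sets.

    The full product is 4 x 5 x 5 x 5 x 5 = 2500 permutations; use
    :func:`chunked` to split it for batch execution.
    """
    base = base or SimulationParams()
    table = dict(TABLE1, **overrides)
    perms = []
    for shr in table["shrinkage_mean"]:
        for sat in table["satellite_prob"]:
            for reg in table["registration_sd_mm"]:
                for seg in table["segmentation_sd_mm"]:
                    for thk in table["slice_thickness_mm"]:
                        perms.append(
                            base.replace(
                                shrinkage_mean=shr,
                                satellite_prob=sat,
                                registration_sd_mm=reg,
                                segmentation_sd_mm=seg,
                                slice_thickness_mm=thk,
                            )
                        )
    return perms


def chunked(seq: Sequence, size: int) -> Iterator[list]:
    """Split a sequence into consecutive chunks of at most ``size``."""
    if size < 1:
        raise ValueError("chunk size must be >= 1")
    for i in range(0, len(seq), size):
        yield list(seq[i : i + size])
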