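"""Summary figures and the 5-mm reliability verdict.

Report functions consume persisted estimates (or in-memory results);
they never re-run simulations, so figures regenerate deterministically
from stored outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import A0Estimate

__all__ = [
    "ReliabilityVerdict",
    "verdict",
    "plot_coverage_curve",
    "plot_coverage_curves",
    "plot_a0_contour",
]


@dataclass(frozen=True)
class ReliabilityVerdict:
    """Is the conventional 5-mm observed-margin rule reliable?"""

    x_a0_mm: float
    five_mm_reliable: bool
    p_coverage_at_5mm: float

    def to_dict(self) -> dict:
        return {
            "x_a0_mm": self.x_a0_mm,
            "five_mm_reliable": self.five_mm_reliable,
            "p_coverage_at_5mm": self.p_coverage_at_5mm,
        }


def verdict(estimate: A0Estimate) -> ReliabilityVerdict:
    """Judge the 5-mm rule against a fitted estimate (boundary inclusive)."""
    return ReliabilityVerdict(
        x_a0_mm=estimate.x_a0_mm,
        five_mm_reliable=bool(estimate.x_a0_mm <= 5.0),
        p_coverage_at_5mm=estimate.p_coverage_at_5mm,
    )


def _require_matplotlib():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_coverage_curve(estimate: A0Estimate, ax=None, label: str | None = None):
    """One fitted sigmoid over observed MAM in [-5, 10] mm."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.linspace(-5.0, 10.0, 301)
    if estimate.separation_fallback:
        warnings.warn("separated fit: plotting a step at the fallback threshold")
        y = (x >= estimate.x_a0_mm).astype(float)
    else:
        y = estimate.predict(x)
    (line,) = ax.plot(x, y, label=label)
    ax.axhline(estimate.p_target, color="0.6", ls="--", lw=0.8)
    if np.isfinite(estimate.x_a0_mm) and -5 <= estimate.x_a0_mm <= 10:
        ax.plot(
            [estimate.x_a0_mm], [estimate.p_target], "o",
            color=line.get_color(), ms=5,
        )
    ax.set_xlabel("observed MAM (mm)")
    ax.set_ylabel("P(true MAM > 0)")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_coverage_curves(
    sweep_results: Sequence, path=None, title: str | None = None
):
    """Fitted sigmoids for a sweep, one curve per parameter value.

    ``sweep_results`` is a sequence of objects with ``estimate`` and
    ``value`` attributes (e.g. :class:`~a0sim.experiment.SweepResult`).
    """
    if len(sweep_results) == 0:
        raise ValueError("no sweep results to plot")
    plt = _require_matplotlib()
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for res in sweep_results:
        est = res.estimate
        if est is None:
            warnings.warn(f"missing fit for value {getattr(res, 'value', '?')}")
            continue
        if res.value is None:
            label = "baseline"
        elif isinstance(res.value, (list, tuple)):
            label = f"{res.varied} = {tuple(res.value)}"
        else:
            label = f"{res.varied} = {res.value:g}"
        label += f" (A0 = {est.x_a0_reported:.1f} mm)"
        plot_coverage_curve(est, ax=ax, label=label)
    ax.legend(loc="lower right", fontsize=8)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(str(path), dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_a0_contour(matrix: pd.DataFrame, path=None):
    """Filled contour of the A0 threshold over segmentation x registration error.

    The 5 mm level line is drawn explicitly; NaN cells are masked with a
    warning.  Requires at least a 2 x 2 matrix.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("contour requires at least a 2x2 matrix")
    plt = _require_matplotlib()
    z = np.ma.masked_invalid(matrix.to_numpy(dtype=float))
    if z.mask.any():
        warnings.warn("NaN cells masked in contour plot")
    fig, ax = plt.subplots(figsize=(6, 5))
    x = matrix.columns.to_numpy(dtype=float)
    y = matrix.index.to_numpy(dtype=float)
    cf = ax.contourf(x, y, z, levels=12, cmap="viridis")
    fig.colorbar(cf, ax=ax, label="A0 threshold (mm)")
    if z.min() < 5.0 < z.max():
        cs = ax.contour(x, y, z, levels=[5.0], colors="white", linewidths=2)
        ax.clabel(cs, fmt="%g mm")
    ax.set_xlabel("registration error (mm)")
    ax.set_ylabel("segmentation error (mm)")
    ax.set_title("A0 threshold (mm)")
    if path is not None:
        fig.savefig(str(path), dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
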