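"""Model/results surface for A0 threshold analysis.

`A0Model` wraps a table of simulated (observed MAM, true coverage)
records — either supplied directly or generated from a
:class:`~a0sim.experiment.SimulationParams` — and `fit()` returns an
:class:`A0Results` with the logistic coefficients, the A0 threshold,
the 5-mm reliability statistic, a text `summary()` and plotting.

Example
-------
>>> from a0sim import A0Model, SimulationParams
>>> model = A0Model.from_params(SimulationParams(seed=1), n_sims=2000)
>>> res = model.fit()
>>> round(res.x_a0_mm, 1)  # doctest: +SKIP
3.4
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import A0Estimate, estimate_a0
from .experiment import SimulationParams, simulate_records

__all__ = ["A0Model", "A0Results"]


class A0Model:
    """Logistic coverage model for the A0 ablation threshold.

    Parameters
    ----------
    records
        Tidy record table with at least ``mam_observed_mm`` and
        ``covered_true`` columns (``e_mag_mm`` is needed for the
        registration-exclusion variant).
    params
        The simulation parameters that produced the records, if known.
    """

    def __init__(self, records: pd.DataFrame, params: SimulationParams | None = None):
        missing = {"mam_observed_mm", "covered_true"} - set(records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        self.records = records
        self.params = params

    @classmethod
    def from_params(
        cls,
        params: SimulationParams | None = None,
        n_sims: int | None = None,
        seed: int | None = None,
        progress: bool = False,
    ) -> "A0Model":
        """Simulate the record table for ``params`` and build the model."""
        params = params or SimulationParams()
        records = simulate_records(params, n_sims=n_sims, seed=seed, progress=progress)
        return cls(records, params)

    @property
    def nobs(self) -> int:
        return len(self.records)

    def fit(
        self,
        p_target: float = 0.99,
        registration_cutoff_mm: float | None = None,
        ridge_penalty: float = 0.0,
    ) -> "A0Results":
        """Fit the coverage curve and solve for the A0 threshold."""
        est = estimate_a0(
            self.records,
            p_target=p_target,
            registration_cutoff_mm=registration_cutoff_mm,
            ridge_penalty=ridge_penalty,
        )
        return A0Results(self, est)


class A0Results:
    """Fitted A0 threshold with diagnostics."""

    def __init__(self, model: A0Model, estimate: A0Estimate):
        self.model = model
        self.estimate = estimate

    # -- statsmodels-flavoured accessors ---------------------------------
    @property
    def params(self) -> np.ndarray:
        """Logistic coefficients ``[beta0, beta1]`` (NaN under fallback)."""
        return np.array([self.estimate.beta0, self.estimate.beta1])

    @property
    def bse(self) -> np.ndarray:
        return np.array(self.estimate.beta_se)

    @property
    def x_a0_mm(self) -> float:
        return self.estimate.x_a0_mm

    @property
    def p_coverage_at_5mm(self) -> float:
        return self.estimate.p_coverage_at_5mm

    @property
    def n_used(self) -> int:
        return self.estimate.n_used

    @property
    def n_excluded(self) -> int:
        return self.estimate.n_excluded

    def predict(self, x) -> np.ndarray:
        """Fitted coverage probability at observed MAM ``x`` (mm)."""
        return self.estimate.predict(x)

    def verdict(self):
        """Reliability verdict for the conventional 5-mm margin rule."""
        from .report import verdict

        return verdict(self.estimate)

    def plot_coverage_curve(self, ax=None, label: str | None = None):
        """Plot the fitted sigmoid with the target-probability crossing."""
        from .report import plot_coverage_curve

        return plot_coverage_curve(self.estimate, ax=ax, label=label)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "A0 threshold estimation (logistic coverage model)",
            "=" * 58,
            f"records used:            {e.n_used}",
            f"records excluded:        {e.n_excluded}",
            f"target probability:      {e.p_target:.2%}",
        ]
        if e.separation_fallback:
            lines += [
                "fit:                     empirical binned fallback "
                "(data separated)",
            ]
        else:
            lines += [
                f"beta0 (intercept):       {e.beta0: .4f}  (se {e.beta_se[0]:.4f})",
                f"beta1 (per mm):          {e.beta1: .4f}  (se {e.beta_se[1]:.4f})",
            ]
        if e.ridge_penalty:
            lines.append(f"ridge penalty:           {e.ridge_penalty}")
        lines += [
            f"A0 threshold x_A0:       {e.x_a0_reported:.1f} mm",
            f"P(covered | obs >= 5mm): {e.p_coverage_at_5mm:.4f}",
            f"5-mm rule reliable:      {'yes' if e.x_a0_mm <= 5.0 else 'no'}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<A0Results x_a0={self.estimate.x_a0_mm:.2f} mm, "
            f"n={self.estimate.n_used}>"
        )
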