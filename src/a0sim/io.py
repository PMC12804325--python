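"""Persistence of simulation results: per-case CSV, estimate JSON, manifest."""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .estimation import A0Estimate
from .experiment import RECORD_COLUMNS, SimulationParams, SweepResult

__all__ = [
    "save_records",
    "load_records",
    "save_estimate",
    "load_estimate",
    "save_sweep",
    "load_sweep_estimates",
    "save_manifest",
]


def _slug(result: SweepResult, i: int) -> str:
    if result.varied is None:
        return "baseline"
    name = str(result.varied).replace(" ", "").replace("x", "_x_")
    return f"{name}_{i:02d}"


def save_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def load_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_estimate(
    estimate: A0Estimate, params: SimulationParams | None, path, **extra
) -> None:
    payload = {"estimate": estimate.to_dict(), **extra}
    if params is not None:
        payload["params"] = params.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def load_estimate(path) -> dict:
    return json.loads(Path(path).read_text())


def save_sweep(
    results: Sequence[SweepResult], outdir, save_record_tables: bool = True
) -> list[Path]:
    """Write one estimate JSON (and optional record CSV) per permutation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, res in enumerate(results):
        slug = _slug(res, i)
        jpath = outdir / f"{slug}.json"
        save_estimate(
            res.estimate, res.params, jpath,
            varied=res.varied, value=res.value, seed=res.params.seed,
        )
        written.append(jpath)
        if save_record_tables and res.records is not None:
            cpath = outdir / f"{slug}_records.csv"
            save_records(res.records, cpath)
            written.append(cpath)
    return written


def load_sweep_estimates(directory) -> list[dict]:
    """Load every estimate JSON in a results directory, sorted by name."""
    return [
        load_estimate(p)
        for p in sorted(Path(directory).glob("*.json"))
        if p.name != "manifest.json"
    ]


def save_manifest(outdir, params: SimulationParams, seed: int | None = None) -> Path:
    import numpy
    import scipy

    manifest = {
        "a0sim_version": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "params": params.to_dict(),
        "seed": params.seed if seed is None else seed,
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    return path
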