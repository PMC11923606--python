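"""Structured outputs: tidy CSV tables and the JSON run manifest.

All tables are comma-separated UTF-8 with a header row, '.' decimal, and NA
for undefined values (e.g. sigma on empty-group steps).  Every output
directory carries a manifest tying its files to the exact parameters, seed
and package version that produced them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .engine import IndividualRecord, SimResult
from .evolution import FitnessSurface, GradientEstimate
from .params import SimParams

__all__ = [
    "RunManifest",
    "sim_result_frame",
    "lifetime_frame",
    "surface_frame",
    "gradient_frame",
    "write_tables",
]


@dataclass
class RunManifest:
    """Provenance of one command invocation."""

    command: str
    params: dict
    seed: int
    outdir: str
    version: str = field(default_factory=lambda: __version__)
    extra: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def resolved_params(self) -> SimParams:
        return SimParams.from_dict(self.params)


def sim_result_frame(result: SimResult) -> pd.DataFrame:
    """One summary row per run."""
    return pd.DataFrame(
        [
            {
                "r": result.params.r,
                "d": result.params.d,
                "lam": result.params.lam,
                "K": result.params.K,
                "f": result.params.f,
                "mu": result.params.mu,
                "nu": result.params.nu,
                "seed": result.params.seed,
                "mean_G": result.mean_G,
                "mean_sigma": result.mean_sigma,
                "mean_N": result.group_size["mean"],
                "var_N": result.group_size["variance"],
                "cv_N": result.group_size["cv"],
                "n_recorded_steps": result.n_recorded_steps,
                "n_empty_steps": result.n_empty_steps,
                "n_recruits": result.n_recruits_recorded,
                "mean_task_changes": (
                    np.nan if result.mean_task_changes is None else result.mean_task_changes
                ),
            }
        ]
    )


def lifetime_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    """One row per completed lifetime; change ages joined with ';'."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "birth_time": r.birth_time,
                "lifespan": r.lifespan,
                "n_task_changes": r.n_task_changes,
                "change_ages": ";".join(str(a) for a in r.change_ages),
            }
            for r in records
        ]
    )


def trace_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    """Long-format experience traces: one row per (individual, age, task)."""
    rows = []
    for r in records:
        if r.experience_trace is None:
            continue
        for age, E in enumerate(r.experience_trace, start=1):
            for k, e in enumerate(E):
                rows.append({"id": r.id, "age": age, "task": k, "experience": e})
    return pd.DataFrame(rows)


def surface_frame(surface: FitnessSurface) -> pd.DataFrame:
    return surface.to_frame()


def fstar_frame(surface: FitnessSurface, c_grid) -> pd.DataFrame:
    from .evolution import optimal_responsiveness

    return pd.DataFrame(
        [{"c": float(c), "f_star": optimal_responsiveness(surface, c)} for c in c_grid]
    )


def gradient_frame(est: GradientEstimate) -> pd.DataFrame:
    rows = [
        {
            "which": est.which,
            "f_star": est.f_star,
            "c": est.c,
            "pair": j,
            "gain_pct": g,
            "aggregate": False,
        }
        for j, g in enumerate(est.per_pair_pct)
    ]
    rows.append(
        {
            "which": est.which,
            "f_star": est.f_star,
            "c": est.c,
            "pair": -1,
            "gain_pct": est.gain_pct,
            "aggregate": True,
        }
    )
    return pd.DataFrame(rows)


def write_tables(frames: dict[str, pd.DataFrame], outdir: str | Path, manifest: RunManifest) -> list[Path]:
    """Write each named DataFrame as <name>.csv plus manifest.json in outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in frames.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, na_rep="NA")
        written.append(path)
    written.append(manifest.save(outdir / "manifest.json"))
    return written
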