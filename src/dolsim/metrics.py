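"""Group- and individual-level summary statistics.

Work per capita G = sum(L)/N is the mean competence-weighted output per group
member, bounded in [1, 2].  Labour variation sigma measures how unevenly that
work is spread over tasks: the default variant is the standard deviation of
the labour shares s_k = L_k / sum(L) around the uniform share 1/K,
sigma = sqrt(sum_k (s_k - 1/K)^2), which is zero iff the shares are uniform
and invariant to rescaling L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabourDistribution, _as_labour

__all__ = [
    "LabourSummary",
    "work_per_capita",
    "labour_sigma",
    "labour_summary",
    "task_change_stats",
    "group_size_stats",
]


@dataclass
class LabourSummary:
    G: float
    sigma: float
    shares: np.ndarray


def work_per_capita(L, N: int) -> float:
    """G = sum_k L_k / N.  Undefined (raises) for an empty group."""
    if N <= 0:
        raise ValueError("work per capita is undefined for an empty group (N=0)")
    return float(_as_labour(L).sum() / N)


def labour_sigma(L, K: int | None = None, variant: str = "sqrt_share") -> float:
    """Dispersion of the labour shares around the uniform share 1/K.

    ``sqrt_share`` (default) returns sqrt(sum_k (s_k - 1/K)^2); ``sum_sq``
    returns the same sum of squares without the root.  Both are zero iff the
    shares are exactly uniform, permutation-invariant, and scale-invariant in L.
    """
    L = _as_labour(L)
    if K is None:
        K = L.shape[-1]
    total = L.sum()
    if total <= 0:
        raise ValueError("labour variation is undefined when total labour is zero")
    shares = L / total
    ss = float(np.sum((shares - 1.0 / K) ** 2))
    if variant == "sqrt_share":
        return float(np.sqrt(ss))
    if variant == "sum_sq":
        return ss
    raise ValueError(f"unknown sigma variant {variant!r}")


def labour_summary(L, N: int, variant: str = "sqrt_share") -> LabourSummary:
    L = _as_labour(L)
    return LabourSummary(
        G=work_per_capita(L, N),
        sigma=labour_sigma(L, variant=variant),
        shares=L / L.sum(),
    )


def task_change_stats(records, age_bin: int = 10) -> dict:
    """Task-change statistics over completed lifetimes.

    Returns a dict with ``mean_changes_per_lifetime`` (mean over records of
    the number of re-evaluations whose outcome differed from the current task)
    and ``by_age``, a DataFrame with one row per age bin: the number of
    changes made in the bin, the individual-steps of exposure, and the change
    frequency per time step (changes / exposure).  The initial task assignment
    at birth is not a change.
    """
    records = list(records)
    if not records:
        raise ValueError("task_change_stats requires at least one complete record")
    n_changes = np.array([rec.n_task_changes for rec in records], dtype=float)
    lifespans = np.array([rec.lifespan for rec in records], dtype=float)
    max_age = int(lifespans.max()) if len(lifespans) else 0
    n_bins = max(1, int(np.ceil((max_age + 1) / age_bin)))
    changes = np.zeros(n_bins)
    exposure = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * age_bin
    for rec in records:
        # steps lived inside each bin
        lived = np.clip(rec.lifespan - edges[:-1], 0, age_bin)
        exposure += lived
        for a in rec.change_ages:
            changes[min(int(a) // age_bin, n_bins - 1)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(exposure > 0, changes / exposure, np.nan)
    by_age = pd.DataFrame(
        {
            "age_bin_start": edges[:-1],
            "changes": changes.astype(int),
            "exposure_steps": exposure,
            "change_rate": rate,
        }
    )
    return {
        "mean_changes_per_lifetime": float(n_changes.mean()),
        "mean_lifespan": float(lifespans.mean()),
        "n_records": len(records),
        "by_age": by_age,
    }


def group_size_stats(N_trajectory) -> dict:
    """Sample mean, variance and coefficient of variation of group size.

    At stationarity the immigration-death chain is Poisson(r/d), so mean and
    variance should both approach r/d and CV = (r/d)^(-1/2) — larger groups
    fluctuate less in relative terms.
    """
    N = np.asarray(N_trajectory, dtype=float)
    if N.size < 2:
        raise ValueError("group_size_stats requires at least two recorded steps")
    mean = float(N.mean())
    var = float(N.var(ddof=1))
    cv = float(np.sqrt(var) / mean) if mean > 0 else float("nan")
    return {"mean": mean, "variance": var, "cv": cv}
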