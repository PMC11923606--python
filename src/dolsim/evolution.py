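"""Fitness surfaces over responsiveness and selection gradients.

Group fitness trades total output against labour imbalance, W = G - c*sigma:
a group earns the time-averaged work per capita G but pays a penalty c per
unit of labour variation sigma.  The optimal responsiveness f*(c) is found by
grid search over simulated (f -> G, sigma) surfaces, and selection gradients
on the learning and forgetting rates are estimated at f* by paired
perturbation runs sharing common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import run_simulation
from .params import SimParams

__all__ = [
    "FitnessSurface",
    "GradientEstimate",
    "fitness",
    "derive_seed",
    "sweep_responsiveness",
    "optimal_responsiveness",
    "selection_gradient",
    "learning_rate_sweep",
]


def derive_seed(root: int, *indices: int) -> int:
    """Deterministic child seed < 2**31 from a root seed and stream indices."""
    ss = np.random.SeedSequence([int(root), *map(int, indices)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def fitness(G, sigma, c: float):
    """W = G - c*sigma (elementwise for array inputs)."""
    if c < 0:
        raise ValueError(f"variation cost c must be >= 0, got {c}")
    return G - c * np.asarray(sigma) if np.ndim(sigma) else G - c * sigma


@dataclass
class FitnessSurface:
    """Simulated (f -> G, sigma) surface, with per-seed replicates.

    ``G`` and ``sigma`` have shape (len(f_grid), n_seeds); replicate j uses the
    same seed at every f, so surfaces are smoothed by common random numbers.
    """

    f_grid: np.ndarray
    G: np.ndarray
    sigma: np.ndarray
    seeds: np.ndarray
    params: SimParams  # base parameters (f field ignored)

    @property
    def n_seeds(self) -> int:
        return self.G.shape[1]

    @property
    def mean_G(self) -> np.ndarray:
        return self.G.mean(axis=1)

    @property
    def mean_sigma(self) -> np.ndarray:
        return self.sigma.mean(axis=1)

    def W(self, c: float) -> np.ndarray:
        return fitness(self.mean_G, self.mean_sigma, c)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: one row per (f, seed) plus aggregate rows."""
        rows = []
        for i, f in enumerate(self.f_grid):
            for j in range(self.n_seeds):
                rows.append(
                    {"f": f, "seed": int(self.seeds[j]), "G": self.G[i, j],
                     "sigma": self.sigma[i, j], "aggregate": False}
                )
            rows.append(
                {"f": f, "seed": -1, "G": self.mean_G[i],
                 "sigma": self.mean_sigma[i], "aggregate": True}
            )
        return pd.DataFrame(rows)


def sweep_responsiveness(
    params_base: SimParams,
    f_grid,
    n_seeds: int = 5,
    base_seed: int | None = None,
) -> FitnessSurface:
    """Run the simulation at every (f, replicate) and collect G and sigma.

    Replicate j's seed depends only on (base_seed, j), never on f, so every
    grid point of a replicate shares its demography — differences along f are
    then due to f, not to demographic luck.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.ndim != 1 or f_grid.size == 0:
        raise ValueError("f_grid must be a non-empty 1-D grid")
    if np.any((f_grid < 0) | (f_grid > 1)):
        raise ValueError("responsiveness grid must lie in [0, 1]")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if base_seed is None:
        base_seed = params_base.seed
    seeds = np.array([derive_seed(base_seed, j) for j in range(n_seeds)], dtype=np.int64)
    G = np.empty((f_grid.size, n_seeds))
    sigma = np.empty_like(G)
    for i, f in enumerate(f_grid):
        for j, seed in enumerate(seeds):
            res = run_simulation(params_base.replace(f=float(f), seed=int(seed)))
            G[i, j] = res.mean_G
            sigma[i, j] = res.mean_sigma
    return FitnessSurface(f_grid=f_grid, G=G, sigma=sigma, seeds=seeds, params=params_base)


def optimal_responsiveness(surface: FitnessSurface, c: float) -> float:
    """f* = grid argmax of W(f; c) = mean_G(f) - c*mean_sigma(f).

    Exact ties go to the smallest f (least switching); recomputation on the
    same surface is deterministic.
    """
    W = surface.W(c)
    return float(surface.f_grid[int(np.argmax(W))])


@dataclass
class GradientEstimate:
    """Paired-replicate estimate of a relative fitness change, in percent."""

    gain_pct: float
    se_pct: float
    per_pair_pct: np.ndarray
    which: str
    f_star: float
    c: float

    @property
    def n_pairs(self) -> int:
        return self.per_pair_pct.size


def selection_gradient(
    params_base: SimParams,
    f_star: float,
    which: str = "learning",
    delta: float = 0.1,
    c: float | None = None,
    n_seeds: int = 10,
    base_seed: int | None = None,
    nu_low: float = 0.05,
) -> GradientEstimate:
    """Relative fitness change (%) from a learning/forgetting perturbation at f*.

    ``learning`` bumps mu multiplicatively, mu -> (1+delta)*mu; ``forgetting``
    compares the base nu against ``nu_low`` (an improvement, since forgetting
    hurts).  Base and perturbed runs of each pair share a seed (common random
    numbers), so demography and evaluation schedules cancel out of the paired
    differences; the standard error reported is that of the paired estimates.
    """
    if which not in ("learning", "forgetting"):
        raise ValueError("which must be 'learning' or 'forgetting'")
    if which == "learning" and not delta > 0:
        raise ValueError("delta must be > 0 for a learning-rate bump")
    if c is None:
        c = params_base.c
    if base_seed is None:
        base_seed = params_base.seed
    base = params_base.replace(f=float(f_star))
    if which == "learning":
        perturbed = base.replace(mu=min(1.0, (1.0 + delta) * base.mu))
    else:
        perturbed = base.replace(nu=nu_low)
    gains = np.empty(n_seeds)
    for j in range(n_seeds):
        seed = derive_seed(base_seed, 7, j)
        rb = run_simulation(base.replace(seed=seed))
        rp = run_simulation(perturbed.replace(seed=seed))
        Wb = fitness(rb.mean_G, rb.mean_sigma, c)
        Wp = fitness(rp.mean_G, rp.mean_sigma, c)
        gains[j] = 100.0 * (Wp - Wb) / Wb
    se = float(gains.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else float("nan")
    return GradientEstimate(
        gain_pct=float(gains.mean()),
        se_pct=se,
        per_pair_pct=gains,
        which=which,
        f_star=float(f_star),
        c=float(c),
    )


def learning_rate_sweep(
    params_base: SimParams,
    mu_grid=(0.01, 0.02, 0.05, 0.1, 0.2),
    f_grid=None,
    c_grid=(0.0, 0.5, 1.0, 2.0, 3.0, 5.0),
    n_seeds: int = 5,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """f*(c) for each learning rate: one fresh surface per mu.

    Returns a tidy table with one row per (mu, c) and the corresponding f*.
    Faster learners are expected to tolerate more switching, so f* should
    (noisily) increase with mu at intermediate c.
    """
    if f_grid is None:
        f_grid = np.arange(0.0, 1.0001, 0.05)
    if base_seed is None:
        base_seed = params_base.seed
    rows = []
    for mu in mu_grid:
        surface = sweep_responsiveness(
            params_base.replace(mu=float(mu)), f_grid, n_seeds=n_seeds, base_seed=base_seed
        )
        for c in c_grid:
            rows.append({"mu": float(mu), "c": float(c),
                         "f_star": optimal_responsiveness(surface, c)})
    return pd.DataFrame(rows)
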