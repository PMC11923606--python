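"""Elementary update rules of the division-of-labour model.

The model tracks a group of individuals, each performing one of K tasks.
Experience in the performed task grows with diminishing returns at rate mu and
decays exponentially at rate nu in the others; competence is 1 + experience,
bounded in [1, 2].  The group's labour distribution L sums the competences of
the individuals currently assigned to each task.  When an individual
re-evaluates its task it scores each task k as

    (1 - f) * p_k / sum_j p_j  +  f * (1 - L_k / sum_j L_j)

and adopts the argmax (ties broken uniformly at random): at f=0 it follows its
own competence only, at f=1 the group's unmet needs only.  In these score
functions L is the labour the individual weighs — for a group member, the
labour of the rest of the group (the engine removes the focal contribution
before scoring); for an arriving recruit, the labour of the group it joins.
Demography is an
immigration-death process — Poisson(r) naive recruits and Binomial(N, d)
deaths per step — whose stationary group size is Poisson-distributed with
mean N* = r/d.

Task indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimParams

__all__ = [
    "TIE_REL_TOL",
    "Individual",
    "LabourDistribution",
    "GroupState",
    "update_experience",
    "competence",
    "labour_distribution",
    "task_scores",
    "choose_task",
    "switching_threshold",
    "demographic_step",
    "initialize_group",
    "simulate_group_size",
]

#: Relative tolerance within which two task scores count as tied.  The analytic
#: tie point of the lone-specialist scenario (f = 0.25 at p=(2,1), L=(2,0))
#: makes exact float equality fragile.
TIE_REL_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Individual:
    """One group member (a read-only view onto the group's arrays)."""

    id: int
    birth_time: int
    experience: np.ndarray
    current_task: int
    task_change_times: list[int] = field(default_factory=list)
    next_update_time: float = np.inf


@dataclass
class LabourDistribution:
    """Per-task totals of competence-weighted work, L_k >= 0."""

    L: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)

    @property
    def total(self) -> float:
        return float(self.L.sum())

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.L, dtype=dtype)

    def __len__(self) -> int:
        return len(self.L)


def _as_labour(L) -> np.ndarray:
    if isinstance(L, LabourDistribution):
        return L.L
    return np.asarray(L, dtype=float)


class GroupState:
    """Current state of the group, stored as flat arrays over living members.

    Attributes
    ----------
    time : int
        Current time step t.
    experience : (N, K) float array
        Experience of each living individual in each task, in [0, 1].
    task : (N,) int array
        Current task of each individual, in {0..K-1}.
    birth_time, ids, n_changes : (N,) int arrays
    change_ages : list of lists
        Ages (steps since birth) at each task change, per individual.
    next_update : (N,) float array
        Scheduled time of the next task re-evaluation (event-queue mode).
    cumulative_recruits : int
        Total recruits since the simulation started.
    """

    __slots__ = (
        "K",
        "time",
        "experience",
        "task",
        "birth_time",
        "ids",
        "n_changes",
        "change_ages",
        "next_update",
        "cumulative_recruits",
        "_next_id",
    )

    def __init__(self, K: int, time: int = 0):
        self.K = int(K)
        self.time = int(time)
        self.experience = np.empty((0, self.K), dtype=float)
        self.task = np.empty(0, dtype=np.int64)
        self.birth_time = np.empty(0, dtype=np.int64)
        self.ids = np.empty(0, dtype=np.int64)
        self.n_changes = np.empty(0, dtype=np.int64)
        self.change_ages: list[list[int]] = []
        self.next_update = np.empty(0, dtype=float)
        self.cumulative_recruits = 0
        self._next_id = 0

    @property
    def size(self) -> int:
        """Group size N(t)."""
        return self.task.shape[0]

    @property
    def individuals(self) -> list[Individual]:
        """Materialize the members as :class:`Individual` views."""
        t0 = self.birth_time
        return [
            Individual(
                id=int(self.ids[i]),
                birth_time=int(t0[i]),
                experience=self.experience[i].copy(),
                current_task=int(self.task[i]),
                task_change_times=[int(t0[i] + a) for a in self.change_ages[i]],
                next_update_time=float(self.next_update[i]),
            )
            for i in range(self.size)
        ]

    def labour(self) -> np.ndarray:
        """Labour distribution L: per-task sums of current-task competences."""
        if not self.size:
            return np.zeros(self.K)
        p_cur = 1.0 + self.experience[np.arange(self.size), self.task]
        return np.bincount(self.task, weights=p_cur, minlength=self.K)

    def add_member(self, task: int, next_update: float = np.inf) -> int:
        """Append one naive individual performing `task`; returns its row index."""
        self.experience = np.vstack([self.experience, np.zeros((1, self.K))])
        self.task = np.append(self.task, np.int64(task))
        self.birth_time = np.append(self.birth_time, np.int64(self.time))
        self.ids = np.append(self.ids, np.int64(self._next_id))
        self.n_changes = np.append(self.n_changes, np.int64(0))
        self.change_ages.append([])
        self.next_update = np.append(self.next_update, float(next_update))
        self._next_id += 1
        self.cumulative_recruits += 1
        return self.size - 1

    def remove(self, keep: np.ndarray) -> list[tuple[int, int, int, list[int]]]:
        """Drop members where ``keep`` is False; return (id, birth, n_changes,
        change_ages) tuples of the removed, in storage order."""
        removed = [
            (int(self.ids[i]), int(self.birth_time[i]), int(self.n_changes[i]), self.change_ages[i])
            for i in np.flatnonzero(~keep)
        ]
        if removed:
            self.experience = self.experience[keep]
            self.task = self.task[keep]
            self.birth_time = self.birth_time[keep]
            self.ids = self.ids[keep]
            self.n_changes = self.n_changes[keep]
            self.change_ages = [a for a, k in zip(self.change_ages, keep) if k]
            self.next_update = self.next_update[keep]
        return removed


# ---------------------------------------------------------------------------
# elementary operations


def update_experience(E, performed: int, mu: float, nu: float) -> np.ndarray:
    """One experience update: learn at the performed task, forget at the rest.

    The performed element becomes (1-mu)*E + mu (diminishing returns toward the
    maximum of 1); every other element decays to (1-nu)*E.
    """
    if not 0 <= mu <= 1 or not 0 <= nu <= 1:
        raise ValueError(f"mu and nu must lie in [0, 1], got mu={mu}, nu={nu}")
    E = np.asarray(E, dtype=float)
    if not (0 <= performed < E.shape[-1]):
        raise IndexError(f"task index {performed} out of range for K={E.shape[-1]}")
    out = (1.0 - nu) * E
    out[performed] = (1.0 - mu) * E[performed] + mu
    return out


def competence(E) -> np.ndarray:
    """Competence p = 1 + E elementwise; naive baseline 1, maximum 2."""
    E = np.asarray(E, dtype=float)
    return 1.0 + E


def labour_distribution(group: GroupState) -> LabourDistribution:
    """Total competence-weighted work per task; all-zero for an empty group."""
    return LabourDistribution(group.labour())


def task_scores(p, L, f: float) -> np.ndarray:
    """Score each task as (1-f) * own-competence share + f * unmet group need.

    With an empty or fully idle group (sum L = 0) the group-need term is the
    uniform value 1 - 1/K for every task, which keeps the scores symmetric and
    reduces the choice to competence plus a random tie-break.
    """
    p = np.asarray(p, dtype=float)
    L = _as_labour(L)
    K = p.shape[-1]
    own = p / p.sum()
    total = L.sum()
    if total > 0:
        need = 1.0 - L / total
    else:
        need = np.full(K, 1.0 - 1.0 / K)
    return (1.0 - f) * own + f * need


def choose_task(p, L, f: float, rng: np.random.Generator, current: int | None = None) -> int:
    """Argmax of :func:`task_scores`; the choice is absolute — the best-scoring
    task is adopted regardless of how small the score gap is.

    Near-ties (within :data:`TIE_REL_TOL`) are broken uniformly at random,
    except that an individual re-evaluating its task (``current`` given) keeps
    its current task when that task is among the tied maxima: switching at
    exact indifference has no benefit and would otherwise shuttle coverage
    holes around the group forever at full responsiveness.  Arriving recruits
    have no current task and always randomize.
    """
    s = task_scores(p, L, f)
    m = s.max()
    tol = TIE_REL_TOL * max(1.0, abs(m))
    tied = np.flatnonzero(s >= m - tol)
    if tied.size == 1:
        return int(tied[0])
    if current is not None and current in tied:
        return int(current)
    return int(tied[rng.integers(tied.size)])


def switching_threshold(p, L, stay: int, switch_to: int) -> float:
    """Responsiveness at which the preferred task flips from `stay` to `switch_to`.

    Solves score_stay(f) = score_switch(f) in closed form; both scores are
    linear in f.  For the lone specialist p=(2, 1) facing an unattended second
    task, L=(2, 0), this returns exactly 0.25.  Returns nan if the scores never
    cross inside (0, 1).
    """
    p = np.asarray(p, dtype=float)
    L = _as_labour(L)
    own = p / p.sum()
    need = 1.0 - L / L.sum()
    # (1-f)*own_a + f*need_a = (1-f)*own_b + f*need_b
    d_own = own[stay] - own[switch_to]
    d_need = need[stay] - need[switch_to]
    denom = d_own - d_need
    if denom == 0:
        return float("nan")
    f_star = d_own / denom
    return float(f_star) if 0.0 < f_star < 1.0 else float("nan")


def demographic_step(
    group: GroupState,
    r: float,
    d: float,
    f: float,
    rng: np.random.Generator,
    rng_choice: np.random.Generator | None = None,
    dead_log: list | None = None,
) -> GroupState:
    """One demographic transition: deaths, then Poisson(r) naive arrivals.

    Each living individual independently dies with probability d (so deaths
    are Binomial(N, d)).  Each recruit arrives with zero experience and picks
    its initial task via :func:`choose_task` against the labour distribution
    it finds, recruits being inserted one at a time.  Removed individuals'
    lifetime tuples are appended to ``dead_log`` if given.
    """
    if rng_choice is None:
        rng_choice = rng
    n = group.size
    if n:
        keep = rng.random(n) >= d
        removed = group.remove(keep)
        if dead_log is not None:
            dead_log.extend(removed)
    n_new = rng.poisson(r)
    naive = np.ones(group.K)
    for _ in range(n_new):
        k = choose_task(naive, group.labour(), f, rng_choice)
        group.add_member(k)
    return group


def initialize_group(params: SimParams, rng_choice: np.random.Generator) -> GroupState:
    """Group at t=0: round(r/d) naive members, tasks assigned sequentially.

    Each founder picks via :func:`choose_task` against the labour contributed
    by those already placed, which spreads naive founders evenly over tasks
    up to random tie-breaks.
    """
    group = GroupState(params.K)
    n0 = int(round(params.equilibrium_size))
    naive = np.ones(params.K)
    for _ in range(n0):
        k = choose_task(naive, group.labour(), params.f, rng_choice)
        group.add_member(k)
    group.cumulative_recruits = 0  # founders are not recruits
    return group


def simulate_group_size(
    r: float,
    d: float,
    n_steps: int,
    burn_in: int = 0,
    n0: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Trajectory of the pure immigration-death chain N(t+1) = Bin(N, 1-d) + Poi(r).

    Tracks group size only (no tasks); returns the ``n_steps`` sizes after the
    burn-in.  The stationary distribution is Poisson(r/d), so the long-run
    mean and variance both approach N* = r/d.
    """
    rng = np.random.default_rng(rng)
    n = int(round(r / d)) if n0 is None else int(n0)
    out = np.empty(n_steps, dtype=np.int64)
    for t in range(burn_in + n_steps):
        n = rng.binomial(n, 1.0 - d) + rng.poisson(r)
        if t >= burn_in:
            out[t - burn_in] = n
    return out
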