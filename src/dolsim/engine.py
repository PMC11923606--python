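"""Simulation driver: burn-in, stepping, stopping rule and recording.

Each time step applies, in order: (1) demography — deaths, then Poisson
arrivals whose recruits pick an initial task on the labour distribution they
find; (2) task re-evaluations for the individuals whose update is due this
step, performed one at a time in uniformly random order with the labour
distribution refreshed after every switch (a ``simultaneous`` variant decides
all against the start-of-phase distribution); (3) the experience update for
every individual; (4) metric recording.  Sequential updating with refresh
approximates the continuous-time formulation, in which each decision sees the
current state of the group.

Every decision weighs the labour of the rest of the group — the focal
individual's own contribution is excluded before scoring.  This is what makes
stable allocations possible: the group settles into a distribution where no
individual can reduce the labour imbalance by moving (an ideal-free
distribution over tasks), and task changes are then triggered only by births
and deaths.  Were the focal contribution included, whoever sits on the
currently heavier task would always switch and the group would churn
indefinitely at high responsiveness.

Randomness is split over three named streams spawned from the run seed —
demography, scheduler (who is due, and in what order), and choice (tie
breaks) — so that paired runs differing only in learning parameters share
identical demography and evaluation schedules (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import TIE_REL_TOL, GroupState, initialize_group
from .metrics import group_size_stats, labour_sigma
from .params import SimParams

__all__ = [
    "RngStreams",
    "StepRecord",
    "IndividualRecord",
    "SimResult",
    "make_rng_streams",
    "step",
    "run_simulation",
    "run_lifetime_sample",
]


class RngStreams(NamedTuple):
    demography: np.random.Generator
    scheduler: np.random.Generator
    choice: np.random.Generator


def make_rng_streams(seed: int) -> RngStreams:
    """Three independent generator streams derived from one root seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return RngStreams(*(np.random.default_rng(s) for s in children))


@dataclass(frozen=True)
class StepRecord:
    """Post-burn-in per-step observation."""

    time: int
    N: int
    L: tuple[float, ...]
    G: float | None  # None when the group is empty
    sigma: float | None


@dataclass(frozen=True)
class IndividualRecord:
    """Lifetime summary of one individual whose whole life fell in the
    recorded window."""

    id: int
    birth_time: int
    lifespan: int
    n_task_changes: int
    change_ages: tuple[int, ...]
    experience_trace: np.ndarray | None = None  # (steps lived, K) if traced

    def __eq__(self, other):
        if not isinstance(other, IndividualRecord):
            return NotImplemented
        if (self.experience_trace is None) != (other.experience_trace is None):
            return False
        traces_equal = self.experience_trace is None or np.array_equal(
            self.experience_trace, other.experience_trace
        )
        return (
            self.id == other.id
            and self.birth_time == other.birth_time
            and self.lifespan == other.lifespan
            and self.n_task_changes == other.n_task_changes
            and self.change_ages == other.change_ages
            and traces_equal
        )


@dataclass
class SimResult:
    """Time-averaged outcome of one run."""

    params: SimParams
    mean_G: float
    mean_sigma: float
    group_size: dict
    n_recorded_steps: int
    n_empty_steps: int
    n_recruits_recorded: int
    n_evaluations: int
    n_individual_steps: int
    mean_task_changes: float | None = None
    individual_records: list[IndividualRecord] | None = None
    N_trajectory: np.ndarray | None = None

    @property
    def mean_eval_interval(self) -> float:
        """Realized mean number of individual-steps between task re-evaluations (~1/lam)."""
        return self.n_individual_steps / self.n_evaluations if self.n_evaluations else float("nan")


@dataclass
class _Accum:
    """Mutable per-run accumulators shared across steps."""

    G_sum: float = 0.0
    sigma_sum: float = 0.0
    n_metric_steps: int = 0
    n_empty: int = 0
    n_steps: int = 0
    n_evals: int = 0
    n_ind_steps: int = 0
    Ns: list = field(default_factory=list)
    dead: list = field(default_factory=list)  # (id, birth, n_changes, ages, death_time)


def _score_choose(p: list, L: list, f: float, rng: np.random.Generator,
                  current: int | None = None) -> int:
    """Pure-Python mirror of :func:`dolsim.core.choose_task` for the hot loop.

    Identical arithmetic (same operation order, same tie tolerance, same RNG
    consumption), but on small Python lists — for the K <= 5 regime this is
    several times faster than numpy small-array calls.
    """
    K = len(p)
    sp = sum(p)
    total = sum(L)
    if total > 0:
        scores = [(1.0 - f) * (p[k] / sp) + f * (1.0 - L[k] / total) for k in range(K)]
    else:
        uniform_need = f * (1.0 - 1.0 / K)
        scores = [(1.0 - f) * (p[k] / sp) + uniform_need for k in range(K)]
    m = max(scores)
    tol = TIE_REL_TOL * (abs(m) if abs(m) > 1.0 else 1.0)
    tied = [k for k in range(K) if scores[k] >= m - tol]
    if len(tied) == 1:
        return tied[0]
    if current is not None and current in tied:
        return current
    return tied[int(rng.integers(len(tied)))]


def _evaluate_one(group: GroupState, i: int, L: list, params: SimParams, rngs: RngStreams) -> None:
    """Re-evaluate individual i's task, keeping the running full L consistent.

    The individual weighs the labour of the *rest* of the group: its own
    current contribution is removed from L before scoring and the (possibly
    new) contribution added back afterwards.  If it is alone, the remainder
    sums to zero and the degenerate uniform need term applies — a lone
    individual never switches.
    """
    E_i = group.experience[i].tolist()
    old = int(group.task[i])
    if params.choice_mode == "uniform_random":
        k = int(rngs.choice.integers(params.K))
    else:
        p = [1.0 + e for e in E_i]
        L[old] -= p[old]
        k = _score_choose(p, L, params.f, rngs.choice, current=old)
        L[old] += p[old]
    if k != old:
        L[old] -= 1.0 + E_i[old]
        L[k] += 1.0 + E_i[k]
        group.task[i] = k
        group.n_changes[i] += 1
        group.change_ages[i].append(group.time - int(group.birth_time[i]))


def step(
    group: GroupState,
    params: SimParams,
    rngs: RngStreams,
    acc: _Accum | None = None,
    record: bool = False,
) -> StepRecord | None:
    """Advance the group by one time step (mutating it).

    Deterministic given the RNG stream states.  Returns a :class:`StepRecord`
    if ``record`` is true, with G and sigma None for an empty group.
    """
    group.time += 1
    t = group.time

    # --- demography: deaths, then arrivals
    n = group.size
    if n:
        keep = rngs.demography.random(n) >= params.d
        removed = group.remove(keep)
        if acc is not None and removed:
            acc.dead.extend((i, b, nc, ages, t) for (i, b, nc, ages) in removed)
    n_new = rngs.demography.poisson(params.r)
    if n_new:
        naive = [1.0] * params.K
        for _ in range(n_new):
            k = _score_choose(naive, group.labour().tolist(), params.f, rngs.choice)
            idx = group.add_member(k)
            if params.update_mode == "event_queue":
                group.next_update[idx] = t + rngs.scheduler.exponential(1.0 / params.lam)

    # --- task re-evaluations
    n = group.size
    if n:
        if params.update_mode == "per_step_bernoulli":
            due = np.flatnonzero(rngs.scheduler.random(n) < min(params.lam, 1.0))
            reps = {int(i): 1 for i in due}
        else:  # event_queue: possibly several fired events per individual
            reps = {}
            for i in np.flatnonzero(group.next_update <= t):
                count = 0
                while group.next_update[i] <= t:
                    count += 1
                    group.next_update[i] += rngs.scheduler.exponential(1.0 / params.lam)
                reps[int(i)] = count
            due = np.fromiter(reps.keys(), dtype=np.int64, count=len(reps))
        n_events = sum(reps.values())
        if due.size:
            order = rngs.scheduler.permutation(due)
            L = group.labour().tolist()
            if params.within_step_order == "sequential_random":
                for i in order:
                    for _ in range(reps[int(i)]):
                        _evaluate_one(group, int(i), L, params, rngs)
            else:  # simultaneous: all decide against the same start-of-phase L
                decisions = []
                for i in order:
                    if params.choice_mode == "uniform_random":
                        k = int(rngs.choice.integers(params.K))
                    else:
                        p = [1.0 + e for e in group.experience[int(i)].tolist()]
                        old = int(group.task[int(i)])
                        L_rest = list(L)
                        L_rest[old] -= p[old]
                        k = _score_choose(p, L_rest, params.f, rngs.choice, current=old)
                    decisions.append((int(i), k))
                for i, k in decisions:
                    if k != int(group.task[i]):
                        group.task[i] = k
                        group.n_changes[i] += 1
                        group.change_ages[i].append(t - int(group.birth_time[i]))
        if acc is not None:
            acc.n_evals += n_events
            acc.n_ind_steps += n

    # --- experience update for everyone
    n = group.size
    if n:
        idx = np.arange(n)
        perf = group.experience[idx, group.task]
        group.experience *= 1.0 - params.nu
        group.experience[idx, group.task] = (1.0 - params.mu) * perf + params.mu

    # --- metrics
    L_rec = None
    if acc is not None:
        acc.n_steps += 1
        acc.Ns.append(n)
        if n:
            L_rec = group.labour()
            acc.G_sum += L_rec.sum() / n
            acc.sigma_sum += labour_sigma(L_rec, params.K, params.sigma_variant)
            acc.n_metric_steps += 1
        else:
            acc.n_empty += 1
    if record:
        if L_rec is None:
            L_rec = group.labour()
        if n:
            return StepRecord(
                time=t,
                N=n,
                L=tuple(L_rec),
                G=float(L_rec.sum() / n),
                sigma=labour_sigma(L_rec, params.K, params.sigma_variant),
            )
        return StepRecord(time=t, N=0, L=tuple(L_rec), G=None, sigma=None)
    return None


def _start_group(params: SimParams, rngs: RngStreams) -> GroupState:
    group = initialize_group(params, rngs.choice)
    if params.update_mode == "event_queue":
        group.next_update = rngs.scheduler.exponential(1.0 / params.lam, size=group.size)
    for _ in range(params.burn_in):
        step(group, params, rngs)
    return group


def run_simulation(params: SimParams, track_individuals: bool = False) -> SimResult:
    """Run burn-in, then step until ``stop_recruits`` recruits have joined.

    Time averages of G and sigma cover exactly the recorded (post-burn-in)
    steps; steps on which the group was empty are excluded from both averages
    and counted separately.  With ``track_individuals``, lifetime records are
    returned for every individual born and dead inside the recorded window
    (avoiding censoring bias in lifetime change counts).  Fully reproducible
    given ``params`` — the seed is one of them.
    """
    rngs = make_rng_streams(params.seed)
    group = _start_group(params, rngs)
    burn_end_time = group.time
    recruits_base = group.cumulative_recruits

    acc = _Accum()
    while group.cumulative_recruits - recruits_base < params.stop_recruits:
        step(group, params, rngs, acc=acc)

    if acc.n_metric_steps:
        mean_G = acc.G_sum / acc.n_metric_steps
        mean_sigma = acc.sigma_sum / acc.n_metric_steps
        if not (np.isfinite(mean_G) and np.isfinite(mean_sigma)):
            raise RuntimeError("non-finite time-averaged metric encountered")
    else:
        mean_G = mean_sigma = float("nan")

    records = None
    mean_changes = None
    if track_individuals:
        records = [
            IndividualRecord(
                id=i,
                birth_time=b,
                lifespan=death - b,
                n_task_changes=nc,
                change_ages=tuple(int(a) for a in ages),
            )
            for (i, b, nc, ages, death) in acc.dead
            if b > burn_end_time
        ]
        mean_changes = (
            float(np.mean([r.n_task_changes for r in records])) if records else float("nan")
        )

    Ns = np.asarray(acc.Ns, dtype=np.int64)
    stats = (
        group_size_stats(Ns)
        if Ns.size >= 2
        else {"mean": float("nan"), "variance": float("nan"), "cv": float("nan")}
    )
    return SimResult(
        params=params,
        mean_G=float(mean_G),
        mean_sigma=float(mean_sigma),
        group_size=stats,
        n_recorded_steps=acc.n_steps,
        n_empty_steps=acc.n_empty,
        n_recruits_recorded=group.cumulative_recruits - recruits_base,
        n_evaluations=acc.n_evals,
        n_individual_steps=acc.n_ind_steps,
        mean_task_changes=mean_changes,
        individual_records=records,
        N_trajectory=Ns,
    )


def run_lifetime_sample(
    params: SimParams,
    n_individuals: int,
    record_traces: bool = False,
) -> list[IndividualRecord]:
    """Collect complete post-burn-in lifetimes until ``n_individuals`` are seen.

    Optionally records each tracked individual's per-step experience vector —
    enough to reproduce experience-trajectory plots and switch-frequency-by-age
    summaries.  Only individuals born after burn-in are eligible, so every
    returned lifespan is uncensored.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rngs = make_rng_streams(params.seed)
    group = _start_group(params, rngs)
    burn_end_time = group.time

    traces: dict[int, list[np.ndarray]] | None = {} if record_traces else None
    records: list[IndividualRecord] = []
    acc = _Accum()
    while len(records) < n_individuals:
        acc.dead.clear()
        step(group, params, rngs, acc=acc)
        if traces is not None:
            for i in range(group.size):
                if group.birth_time[i] > burn_end_time:
                    traces.setdefault(int(group.ids[i]), []).append(group.experience[i].copy())
        for ind_id, birth, n_ch, ages, death_time in acc.dead:
            if birth <= burn_end_time:
                if traces is not None:
                    traces.pop(ind_id, None)
                continue
            trace = None
            if traces is not None:
                rows = traces.pop(ind_id, None)
                if rows:
                    trace = np.asarray(rows)
            records.append(
                IndividualRecord(
                    id=ind_id,
                    birth_time=birth,
                    lifespan=death_time - birth,
                    n_task_changes=n_ch,
                    change_ages=tuple(int(a) for a in ages),
                    experience_trace=trace,
                )
            )
    return records[:n_individuals]
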