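"""Model and protocol parameters.

A :class:`SimParams` instance bundles the biological parameters of the
division-of-labour model (recruitment, mortality, task-choice rate, number of
tasks, responsiveness, learning and forgetting rates, variation cost) with the
protocol settings of a single simulation run (burn-in length, stopping rule,
seed, implementation variants).  Instances are frozen; use :meth:`SimParams.replace`
to derive modified copies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["SimParams", "SIGMA_VARIANTS", "UPDATE_MODES", "ORDER_MODES", "CHOICE_MODES"]

SIGMA_VARIANTS = ("sqrt_share", "sum_sq")
UPDATE_MODES = ("per_step_bernoulli", "event_queue")
ORDER_MODES = ("sequential_random", "simultaneous")
CHOICE_MODES = ("model", "uniform_random")

#: Recruitment-rate presets and the equilibrium group sizes they imply at d=0.006.
GROUP_SIZE_PRESETS = {"small": 0.03, "intermediate": 0.06, "large": 0.2}


@dataclass(frozen=True)
class SimParams:
    """All parameters of one simulation run.

    Parameters
    ----------
    r : float
        Recruitment rate — expected number of naive arrivals per time step
        (Poisson).  Presets 0.03 / 0.06 / 0.2 correspond to equilibrium group
        sizes N* = r/d of 5, 10 and 33.
    d : float
        Per-step mortality probability; life expectancy is 1/d (~166 steps at
        the default 0.006).
    lam : float
        Task-choice rate: individuals re-evaluate their task on average every
        1/lam steps (default 0.2, i.e. every 5 steps).
    K : int
        Number of tasks the group must perform.
    f : float
        Responsiveness in [0, 1] — the weight an individual gives to the
        group's labour needs versus its own competence when choosing a task.
    mu, nu : float
        Learning and forgetting rates of the experience dynamics.
    c : float
        Fitness cost per unit of labour variation, W = G - c*sigma.
    burn_in : int
        Time steps discarded before any statistic is recorded.
    stop_recruits : int
        The run ends once this many individuals have joined the group after
        burn-in.
    seed : int
        Root seed; all RNG streams of the run derive from it.
    sigma_variant : str
        ``sqrt_share`` (default): sigma = sqrt(sum_k (s_k - 1/K)^2) on labour
        shares; ``sum_sq``: the same sum of squares without the root.
    update_mode : str
        ``per_step_bernoulli`` (default): each individual re-evaluates each
        step with probability min(lam, 1); ``event_queue``: explicit Exp(lam)
        waiting times fired at the first step boundary past the scheduled time.
        Both realize lam evaluations per individual per step on average.
    within_step_order : str
        ``sequential_random`` (default): due individuals decide one at a time
        in random order with the labour distribution refreshed after each
        switch; ``simultaneous``: all due individuals decide against the same
        start-of-phase labour distribution.
    choice_mode : str
        ``model`` (default): the competence/group-need rule; ``uniform_random``:
        validation mode where every re-evaluation picks a task uniformly at
        random (used to check the analytic switching expectation lam/(2d)).
    """

    r: float = 0.06
    d: float = 0.006
    lam: float = 0.2
    K: int = 2
    f: float = 0.5
    mu: float = 0.1
    nu: float = 0.1
    c: float = 1.0
    burn_in: int = 5000
    stop_recruits: int = 5000
    seed: int = 1
    sigma_variant: str = "sqrt_share"
    update_mode: str = "per_step_bernoulli"
    within_step_order: str = "sequential_random"
    choice_mode: str = "model"

    def __post_init__(self) -> None:
        if not self.r >= 0:
            raise ValueError(f"recruitment rate r must be >= 0, got {self.r}")
        if not 0 < self.d < 1:
            raise ValueError(f"mortality d must be in (0, 1), got {self.d}")
        if not self.lam > 0:
            raise ValueError(f"task-choice rate lam must be > 0, got {self.lam}")
        if not (isinstance(self.K, int) and self.K >= 1):
            raise ValueError(f"number of tasks K must be an integer >= 1, got {self.K}")
        if not 0 <= self.f <= 1:
            raise ValueError(f"responsiveness f must be in [0, 1], got {self.f}")
        if not 0 < self.mu <= 1:
            raise ValueError(f"learning rate mu must be in (0, 1], got {self.mu}")
        if not 0 <= self.nu <= 1:
            raise ValueError(f"forgetting rate nu must be in [0, 1], got {self.nu}")
        if not self.c >= 0:
            raise ValueError(f"variation cost c must be >= 0, got {self.c}")
        if not (isinstance(self.burn_in, int) and self.burn_in >= 0):
            raise ValueError(f"burn_in must be an integer >= 0, got {self.burn_in}")
        if not (isinstance(self.stop_recruits, int) and self.stop_recruits >= 1):
            raise ValueError(f"stop_recruits must be an integer >= 1, got {self.stop_recruits}")
        if self.sigma_variant not in SIGMA_VARIANTS:
            raise ValueError(f"sigma_variant must be one of {SIGMA_VARIANTS}")
        if self.update_mode not in UPDATE_MODES:
            raise ValueError(f"update_mode must be one of {UPDATE_MODES}")
        if self.within_step_order not in ORDER_MODES:
            raise ValueError(f"within_step_order must be one of {ORDER_MODES}")
        if self.choice_mode not in CHOICE_MODES:
            raise ValueError(f"choice_mode must be one of {CHOICE_MODES}")

    @property
    def equilibrium_size(self) -> float:
        """Expected stationary group size N* = r/d."""
        return self.r / self.d

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)
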