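# Methods

## The model

`dolsim` simulates a cooperative group whose members divide K tasks among
themselves. Time is discrete; a step may be thought of as an hour or a day.
Three processes run on top of each other:

**Demography.** The group is an immigration–death process. Each step every
individual dies independently with probability d, and a Poisson(r) number of
naive recruits joins. Group size therefore fluctuates around the equilibrium
N\* = r/d with a Poisson(r/d) stationary distribution, and individuals live
1/d steps on average. Because mortality is per capita, small groups fluctuate
more in relative terms (CV = (r/d)^(-1/2)): a single death disturbs a group
of 5 far more than a group of 33. This demographic stochasticity — not group
size per se — is what drives the group-size effects in the model.

**Learning and forgetting.** Individual i holds an experience value
E_ik ∈ [0, 1] per task. Performing task k updates E_ik ← (1−μ)E_ik + μ
(diminishing returns toward 1); every other task decays E_ij ← (1−ν)E_ij.
Under uninterrupted practice E follows the exact curve 1 − (1−μ)^t.
Competence is p_ik = 1 + E_ik ∈ [1, 2]: a naive individual works at
baseline efficiency 1, a fully practised one at 2.

**Task choice.** The labour distribution L_k sums the current-task
competences of the workers at task k. On average every 1/λ steps an
individual re-evaluates its task, scoring each task k as

    score_k = (1 − f) · p_ik / Σ_j p_ij  +  f · (1 − L_k / Σ_j L_j)

and adopting the argmax. The responsiveness f weighs own competence (f = 0:
pure habit/efficiency) against the group's unmet needs (f = 1: pure
task-demand tracking). The choice is absolute: the highest-scoring task is
taken no matter how small the gap.

**Group performance and fitness.** Per recorded step the model tracks work
per capita G = ΣL_k / N ∈ [1, 2] and the labour variation
σ = sqrt(Σ_k (s_k − 1/K)²) on the shares s_k = L_k/ΣL. Group fitness trades
the two: W = G − c·σ, where c is the cost per unit of labour imbalance. The
analysis layer grid-searches the simulated (f → G, σ) surface for the optimal
responsiveness f\*(c), and estimates selection gradients on μ and ν by paired
perturbation runs at f\*.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| r | recruitment rate (arrivals/step) | 0.06 | presets 0.03 / 0.06 / 0.2 → N\* = 5 / 10 / 33 |
| d | mortality probability/step | 0.006 | life expectancy 1/d ≈ 166 steps |
| λ | task re-evaluation rate | 0.2 | one decision per ~5 steps |
| K | number of tasks | 2 | also 3, 5 |
| f | responsiveness | swept in [0, 1] | the focal trait of the analysis |
| μ | learning rate | 0.1 | sweep range 0.01–0.2 |
| ν | forgetting rate | 0.1 | alternative 0.05 |
| c | variation cost | 1.0 | range 0–5 in the f\* analysis |
| burn-in | unrecorded steps | 5000 | statistics start afterwards |
| stop_recruits | stopping rule | 5000 | run ends after this many post-burn-in arrivals |

## Implementation decisions

These are the points where the verbal model admits more than one reading;
each choice below is load-bearing and deliberate.

**Whose labour does a decision-maker see?** When an individual re-evaluates,
it scores tasks against the labour of the *rest* of the group — its own
contribution is removed first (a recruit choosing at arrival naturally sees
the group it is joining). This is the convention under which stable
allocations exist: the group settles into an ideal-free-distribution-like
state in which no individual can reduce the imbalance by moving, and task
changes are then triggered only by births and deaths — which is what makes
task specialization emerge even at f = 1. If the focal contribution were
included, whoever occupied the currently heavier task would always prefer to
leave it, the allocation would never stabilize, and at f = 1 individuals
would churn at the random-choice rate (~17 changes per lifetime instead of
< 1.5). The lone-specialist threshold is unaffected: with task 2 unattended
the remaining shares are (1, 0) either way, so the switch point sits at
exactly f = 0.25.

**Ties.** Scores tie when they agree within a relative 10⁻¹². Arriving
recruits break ties uniformly at random (for a naive individual in a
balanced group this means a uniform draw over all K tasks). At a
re-evaluation, however, an individual whose *current* task is among the tied
maxima stays: switching at exact indifference has no benefit, and because at
f = 1 an individual alone at its task scores its own need as exactly 1.0 —
tying with any truly empty task — random tie-breaking would otherwise
shuttle coverage holes around the group forever whenever N < K. With
stay-on-tie, a group of ~5 sits stably on five tasks (one each), which is
also why small groups switch *less* with five tasks than with three.

**Scheduling.** Default `per_step_bernoulli`: each individual re-evaluates
each step with probability min(λ, 1), realizing exactly λ evaluations per
individual-step and a mean interval of 1/λ = 5 steps. The `event_queue` mode
draws explicit Exp(λ) waiting times in continuous time and fires every event
at the first step boundary past its scheduled time; it realizes the same
rate. (A Bernoulli probability of 1 − e^(−λ) would thin the rate to 0.18 at
λ = 0.2 and bias every rate-based statistic by ~10%, so it is not used.)

**Within-step order.** Demography (deaths, then arrivals) → task
re-evaluations → experience update → recording. Due individuals decide
sequentially in uniformly random order with L refreshed after every switch,
approximating the continuous-time limit in which each decision sees the
current state; a `simultaneous` variant (all due individuals decide against
the same start-of-phase L) is available for sensitivity checks. The running
L is rebuilt from scratch each step, so floating-point drift cannot
accumulate across steps into the tie tolerance.

**Demographic update.** Survivors are Binomial(N, 1 − d) and recruits
Poisson(r) — the composition that actually has equilibrium r/d and a Poisson
stationary law. Each arriving recruit picks its initial task with the normal
choice rule against the labour it finds, recruits inserted one at a time;
this initial assignment is not counted as a task change. The group starts at
round(r/d) naive founders placed the same way, followed by the burn-in.

**Degenerate cases.** If the labour a decision-maker weighs sums to zero
(empty group, or a lone individual after self-exclusion), the need term is
the uniform 1 − 1/K for every task, reducing the choice to competence plus
tie-breaking — a lone individual therefore never abandons its task. Steps on
which the whole group is empty leave G and σ undefined; they are excluded
from both time averages and counted separately (they essentially only occur
in the N\* = 5 regime, and rarely).

**The σ statistic.** The default is the standard deviation of the labour
shares around 1/K: σ = sqrt(Σ(s_k − 1/K)²), which is zero iff labour is
uniform, permutation-invariant and scale-invariant. A `sum_sq` variant
(the same sum of squares without the root) is provided for sensitivity
analysis; all qualitative orderings (across group size, K, and f) are
unaffected by the variant, only the numeric scale of c changes.

## What the simulations emulate — and what they do not

All data are generated by the model itself; there is no external input. The
study conditions are the parameter grid above: three group sizes crossed
with K ∈ {2, 3, 5}, responsiveness swept over [0, 1], defaults elsewhere.
Real cooperative groups differ in ways the model deliberately ignores: no
spatial structure, no individual variation in baseline ability, no
task-specific costs or synergies, no genetics, and no conflict of interest
between members (individual and group fitness are assumed aligned). Passing
tests therefore validate the internal logic of the learning/choice/demography
mechanism, not its fit to any particular species.

## Problem sizes

Desk-scale runs keep every analysis inside minutes while leaving Monte-Carlo
error well below the effect sizes of interest:

- stationary demography: 10⁵ steps after a 5000-step burn-in;
- switching-rate validation: 10⁴ complete lifetimes;
- full-responsiveness specialization: ≥ 20 000 recorded steps per
  (group size × K) combination;
- fitness surfaces: f-grid step 0.05, 3 replicate seeds, 1500 recruits per
  run (~25 000 recorded steps at N\* = 10);
- selection gradients: 12 paired replicates with common random numbers
  (shared demography and evaluation-schedule streams), 2000 recruits per run
  for the learning bump and 600 for the forgetting comparison at N\* = 5.

The forgetting comparison is evaluated at c = 0 (W = G), so the paired
difference isolates the effect of forgetting on output; at fixed f the σ
term would only add noise. The learning bump is evaluated at the f\* of the
smallest cost c ∈ {0.5, …, 5} whose optimum reaches f\* ≥ 0.8.

## Known limitations

- The f\*(c) argmax is noisy at low c, where G(f) and σ(f) are nearly flat;
  ties resolve toward the smallest f (least switching).
- Per-step discretization means several demographic events and decisions can
  fall in the same step; the sequential-refresh order makes this a good
  approximation of the continuous-time limit, but it is not event-exact.
- Time averages start right after the burn-in regardless of whether slow
  modes (e.g. experience saturation at very small μ) have fully equilibrated;
  at μ = 0.01 the first ~500 steps after burn-in still carry a mild
  transient, common to both arms of any paired comparison.
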