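"""Elementary update rules: experience, competence, labour, task choice, demography."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dolsim import (
    GroupState,
    SimParams,
    choose_task,
    competence,
    demographic_step,
    initialize_group,
    labour_distribution,
    simulate_group_size,
    switching_threshold,
    task_scores,
    update_experience,
)

experience_vectors = arrays(
    float,
    st.integers(min_value=1, max_value=5),
    elements=st.floats(0.0, 1.0, allow_nan=False),
)


class TestUpdateExperience:
    @pytest.mark.parametrize(
        "E, performed, expected",
        [
            ((0.0, 0.0), 0, (0.1, 0.0)),  # naive learner gains mu
            ((1.0, 0.5), 0, (1.0, 0.45)),  # E=1 is the fixed point; others decay
            ((0.5, 0.5, 0.5), 1, (0.45, 0.55, 0.45)),
        ],
    )
    def test_single_update(self, E, performed, expected):
        out = update_experience(np.array(E), performed, mu=0.1, nu=0.1)
        np.testing.assert_allclose(out, expected)

    @pytest.mark.parametrize("mu", [0.01, 0.1, 0.5])
    @pytest.mark.parametrize("t", [1, 10, 100])
    def test_learning_curve_closed_form(self, mu, t):
        """Uninterrupted practice follows E(t) = 1 - (1-mu)^t to machine precision."""
        E = np.zeros(2)
        for _ in range(t):
            E = update_experience(E, 0, mu=mu, nu=0.1)
        assert E[0] == pytest.approx(1.0 - (1.0 - mu) ** t, abs=1e-14)
        assert E[1] == 0.0  # forgetting has no effect at the floor

    @given(E=experience_vectors, mu=st.floats(0.0, 1.0), nu=st.floats(0.0, 1.0))
    def test_bounds_preserved(self, E, mu, nu):
        out = update_experience(E, 0, mu=mu, nu=nu)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_invalid_task_index_is_a_caller_bug(self):
        with pytest.raises(IndexError):
            update_experience(np.zeros(2), 2, mu=0.1, nu=0.1)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            update_experience(np.zeros(2), 0, mu=1.5, nu=0.1)


class TestCompetence:
    @pytest.mark.parametrize(
        "E, expected",
        [
            ((0.0, 0.0), (1.0, 1.0)),  # naive baseline
            ((1.0, 0.0), (2.0, 1.0)),  # full specialist
            ((0.5, 0.25, 0.0), (1.5, 1.25, 1.0)),
        ],
    )
    def test_examples(self, E, expected):
        np.testing.assert_allclose(competence(np.array(E)), expected)

    @given(E=experience_vectors)
    def test_bounded_in_1_2(self, E):
        p = competence(E)
        assert np.all(p >= 1.0) and np.all(p <= 2.0)


class TestLabourDistribution:
    def _group(self, experiences, tasks):
        g = GroupState(K=len(experiences[0]))
        for E, tau in zip(experiences, tasks):
            g.add_member(tau)
            g.experience[-1] = E
        return g

    def test_one_worker_per_task(self):
        g = self._group([(1.0, 0.0), (0.0, 1.0)], [0, 1])
        L = labour_distribution(g)
        np.testing.assert_allclose(L.L, [2.0, 2.0])
        assert L.total == 4.0

    def test_unattended_task_has_zero_labour(self):
        g = self._group([(1.0, 0.0)], [0])
        np.testing.assert_allclose(labour_distribution(g).L, [2.0, 0.0])

    def test_empty_group_all_zero(self):
        g = GroupState(K=3)
        np.testing.assert_allclose(labour_distribution(g).L, [0.0, 0.0, 0.0])

    def test_total_bounded_by_competence_range(self, rng):
        g = GroupState(K=3)
        for _ in range(7):
            g.add_member(int(rng.integers(3)))
        g.experience[:] = rng.random((7, 3))
        total = labour_distribution(g).total
        assert g.size <= total <= 2 * g.size


class TestTaskScores:
    def test_lone_specialist_tie_at_quarter(self):
        """p=(2,1) facing L=(2,0): scores are exactly tied at f=0.25."""
        s = task_scores((2.0, 1.0), (2.0, 0.0), f=0.25)
        np.testing.assert_allclose(s, [0.5, 0.5])

    def test_above_tie_point_neglected_task_wins(self):
        s = task_scores((2.0, 1.0), (2.0, 0.0), f=0.3)
        assert s[0] == pytest.approx(0.7 * 2 / 3)
        assert s[1] == pytest.approx(0.7 * 1 / 3 + 0.3)
        assert s[1] > s[0]

    @given(E=experience_vectors)
    def test_f_zero_reduces_to_competence_share(self, E):
        p = competence(E)
        L = np.ones_like(p)
        np.testing.assert_allclose(task_scores(p, L, f=0.0), p / p.sum())

    def test_idle_group_need_term_is_uniform(self):
        s = task_scores((1.0, 1.0, 1.0), (0.0, 0.0, 0.0), f=1.0)
        np.testing.assert_allclose(s, 1.0 - 1.0 / 3)

    def test_scores_are_a_convex_blend(self, rng):
        p = competence(rng.random(4))
        L = rng.random(4) * 5
        for f in (0.0, 0.3, 1.0):
            s = task_scores(p, L, f)
            blend = (1 - f) * p / p.sum() + f * (1 - L / L.sum())
            np.testing.assert_allclose(s, blend)


class TestChooseTask:
    def test_threshold_sweep_lone_specialist(self, rng):
        """Stay below f=0.25, switch above, across a fine grid."""
        for f in np.arange(0.0, 0.249, 0.004):
            assert choose_task((2.0, 1.0), (2.0, 0.0), f, rng) == 0
        for f in np.arange(0.251, 1.0001, 0.004):
            assert choose_task((2.0, 1.0), (2.0, 0.0), f, rng) == 1

    def test_switching_threshold_closed_form(self):
        assert switching_threshold((2.0, 1.0), (2.0, 0.0), stay=0, switch_to=1) == pytest.approx(
            0.25
        )

    def test_naive_uniform_choice(self, rng):
        """Full symmetry: a naive individual picks uniformly among all K tasks."""
        K = 4
        counts = np.zeros(K)
        for _ in range(4000):
            counts[choose_task(np.ones(K), np.ones(K), f=0.7, rng=rng)] += 1
        # chi-square-ish sanity: each task within 5 sigma of the uniform count
        expected = 4000 / K
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected * (1 - 1 / K)))

    def test_exact_tie_randomized(self, rng):
        picks = {choose_task((2.0, 1.0), (2.0, 0.0), 0.25, rng) for _ in range(200)}
        assert picks == {0, 1}

    @given(E=experience_vectors)
    def test_f_zero_absorption(self, E):
        """With a strictly maximal experience and f=0, the argmax never moves."""
        if E.size < 2:
            return
        E = E.copy()
        E[0] = max(E.max(), 0.5) + 1e-3 if E.max() < 1 else 1.0
        E[1:] = np.clip(E[1:], 0, E[0] - 1e-6)
        if E[0] <= E[1:].max():
            return
        L = np.abs(np.random.default_rng(1).random(E.size)) + 0.1
        assert choose_task(competence(E), L, f=0.0, rng=np.random.default_rng(0)) == 0


class TestDemography:
    def test_no_mortality_keeps_everyone(self, rng):
        g = GroupState(K=2)
        for _ in range(10):
            g.add_member(0)
        ids_before = g.ids.copy()
        demographic_step(g, r=0.0, d=1e-300, f=0.5, rng=rng)
        np.testing.assert_array_equal(g.ids, ids_before)

    def test_recruits_arrive_naive_and_counted(self, rng):
        g = GroupState(K=2)
        demographic_step(g, r=50.0, d=0.5, f=1.0, rng=rng)
        assert g.size == g.cumulative_recruits > 0
        assert np.all(g.experience == 0.0)

    def test_stationary_mean_matches_r_over_d(self):
        """Immigration-death chain: long-run mean and variance both ~ r/d."""
        traj = simulate_group_size(r=0.06, d=0.006, n_steps=60_000, burn_in=2000, rng=7)
        target = 10.0
        # autocorrelation time ~ 1/d, so effective sample size ~ n*d/2
        se = np.sqrt(target / (60_000 * 0.006 / 2))
        assert abs(traj.mean() - target) < 4 * se
        assert abs(traj.var(ddof=1) - target) < 6 * se * np.sqrt(2 * target)

    def test_initial_group_balanced_over_tasks(self, rng):
        params = SimParams(r=0.2, d=0.006, K=5, f=1.0)
        g = initialize_group(params, rng)
        assert g.size == round(params.equilibrium_size)
        counts = np.bincount(g.task, minlength=5)
        assert counts.max() - counts.min() <= 1  # naive founders spread evenly
        assert g.cumulative_recruits == 0


class TestSimParams:
    def test_table_defaults(self):
        p = SimParams()
        assert (p.d, p.lam, p.mu, p.nu) == (0.006, 0.2, 0.1, 0.1)
        assert p.r in (0.03, 0.06, 0.2) and p.K in (2, 3, 5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"f": -0.1},
            {"f": 1.2},
            {"d": 0.0},
            {"d": 1.0},
            {"mu": 0.0},
            {"K": 0},
            {"stop_recruits": 0},
            {"sigma_variant": "bogus"},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)

    @pytest.mark.parametrize("r, nstar", [(0.03, 5), (0.06, 10), (0.2, 33)])
    def test_equilibrium_size_presets(self, r, nstar):
        assert round(SimParams(r=r).equilibrium_size) == nstar
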