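"""Rewards, allocation, and strategy composition."""

import itertools

import numpy as np
import pytest

from adaptivebind import (
    Cluster,
    ClusteringState,
    Conformation,
    MissingMetricError,
    ReceptorFrame,
    SpawningParams,
    SpawningPlan,
    allocate,
    reward_inverse,
    reward_metric,
    spawn,
)
from adaptivebind.spawning import spawning_report


def make_cluster(cid=0, density=1.0, visits=1, metric=None):
    center = Conformation(np.full((3, 3), 20.0) + cid)
    cl = Cluster(
        id=cid, center=center, threshold=5.0, contact_ratio=0.0,
        density=density, visit_count=visits,
    )
    if metric is not None:
        lo, hi = metric
        cl.metric_min["energy"] = lo
        cl.metric_max["energy"] = hi
    return cl


def make_state(clusters):
    frame = ReceptorFrame([[0.0, 0.0, 0.0]])
    state = ClusteringState(frame)
    state.clusters = list(clusters)
    return state


class TestRewardInverse:
    @pytest.mark.parametrize("rho,visits,expected", [(1.0, 1, 1.0), (2.0, 4, 0.5)])
    def test_substitution(self, rho, visits, expected):
        assert reward_inverse(make_cluster(density=rho, visits=visits)) == expected

    def test_doubling_visits_halves_reward(self):
        r1 = reward_inverse(make_cluster(density=3.0, visits=5))
        r2 = reward_inverse(make_cluster(density=3.0, visits=10))
        assert r2 == pytest.approx(r1 / 2.0)


class TestRewardMetric:
    def test_minimize_uses_cluster_maximum(self):
        a = make_cluster(0, metric=(-6.0, -5.0))
        b = make_cluster(1, metric=(-4.0, -3.0))
        assert reward_metric(a, -6.0, -3.0, "minimize") == pytest.approx(2.0)
        assert reward_metric(b, -6.0, -3.0, "minimize") == pytest.approx(0.0)

    def test_maximize_uses_cluster_minimum(self):
        for m_i_min, expected in [(1.0, 0.0), (4.0, 3.0), (7.0, 6.0)]:
            cl = make_cluster(metric=(m_i_min, m_i_min + 0.5))
            assert reward_metric(cl, 1.0, 7.5, "maximize") == pytest.approx(expected)

    def test_identical_metrics_give_zero_everywhere(self):
        cl = make_cluster(metric=(2.0, 2.0))
        assert reward_metric(cl, 2.0, 2.0, "maximize") == 0.0
        assert reward_metric(cl, 2.0, 2.0, "minimize") == 0.0

    def test_cluster_best_switch_flips_the_extremum(self):
        cl = make_cluster(metric=(-6.0, -2.0))
        # published pairing: minimize ↦ per-cluster maximum
        assert reward_metric(cl, -6.0, 0.0, "minimize") == pytest.approx(2.0)
        # best-value pairing: minimize ↦ per-cluster minimum
        assert reward_metric(cl, -6.0, 0.0, "minimize", use_cluster_best=True) == pytest.approx(6.0)

    def test_missing_metric_raises(self):
        with pytest.raises(MissingMetricError):
            reward_metric(make_cluster(), 0.0, 1.0, "minimize")


def largest_remainder_by_enumeration(probabilities, n):
    """Brute force: the count vector summing to n closest to n·p in L2."""
    k = len(probabilities)
    quotas = [n * p for p in probabilities]
    best, best_cost = None, None
    for counts in itertools.product(range(n + 1), repeat=k):
        if sum(counts) != n:
            continue
        cost = sum((c - q) ** 2 for c, q in zip(counts, quotas))
        if best_cost is None or cost < best_cost - 1e-12:
            best, best_cost = counts, cost
    return best, best_cost


class TestAllocate:
    def test_single_cluster_gets_everything(self):
        plan = allocate({0: 0.7}, 8, mode="deterministic")
        assert plan.counts == {0: 8}

    def test_symmetric_rewards_split_evenly(self):
        plan = allocate({0: 1.0, 1: 1.0}, 4, mode="deterministic")
        assert plan.counts == {0: 2, 1: 2}

    def test_zero_rewards_fall_back_to_uniform(self):
        plan = allocate({0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0}, 8, mode="deterministic")
        assert plan.counts == {0: 2, 1: 2, 2: 2, 3: 2}

    @pytest.mark.parametrize("seed", range(6))
    def test_deterministic_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 5))
        n = int(rng.integers(1, 21))
        rewards = {i: float(rng.uniform(0.0, 3.0)) for i in range(k)}
        total = sum(rewards.values()) or 1.0
        p = [rewards[i] / total if sum(rewards.values()) else 1.0 / k for i in range(k)]
        plan = allocate(rewards, n, mode="deterministic")
        _, best_cost = largest_remainder_by_enumeration(p, n)
        got_cost = sum((plan.counts[i] - n * p[i]) ** 2 for i in range(k))
        assert got_cost == pytest.approx(best_cost, abs=1e-9)
        assert sum(plan.counts.values()) == n

    def test_stochastic_counts_near_expectation(self):
        plan = allocate({0: 3.0, 1: 1.0}, 40000, mode="stochastic", rng_seed=123)
        sigma = np.sqrt(40000 * 0.75 * 0.25)
        assert abs(plan.counts[0] - 30000) < 3 * sigma
        assert plan.counts[0] + plan.counts[1] == 40000

    def test_stochastic_reproducible_at_fixed_seed(self):
        a = allocate({0: 1.0, 1: 2.0, 2: 3.0}, 50, mode="stochastic", rng_seed=9)
        b = allocate({0: 1.0, 1: 2.0, 2: 3.0}, 50, mode="stochastic", rng_seed=9)
        assert a.counts == b.counts

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            allocate({0: -1.0}, 4)
        with pytest.raises(ValueError):
            allocate({0: 1.0}, 0)
        with pytest.raises(ValueError):
            allocate({}, 4)
        with pytest.raises(ValueError):
            SpawningPlan(counts={0: 3}, total=4)


class TestSpawn:
    def setup_method(self):
        # two clusters: cluster 1 metric-best, equal densities, equal visits
        self.state = make_state(
            [
                make_cluster(0, density=1.0, visits=2, metric=(-1.0, -1.0)),
                make_cluster(1, density=1.0, visits=2, metric=(-5.0, -5.0)),
            ]
        )

    def test_epsilon_one_equals_pure_inverse(self):
        pe = SpawningParams(strategy="epsilon_greedy", epsilon=1.0, rng_seed=4)
        pi = SpawningParams(strategy="inversely_proportional", rng_seed=4)
        assert spawn(self.state, pe, 10).counts == spawn(self.state, pi, 10).counts

    def test_epsilon_zero_equals_pure_metric(self):
        pe = SpawningParams(strategy="epsilon_greedy", epsilon=0.0, rng_seed=4)
        pm = SpawningParams(strategy="metric_guided", rng_seed=4)
        assert spawn(self.state, pe, 10).counts == spawn(self.state, pm, 10).counts

    def test_epsilon_split_rounds_half_up(self):
        # ε=0.25, N=8 → 6 metric-guided seeds (all to cluster 1) + 2 inverse
        params = SpawningParams(
            strategy="epsilon_greedy", epsilon=0.25, allocation_mode="deterministic"
        )
        plan = spawn(self.state, params, 8)
        assert plan.total == 8
        # metric rewards: cluster 0 is worst (0), cluster 1 gets all 6;
        # inverse rewards are symmetric, 2 seeds split 1/1
        assert plan.counts == {0: 1, 1: 7}

    def test_plans_reproducible_and_sum_to_n(self):
        params = SpawningParams(strategy="inversely_proportional", rng_seed=77)
        a = spawn(self.state, params, 25)
        b = spawn(self.state, params, 25)
        assert a.counts == b.counts
        assert sum(a.counts.values()) == 25

    def test_empty_state_raises(self):
        with pytest.raises(ValueError):
            spawn(make_state([]), SpawningParams(), 4)

    def test_report_columns(self):
        plan = spawn(self.state, SpawningParams(strategy="metric_guided"), 6)
        report = spawning_report(plan)
        assert list(report.columns) == ["cluster_id", "reward", "probability", "seeds"]
        assert report["seeds"].sum() == 6


class TestPopulationBalance:
    def test_visit_ratio_tends_to_density_ratio(self):
        """On a two-cluster chain with equal densities the 1/C reward drives
        the visit-count ratio to 1 (the long-run population guarantee)."""
        clusters = [
            make_cluster(0, density=1.0, visits=1),
            make_cluster(1, density=1.0, visits=20),  # start unbalanced
        ]
        state = make_state(clusters)
        params = SpawningParams(
            strategy="inversely_proportional", allocation_mode="deterministic"
        )
        n, l = 10, 1
        for _ in range(200):
            plan = spawn(state, params, n)
            for cid, count in plan.counts.items():
                clusters[cid].visit_count += count * l
        ratio = clusters[0].visit_count / clusters[1].visit_count
        assert abs(ratio - 1.0) < 0.05
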