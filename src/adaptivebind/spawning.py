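"""Cluster rewards and seed allocation (the multi-armed-bandit step).

Each cluster is an arm; seeding a trajectory from its centre is a pull.
Rewards come in two flavours:

* *inversely proportional*: r = ρ / C, where ρ is the cluster's density and
  C its visit count.  The 1/C factor drives the long-run population ratio of
  any two clusters towards the ratio of their densities, producing a
  metric-independent diffusion over the discretised landscape.
* *metric guided*: with per-cluster metric extrema m_i,min / m_i,max and
  global extrema m_min / m_max, the reward is m_i,min − m_min when
  maximising and m_max − m_i,max when minimising, so the globally worst
  cluster scores zero.

Seeds are allocated proportionally to rewards — each cluster is pulled with
probability proportional to its reward (Thompson-style proportional
sampling) — either stochastically (multinomial draw) or deterministically
(largest-remainder apportionment).  The ε-greedy strategy sends a 1−ε
fraction of explorers after the metric-guided reward and the rest after the
inversely proportional one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .clustering import Cluster, ClusteringState

__all__ = [
    "SpawningParams",
    "SpawningPlan",
    "MissingMetricError",
    "reward_inverse",
    "reward_metric",
    "allocate",
    "spawn",
    "spawning_report",
]

STRATEGIES = ("inversely_proportional", "epsilon_greedy", "metric_guided")


class MissingMetricError(KeyError):
    """Raised when a cluster has no recorded extrema for the chosen metric."""


@dataclass(frozen=True)
class SpawningParams:
    """Configuration of the spawning step.

    ``use_cluster_best`` switches the metric reward from the published
    extremum pairing (maximise ↦ per-cluster minimum, minimise ↦ per-cluster
    maximum) to the per-cluster best value (maximise ↦ maximum, minimise ↦
    minimum); the published pairing is the default.
    """

    strategy: str = "inversely_proportional"
    epsilon: float = 0.25
    metric_name: str = "energy"
    metric_sense: str = "minimize"
    allocation_mode: str = "stochastic"
    rng_seed: int = 0
    use_cluster_best: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "epsilon_greedy" and not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.metric_sense not in ("maximize", "minimize"):
            raise ValueError(f"unknown metric sense {self.metric_sense!r}")
        if self.allocation_mode not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown allocation mode {self.allocation_mode!r}")


@dataclass
class SpawningPlan:
    """Seeds per cluster for the next epoch; counts always sum to ``total``."""

    counts: Dict[int, int]
    total: int
    rewards: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("plan counts must sum to the total")


def reward_inverse(cluster: Cluster) -> float:
    """r = ρ / C: high for dense, rarely visited clusters."""
    if cluster.visit_count < 1:
        raise ValueError("visit_count must be >= 1")
    return cluster.density / cluster.visit_count


def reward_metric(
    cluster: Cluster,
    global_min: float,
    global_max: float,
    sense: str,
    metric_name: str = "energy",
    use_cluster_best: bool = False,
) -> float:
    """Metric-guided reward from per-cluster extrema; the worst cluster scores 0."""
    if metric_name not in cluster.metric_min:
        raise MissingMetricError(
            f"cluster {cluster.id} has no recorded metric {metric_name!r}"
        )
    if sense == "maximize":
        m_i = cluster.metric_max[metric_name] if use_cluster_best else cluster.metric_min[metric_name]
        return m_i - global_min
    if sense == "minimize":
        m_i = cluster.metric_min[metric_name] if use_cluster_best else cluster.metric_max[metric_name]
        return global_max - m_i
    raise ValueError(f"unknown metric sense {sense!r}")


def allocate(
    rewards: Dict[int, float],
    n_seeds: int,
    mode: str = "stochastic",
    rng: Optional[np.random.Generator] = None,
    rng_seed: int = 0,
) -> SpawningPlan:
    """Distribute ``n_seeds`` over clusters proportionally to their rewards.

    Stochastic mode draws counts from a multinomial with p_i = r_i / Σr;
    deterministic mode apportions N·p_i by largest remainder (ties broken
    by lower cluster id).  All-zero rewards fall back to uniform
    probabilities so a degenerate epoch still explores.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if not rewards:
        raise ValueError("at least one cluster is required")
    ids = sorted(rewards)
    r = np.array([rewards[i] for i in ids], dtype=float)
    if np.any(r < 0):
        raise ValueError("rewards must be >= 0")
    total = r.sum()
    p = r / total if total > 0 else np.full(len(r), 1.0 / len(r))

    if mode == "stochastic":
        if rng is None:
            rng = np.random.default_rng(rng_seed)
        counts = rng.multinomial(n_seeds, p)
    elif mode == "deterministic":
        quotas = n_seeds * p
        counts = np.floor(quotas).astype(int)
        remainder = quotas - counts
        short = n_seeds - int(counts.sum())
        # stable sort: ties in the remainder go to the lower cluster id
        for idx in np.argsort(-remainder, kind="stable")[:short]:
            counts[idx] += 1
    else:
        raise ValueError(f"unknown allocation mode {mode!r}")

    return SpawningPlan(
        counts={i: int(c) for i, c in zip(ids, counts)},
        total=n_seeds,
        rewards=dict(rewards),
    )


def _inverse_rewards(state: ClusteringState) -> Dict[int, float]:
    return {cl.id: reward_inverse(cl) for cl in state.clusters}


def _metric_rewards(state: ClusteringState, params: SpawningParams) -> Dict[int, float]:
    name = params.metric_name
    mins = [cl.metric_min[name] for cl in state.clusters if name in cl.metric_min]
    maxs = [cl.metric_max[name] for cl in state.clusters if name in cl.metric_max]
    if not mins:
        raise MissingMetricError(f"no cluster has recorded metric {name!r}")
    global_min, global_max = min(mins), max(maxs)
    return {
        cl.id: reward_metric(
            cl, global_min, global_max, params.metric_sense, name, params.use_cluster_best
        )
        for cl in state.clusters
    }


def spawn(
    state: ClusteringState,
    params: SpawningParams,
    n_seeds: int,
    rng: Optional[np.random.Generator] = None,
) -> SpawningPlan:
    """Build the next epoch's seeding plan from the current cluster state.

    ε-greedy splits the N explorers with round-half-up on (1−ε)·N going to
    the metric-guided arm and the remainder to the inversely proportional
    one; the two partial plans are summed.  An explicit ``rng`` overrides
    ``params.rng_seed``.
    """
    if len(state) < 1:
        raise ValueError("clustering state has no clusters")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    if params.strategy == "inversely_proportional":
        return allocate(_inverse_rewards(state), n_seeds, params.allocation_mode, rng=rng)
    if params.strategy == "metric_guided":
        return allocate(_metric_rewards(state, params), n_seeds, params.allocation_mode, rng=rng)

    # epsilon-greedy: round-half-up on the metric fraction
    n_metric = int(np.floor((1.0 - params.epsilon) * n_seeds + 0.5))
    n_inverse = n_seeds - n_metric
    counts: Dict[int, int] = {cl.id: 0 for cl in state.clusters}
    rewards: Dict[int, float] = {}
    if n_metric > 0:
        part = allocate(_metric_rewards(state, params), n_metric, params.allocation_mode, rng=rng)
        for i, c in part.counts.items():
            counts[i] += c
        rewards.update({i: r for i, r in part.rewards.items()})
    if n_inverse > 0:
        part = allocate(_inverse_rewards(state), n_inverse, params.allocation_mode, rng=rng)
        for i, c in part.counts.items():
            counts[i] += c
        for i, r in part.rewards.items():
            rewards.setdefault(i, r)
    return SpawningPlan(counts=counts, total=n_seeds, rewards=rewards)


def spawning_report(plan: SpawningPlan) -> pd.DataFrame:
    """Per-epoch report: cluster id, reward, probability, allocated seeds."""
    total_reward = sum(plan.rewards.values())
    rows = []
    for cid in sorted(plan.counts):
        r = plan.rewards.get(cid, 0.0)
        rows.append(
            {
                "cluster_id": cid,
                "reward": r,
                "probability": r / total_reward if total_reward > 0 else 1.0 / len(plan.counts),
                "seeds": plan.counts[cid],
            }
        )
    return pd.DataFrame(rows)
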