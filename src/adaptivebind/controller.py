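"""The adaptive epoch loop and the adaptive-vs-independent benchmark.

One epoch = a swarm of N short trajectories (l steps each), followed by
leader clustering of every new snapshot and a spawning step that picks the
seeds for the next epoch.  The independent baseline runs the same N
trajectories without any clustering feedback.  Both arms consume rng
streams derived from a single master seed by a counter-based split, one
child stream per (epoch, trajectory), so they are comparable at matched
seeds: before any feedback has occurred their trajectories are identical.

Binding times are reported in per-trajectory MC steps (1-based): the first
step at which any trajectory's ligand RMSD to the native pose drops below
the cutoff, or the step cap when no trajectory binds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .clustering import ClusteringState
from .core import (
    Conformation,
    DensityPolicy,
    ReceptorFrame,
    ThresholdPolicy,
    ligand_rmsd,
)
from .spawning import SpawningParams, SpawningPlan, spawn
from .simulator import MoveParams, ToySystem, make_sampler

__all__ = [
    "AdaptiveParams",
    "RunRecord",
    "SamplerContractError",
    "run_adaptive",
    "run_independent",
    "binding_time",
    "binding_times",
    "benchmark",
    "DEFAULT_BENCHMARK_SEED",
]

#: Shipped base seed for the default benchmark seed set.
DEFAULT_BENCHMARK_SEED = 20170117

logger = logging.getLogger("adaptivebind.controller")


def _plan_entropy(plan: SpawningPlan) -> float:
    p = np.array([c for c in plan.counts.values() if c > 0], dtype=float) / plan.total
    return float(-(p * np.log(p)).sum())


class SamplerContractError(RuntimeError):
    """Raised when a sampler returns a trajectory of the wrong length."""


@dataclass(frozen=True)
class AdaptiveParams:
    """Run-level parameters of the adaptive loop.

    ``n_trajectories`` explorers advance ``steps_per_epoch`` MC steps per
    epoch until each has accumulated ``max_total_steps`` steps.  With
    ``stop_on_binding`` the run ends at the end of the epoch in which the
    first binding event is observed; because all trajectories advance in
    lockstep epochs, the first-passage step is already exact at that point.
    """

    n_trajectories: int
    steps_per_epoch: int = 4
    max_total_steps: int = 3000
    binding_rmsd_cutoff: float = 2.5
    master_seed: int = 0
    spawning: SpawningParams = field(default_factory=SpawningParams)
    stop_on_binding: bool = False
    threshold_policy: Optional[ThresholdPolicy] = None
    density_policy: Optional[DensityPolicy] = None

    def __post_init__(self) -> None:
        if self.n_trajectories < 1 or self.steps_per_epoch < 1:
            raise ValueError("n_trajectories and steps_per_epoch must be >= 1")
        if self.binding_rmsd_cutoff <= 0:
            raise ValueError("binding_rmsd_cutoff must be > 0")
        if self.max_total_steps < self.steps_per_epoch:
            raise ValueError("max_total_steps must be >= steps_per_epoch")


@dataclass
class RunRecord:
    """Everything a run produced: trajectories, cluster state, spawn plans."""

    epochs: List[List[List[Conformation]]]
    epoch_lengths: List[int]
    clustering_state: Optional[ClusteringState]
    spawning_plans: List[SpawningPlan]
    initial_conformation: Conformation

    def iter_conformations(self):
        for trajs in self.epochs:
            for traj in trajs:
                yield from traj


def _resolve_system(
    system: Union[ToySystem, ReceptorFrame],
    initial: Optional[Conformation],
    native: Optional[Conformation],
) -> Tuple[ReceptorFrame, Conformation, Optional[Conformation]]:
    if isinstance(system, ToySystem):
        frame = system.receptor
        initial = initial or system.initial_pose
        native = native or system.native_pose
    else:
        frame = system
        if initial is None:
            raise ValueError("an initial conformation is required with a bare receptor frame")
    return frame, initial, native


def _traj_rng(master_seed: int, epoch: int, traj: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(epoch, traj)))


def _spawn_rng(master_seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(epoch, 1 << 20)))


def _epoch_lengths(params: AdaptiveParams) -> List[int]:
    l, total = params.steps_per_epoch, params.max_total_steps
    n_full, rest = divmod(total, l)
    return [l] * n_full + ([rest] if rest else [])


def _run_epoch(sampler, seeds, epoch, length, params) -> List[List[Conformation]]:
    trajs = []
    for t, (origin, seed_conf) in enumerate(seeds):
        rng = _traj_rng(params.master_seed, epoch, t)
        traj = list(sampler(seed_conf, length, rng))
        if len(traj) != length:
            raise SamplerContractError(
                f"sampler returned {len(traj)} conformations, expected {length}"
            )
        for conf in traj:
            conf.epoch_index = epoch
            conf.trajectory_index = t
            conf.origin_cluster = origin
        trajs.append(traj)
    return trajs


def _epoch_has_binding(trajs, native, cutoff) -> bool:
    for traj in trajs:
        for conf in traj:
            r = conf.metrics.get("rmsd_to_native")
            if r is None:
                r = ligand_rmsd(conf, native)
            if r < cutoff:
                return True
    return False


def run_adaptive(
    sampler,
    system: Union[ToySystem, ReceptorFrame],
    params: AdaptiveParams,
    initial: Optional[Conformation] = None,
    native: Optional[Conformation] = None,
) -> RunRecord:
    """Run the adaptive loop: sample, cluster, spawn, repeat.

    Epoch 0 starts every explorer from the initial pose; each later epoch
    starts them from the cluster centres dictated by the spawning plan.  The
    clustering state persists and accumulates across epochs.  Fully
    reproducible from ``params.master_seed``.
    """
    frame, initial, native = _resolve_system(system, initial, native)
    state = ClusteringState(frame, params.threshold_policy, params.density_policy)
    record = RunRecord(
        epochs=[], epoch_lengths=[], clustering_state=state, spawning_plans=[],
        initial_conformation=initial,
    )
    n = params.n_trajectories
    seeds: List[Tuple[Optional[int], Conformation]] = [(None, initial)] * n
    lengths = _epoch_lengths(params)
    for epoch, length in enumerate(lengths):
        k_before = len(state)
        trajs = _run_epoch(sampler, seeds, epoch, length, params)
        record.epochs.append(trajs)
        record.epoch_lengths.append(length)
        state.add_conformations([c for traj in trajs for c in traj])
        if (
            params.stop_on_binding
            and native is not None
            and _epoch_has_binding(trajs, native, params.binding_rmsd_cutoff)
        ):
            break
        if epoch < len(lengths) - 1:
            plan = spawn(
                state, params.spawning, n, rng=_spawn_rng(params.master_seed, epoch)
            )
            record.spawning_plans.append(plan)
            seeds = []
            for cid in sorted(plan.counts):
                seeds.extend([(cid, state.clusters[cid].center)] * plan.counts[cid])
            logger.info(
                "epoch %d: n=%d new_clusters=%d k=%d comparisons=%d spawn_entropy=%.3f",
                epoch, n * length, len(state) - k_before, len(state),
                state.comparison_count, _plan_entropy(plan),
            )
    return record


def run_independent(
    sampler,
    system: Union[ToySystem, ReceptorFrame],
    params: AdaptiveParams,
    initial: Optional[Conformation] = None,
    native: Optional[Conformation] = None,
) -> RunRecord:
    """Non-adaptive baseline: N trajectories with no clustering feedback.

    Trajectories never restart; each continues from its own last snapshot.
    The epoch chunking and rng-stream derivation match :func:`run_adaptive`
    so the two arms are comparable at matched master seeds.
    """
    frame, initial, native = _resolve_system(system, initial, native)
    record = RunRecord(
        epochs=[], epoch_lengths=[], clustering_state=None, spawning_plans=[],
        initial_conformation=initial,
    )
    n = params.n_trajectories
    current: List[Conformation] = [initial] * n
    for epoch, length in enumerate(_epoch_lengths(params)):
        seeds = [(None, c) for c in current]
        trajs = _run_epoch(sampler, seeds, epoch, length, params)
        record.epochs.append(trajs)
        record.epoch_lengths.append(length)
        current = [traj[-1] for traj in trajs]
        if (
            params.stop_on_binding
            and native is not None
            and _epoch_has_binding(trajs, native, params.binding_rmsd_cutoff)
        ):
            break
    return record


def binding_time(
    record: RunRecord,
    native: Conformation,
    cutoff: float = 2.5,
    cap: int = 3000,
) -> int:
    """First-passage binding step of a run, or the cap if no binding occurred.

    The binding step is the smallest 1-based per-trajectory cumulative step
    index at which any trajectory's ligand RMSD to the native pose is below
    the cutoff.  A run whose initial pose is already below the cutoff binds
    at step 1.
    """
    if ligand_rmsd(record.initial_conformation, native) < cutoff:
        return 1
    offset = 0
    for trajs, length in zip(record.epochs, record.epoch_lengths):
        best: Optional[int] = None
        for traj in trajs:
            for i, conf in enumerate(traj):
                r = conf.metrics.get("rmsd_to_native")
                if r is None:
                    r = ligand_rmsd(conf, native)
                if r < cutoff:
                    step = offset + i + 1
                    if best is None or step < best:
                        best = step
                    break
        if best is not None:
            return min(best, cap)
        offset += length
    return cap


def _strategy_params(strategy: str, overrides: Optional[SpawningParams]) -> SpawningParams:
    if overrides is not None:
        return overrides
    if strategy == "epsilon_greedy":
        return SpawningParams(strategy="epsilon_greedy", epsilon=0.25,
                              metric_name="energy", metric_sense="minimize")
    if strategy == "metric_guided":
        return SpawningParams(strategy="metric_guided",
                              metric_name="energy", metric_sense="minimize")
    return SpawningParams(strategy="inversely_proportional")


def master_seeds(base_seed: int, repeats: int) -> List[int]:
    """Derive ``repeats`` independent 31-bit master seeds from a base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(repeats, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def binding_times(
    system: ToySystem,
    strategy: str,
    n_trajectories: int,
    repeats: int = 10,
    base_seed: int = DEFAULT_BENCHMARK_SEED,
    steps_per_epoch: int = 4,
    max_total_steps: int = 3000,
    cutoff: float = 2.5,
    moves: Optional[MoveParams] = None,
    spawning: Optional[SpawningParams] = None,
) -> np.ndarray:
    """Binding times of one (strategy, N) cell over ``repeats`` master seeds.

    ``strategy`` is one of ``independent``, ``inversely_proportional``,
    ``epsilon_greedy`` or ``metric_guided``; the same derived seed set is
    used for every strategy so arms are matched.
    """
    sampler = make_sampler(system, moves)
    times = []
    for seed in master_seeds(base_seed, repeats):
        params = AdaptiveParams(
            n_trajectories=n_trajectories,
            steps_per_epoch=steps_per_epoch,
            max_total_steps=max_total_steps,
            binding_rmsd_cutoff=cutoff,
            master_seed=seed,
            spawning=_strategy_params(strategy, spawning),
            stop_on_binding=True,
        )
        if strategy == "independent":
            record = run_independent(sampler, system, params)
        else:
            record = run_adaptive(sampler, system, params)
        times.append(binding_time(record, system.native_pose, cutoff, max_total_steps))
    return np.asarray(times)


def benchmark(
    system: ToySystem,
    n_values: Sequence[int],
    repeats: int = 10,
    strategies: Sequence[str] = ("independent", "inversely_proportional", "epsilon_greedy"),
    base_seed: int = DEFAULT_BENCHMARK_SEED,
    **kwargs,
) -> pd.DataFrame:
    """Mean binding times over a (strategy × N) grid of repeated runs.

    Returns a tidy table with one row per cell: strategy, n_trajectories,
    mean_steps, sd_steps, n_binding_events (runs that bound before the step
    cap) and repeats.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    cap = kwargs.get("max_total_steps", 3000)
    rows = []
    for strategy in strategies:
        for n in n_values:
            times = binding_times(
                system, strategy, n, repeats=repeats, base_seed=base_seed, **kwargs
            )
            rows.append(
                {
                    "strategy": strategy,
                    "n_trajectories": n,
                    "mean_steps": float(times.mean()),
                    "sd_steps": float(times.std(ddof=1)),
                    "n_binding_events": int(np.sum(times < cap)),
                    "repeats": repeats,
                }
            )
    return pd.DataFrame(rows)
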