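"""Leader clustering with centroid-distance pruning.

Single-pass clustering: a snapshot joins the first existing cluster (in
creation order) whose centre is within that cluster's RMSD threshold,
otherwise it founds a new cluster and becomes its centre.  The centroid
distance, a lower bound for the RMSD, prunes clusters whose centre cannot
possibly match, so the number of comparisons per epoch is at most k·n for
k clusters and n snapshots.  The cluster list persists across epochs and is
the adaptive run's memory of the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Conformation,
    DensityPolicy,
    ReceptorFrame,
    SizeMismatchError,
    ThresholdPolicy,
    _rmsd,
    contact_ratio,
)

__all__ = ["Cluster", "ClusteringState", "cluster_table"]


@dataclass
class Cluster:
    """One leader cluster: an immutable centre plus accumulated statistics.

    ``visit_count`` counts assigned conformations (the centre included),
    accumulated across epochs; ``metric_min``/``metric_max`` track the
    extrema of every metric seen on member snapshots.
    """

    id: int
    center: Conformation
    threshold: float
    contact_ratio: float
    density: float
    visit_count: int = 1
    metric_min: Dict[str, float] = field(default_factory=dict)
    metric_max: Dict[str, float] = field(default_factory=dict)

    def _absorb_metrics(self, metrics: Dict[str, float]) -> None:
        for name, value in metrics.items():
            if name not in self.metric_min or value < self.metric_min[name]:
                self.metric_min[name] = value
            if name not in self.metric_max or value > self.metric_max[name]:
                self.metric_max[name] = value


class ClusteringState:
    """Ordered cluster list plus the threshold/density policy.

    Parameters
    ----------
    frame
        Receptor Cα frame used to compute contact ratios for new centres
        (snapshots carrying a cached ``"contact_ratio"`` metric skip the
        recomputation).
    threshold_policy, density_policy
        The contact-dependent discretisation: RMSD thresholds shrink and
        spawning densities grow with the contact ratio.
    """

    def __init__(
        self,
        frame: ReceptorFrame,
        threshold_policy: Optional[ThresholdPolicy] = None,
        density_policy: Optional[DensityPolicy] = None,
    ) -> None:
        self.frame = frame
        self.threshold_policy = threshold_policy or ThresholdPolicy()
        self.density_policy = density_policy or DensityPolicy()
        self.clusters: List[Cluster] = []
        self.comparison_count = 0
        # cached centre geometry for the vectorised centroid prune
        self._centroids: List[np.ndarray] = []
        self._thresholds: List[float] = []

    def __len__(self) -> int:
        return len(self.clusters)

    def _contact_ratio_of(self, conf: Conformation) -> float:
        cached = conf.metrics.get("contact_ratio")
        if cached is not None:
            return float(cached)
        return contact_ratio(conf, self.frame)

    def assign(self, conf: Conformation) -> int:
        """Assign one snapshot to the first matching cluster, else found one.

        Clusters are scanned in creation order; a cluster whose centroid
        distance to the snapshot already reaches its threshold is pruned
        without an RMSD evaluation (the lower bound guarantees it cannot
        match).  Every cluster inspected up to the match point counts one
        comparison.  Returns the receiving cluster id.
        """
        k = len(self.clusters)
        if k:
            if conf.n_atoms != self.clusters[0].center.n_atoms:
                raise SizeMismatchError(
                    f"conformation has {conf.n_atoms} atoms, clusters have "
                    f"{self.clusters[0].center.n_atoms}"
                )
            centroids = np.asarray(self._centroids)
            thresholds = np.asarray(self._thresholds)
            cd = np.linalg.norm(centroids - conf.centroid, axis=1)
            for idx in np.nonzero(cd < thresholds)[0]:
                cluster = self.clusters[idx]
                if _rmsd(conf.ligand_coords, cluster.center.ligand_coords) < cluster.threshold:
                    self.comparison_count += int(idx) + 1
                    cluster.visit_count += 1
                    cluster._absorb_metrics(conf.metrics)
                    return cluster.id
        self.comparison_count += k
        return self._found_cluster(conf)

    def _found_cluster(self, conf: Conformation) -> int:
        c = self._contact_ratio_of(conf)
        threshold = self.threshold_policy.threshold_for(c)
        density = self.density_policy.density_for(c, threshold)
        cluster = Cluster(
            id=len(self.clusters),
            center=conf,
            threshold=threshold,
            contact_ratio=c,
            density=density,
        )
        cluster._absorb_metrics(conf.metrics)
        self.clusters.append(cluster)
        self._centroids.append(conf.centroid)
        self._thresholds.append(threshold)
        return cluster.id

    def add_conformations(self, confs: Sequence[Conformation]) -> "ClusteringState":
        """Assign a batch sequentially in the given (trajectory, step) order."""
        for conf in confs:
            self.assign(conf)
        return self


def cluster_table(state: ClusteringState) -> pd.DataFrame:
    """Tabular report: one row per cluster with its statistics and centre."""
    rows = []
    for cl in state.clusters:
        row = {
            "cluster_id": cl.id,
            "contact_ratio": cl.contact_ratio,
            "threshold": cl.threshold,
            "density": cl.density,
            "visit_count": cl.visit_count,
            "center_x": cl.center.centroid[0],
            "center_y": cl.center.centroid[1],
            "center_z": cl.center.centroid[2],
        }
        for name in sorted(cl.metric_min):
            row[f"{name}_min"] = cl.metric_min[name]
            row[f"{name}_max"] = cl.metric_max[name]
        rows.append(row)
    return pd.DataFrame(rows)
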