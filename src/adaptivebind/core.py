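"""Domain types and stateless geometry/policy primitives.

The adaptive exploration framework discretises ligand poses with a leader
clustering over ligand RMSD, using thresholds and spawning densities that
depend on how buried the ligand is.  Burial is measured by the *contact
ratio* ``c``: the number of protein-Cα/ligand-heavy-atom pairs closer than
a cutoff (8 Å by default), divided by the number of ligand heavy atoms.
Poses with ``c <= 0.5`` are solvent exposed; ``c > 1`` marks the rugged
protein frame where a finer discretisation is needed.

All coordinates are Cartesian ångström; RMSD is computed in the shared
receptor frame without superposition and without ligand-symmetry search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Conformation",
    "ReceptorFrame",
    "ThresholdPolicy",
    "DensityPolicy",
    "SizeMismatchError",
    "ligand_rmsd",
    "centroid_distance",
    "contact_ratio",
    "threshold_for",
    "density_for",
    "DEFAULT_THRESHOLD_POLICY",
    "DEFAULT_DENSITY_POLICY",
    "CONTACT_CUTOFF",
]

#: Default Cα–ligand contact cutoff in Å; a pair counts as a contact when
#: its distance is strictly below this value.
CONTACT_CUTOFF = 8.0


class SizeMismatchError(ValueError):
    """Raised when two conformations do not share the ligand atom count."""


def _as_coords(x: object) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise ValueError(f"expected a non-empty (n, 3) coordinate array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")
    return arr


@dataclass
class Conformation:
    """One ligand snapshot: coordinates plus provenance and cached metrics.

    Parameters
    ----------
    ligand_coords
        Ordered ``(n_atoms, 3)`` heavy-atom coordinates in Å, in the fixed
        receptor frame.
    epoch_index, trajectory_index, step_index
        Provenance of the snapshot within the adaptive run.
    metrics
        Cached per-snapshot scalars (e.g. ``"energy"``, ``"rmsd_to_native"``,
        ``"contact_ratio"``).  A metric, once written, is immutable.
    origin_cluster
        Id of the cluster whose centre seeded the trajectory, if any.
    """

    ligand_coords: np.ndarray
    epoch_index: int = 0
    trajectory_index: int = 0
    step_index: int = 0
    metrics: dict = field(default_factory=dict)
    origin_cluster: Optional[int] = None

    def __post_init__(self) -> None:
        self.ligand_coords = _as_coords(self.ligand_coords)
        for i in (self.epoch_index, self.trajectory_index, self.step_index):
            if i < 0:
                raise ValueError("provenance indices must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.ligand_coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.ligand_coords.mean(axis=0)

    def set_metric(self, name: str, value: float) -> None:
        """Record a metric value; re-recording a different value is an error."""
        if name in self.metrics:
            if self.metrics[name] != value:
                raise ValueError(f"metric {name!r} already set to {self.metrics[name]!r}")
            return
        self.metrics[name] = float(value)


@dataclass
class ReceptorFrame:
    """The fixed protein reference used for contacts: Cα coordinates only."""

    calpha_coords: np.ndarray
    contact_cutoff: float = CONTACT_CUTOFF

    def __post_init__(self) -> None:
        self.calpha_coords = _as_coords(self.calpha_coords)
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")


@dataclass(frozen=True)
class ThresholdPolicy:
    """Piecewise-constant, non-increasing RMSD threshold as a function of c.

    ``bands`` is an ordered sequence of ``(c_upper_bound, threshold)`` pairs;
    a contact ratio ``c`` falls in the first band with ``c <= c_upper_bound``,
    and above the last bound the ``terminal`` threshold applies.  The default
    table steps from 5 Å in the solvent (c ≤ 0.5) down to 2 Å in the protein
    frame (c > 1).
    """

    bands: Tuple[Tuple[float, float], ...] = ((0.5, 5.0), (0.75, 4.0), (1.0, 3.0))
    terminal: float = 2.0

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.bands]
        thrs = [t for _, t in self.bands] + [self.terminal]
        if any(t <= 0 for t in thrs):
            raise ValueError("thresholds must be > 0")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("c upper bounds must be strictly increasing")
        if any(t2 > t1 for t1, t2 in zip(thrs, thrs[1:])):
            raise ValueError("thresholds must be non-increasing in c")

    def threshold_for(self, c: float) -> float:
        if c < 0:
            raise ValueError("contact ratio must be >= 0")
        for bound, thr in self.bands:
            if c <= bound:
                return thr
        return self.terminal


@dataclass(frozen=True)
class DensityPolicy:
    """Spawning density ρ assigned to a cluster at creation.

    Modes
    -----
    ``constant``
        ρ = 1 everywhere: the baseline that spreads exploration over the
        whole domain.
    ``inverse_volume``
        ρ ∝ 1/V with the cluster volume taken proportional to threshold³,
        normalised so the widest (reference) threshold has ρ = 1.
    ``contacts``
        Band lookup on the contact ratio, mirroring the threshold bands;
        denser spawning where the landscape is rugged.
    """

    mode: str = "inverse_volume"
    reference_threshold: float = 5.0
    contact_bands: Tuple[Tuple[float, float], ...] = ((0.5, 1.0), (0.75, 2.0), (1.0, 4.0))
    contact_terminal: float = 8.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "contacts", "inverse_volume"):
            raise ValueError(f"unknown density mode {self.mode!r}")
        if self.reference_threshold <= 0:
            raise ValueError("reference_threshold must be > 0")
        if any(v <= 0 for _, v in self.contact_bands) or self.contact_terminal <= 0:
            raise ValueError("densities must be > 0")

    def density_for(self, c: float, threshold: float) -> float:
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.mode == "constant":
            return 1.0
        if self.mode == "inverse_volume":
            return (self.reference_threshold / threshold) ** 3
        for bound, rho in self.contact_bands:
            if c <= bound:
                return rho
        return self.contact_terminal


DEFAULT_THRESHOLD_POLICY = ThresholdPolicy()
DEFAULT_DENSITY_POLICY = DensityPolicy()


def _matched_coords(a: Conformation, b: Conformation) -> Tuple[np.ndarray, np.ndarray]:
    if a.n_atoms != b.n_atoms:
        raise SizeMismatchError(f"ligand atom counts differ: {a.n_atoms} vs {b.n_atoms}")
    return a.ligand_coords, b.ligand_coords


def _rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    d = xa - xb
    return math.sqrt(float(np.einsum("ij,ij->", d, d)) / xa.shape[0])


def ligand_rmsd(a: Conformation, b: Conformation) -> float:
    """Ligand RMSD between two snapshots in the shared receptor frame.

    No superposition is performed and atom order must match; raises
    :class:`SizeMismatchError` on differing atom counts.
    """
    xa, xb = _matched_coords(a, b)
    return _rmsd(xa, xb)


def centroid_distance(a: Conformation, b: Conformation) -> float:
    """Distance between ligand centroids — a lower bound for the RMSD.

    For any two matched coordinate sets the centroid distance never exceeds
    the RMSD, with equality under pure rigid translation; this makes it a
    cheap pruning test before the full RMSD evaluation.
    """
    xa, xb = _matched_coords(a, b)
    return float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))


def contact_ratio(conf: Conformation, frame: ReceptorFrame) -> float:
    """Protein–ligand contact pairs within the cutoff per ligand heavy atom.

    A (Cα, ligand-atom) pair is a contact when its distance is *strictly*
    below ``frame.contact_cutoff``; ties at exactly the cutoff do not count.
    """
    diff = conf.ligand_coords[:, None, :] - frame.calpha_coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    n_contacts = int(np.count_nonzero(d2 < frame.contact_cutoff**2))
    return n_contacts / conf.n_atoms


def threshold_for(c: float, policy: ThresholdPolicy = DEFAULT_THRESHOLD_POLICY) -> float:
    """Cluster RMSD threshold (Å) for a contact ratio under a step policy."""
    return policy.threshold_for(c)


def density_for(
    c: float, threshold: float, policy: DensityPolicy = DEFAULT_DENSITY_POLICY
) -> float:
    """Spawning density ρ for a cluster with the given c and threshold."""
    return policy.density_for(c, threshold)
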