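"""Shared fixtures and independent reference implementations.

The reference functions here (brute-force RMSD, naive unpruned leader
clustering, largest-remainder enumeration) deliberately avoid the package's
own fast paths so they can serve as independent oracles.
"""

import math

import numpy as np
import pytest

from adaptivebind import (
    Conformation,
    DensityPolicy,
    ReceptorFrame,
    ThresholdPolicy,
    build_toy_system,
)


@pytest.fixture(scope="session")
def toy_system():
    return build_toy_system()


@pytest.fixture()
def small_frame():
    """A handful of pseudo-Cα points around the origin."""
    rng = np.random.default_rng(7)
    return ReceptorFrame(rng.normal(scale=4.0, size=(8, 3)))


def brute_force_rmsd(a: Conformation, b: Conformation) -> float:
    """Per-atom-pair evaluation of the RMSD formula, written longhand."""
    total = 0.0
    for xa, xb in zip(a.ligand_coords, b.ligand_coords):
        total += sum((float(p) - float(q)) ** 2 for p, q in zip(xa, xb))
    return math.sqrt(total / len(a.ligand_coords))


def brute_force_contact_pairs(conf: Conformation, frame: ReceptorFrame) -> int:
    """Double loop over (Cα, ligand atom) pairs with the strict cutoff."""
    pairs = 0
    for ca in frame.calpha_coords:
        for atom in conf.ligand_coords:
            if math.dist(ca, atom) < frame.contact_cutoff:
                pairs += 1
    return pairs


def random_conformations(rng, n, n_atoms=5, spread=12.0, atom_scale=1.5):
    """Random rigid-ish conformations scattered in a sphere of ``spread`` Å."""
    confs = []
    for _ in range(n):
        center = rng.normal(scale=spread / 2.0, size=3)
        atoms = center + rng.normal(scale=atom_scale, size=(n_atoms, 3))
        confs.append(Conformation(atoms))
    return confs


def naive_leader(confs, frame, threshold_policy=None, density_policy=None):
    """Unpruned leader clustering: always evaluates the RMSD.

    Returns (centers, thresholds, assignments, visit_counts).
    """
    from adaptivebind import contact_ratio

    threshold_policy = threshold_policy or ThresholdPolicy()
    centers, thresholds, assignments = [], [], []
    visits = []
    for conf in confs:
        placed = None
        for j, (center, thr) in enumerate(zip(centers, thresholds)):
            if brute_force_rmsd(conf, center) < thr:
                placed = j
                break
        if placed is None:
            thr = threshold_policy.threshold_for(contact_ratio(conf, frame))
            centers.append(conf)
            thresholds.append(thr)
            visits.append(1)
            placed = len(centers) - 1
        else:
            visits[placed] += 1
        assignments.append(placed)
    return centers, thresholds, assignments, visits
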