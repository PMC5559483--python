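"""A toy protein–ligand Metropolis Monte Carlo sampler.

The sampler stands in for a full protein–ligand MC engine while keeping the
statistical structure that adaptive spawning exploits: a rigid receptor
pocket whose interior is reachable only through an aperture channel, an
energy funnel toward a buried native pose, a metastable decoy sub-pocket
near the pocket mouth, and ligand moves whose translation magnitude depends
on how solvent-exposed the ligand is.  Energies are in kT-scale surrogate
units (loosely kcal/mol); no thermodynamic accuracy is claimed.

The ligand is a 5-point rigid body (centroid plus four tetrahedral offsets)
so RMSD, rotation and contact ratio are all non-trivial yet cheap.

For detailed-balance smoke testing the module also exposes
:func:`double_well_energy`, a 1-D two-well reduction of the energy surface:
two Gaussian wells on a line, sampled with the same Metropolis rule, whose
occupancies can be checked against Boltzmann weights by quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .core import Conformation, ReceptorFrame, _rmsd

__all__ = [
    "MoveParams",
    "ToySystem",
    "ToySystemError",
    "build_toy_system",
    "energy",
    "exposure",
    "metropolis_accept",
    "mc_trajectory",
    "make_sampler",
    "double_well_energy",
]

#: Contact-ratio value at which the exposure surrogate saturates to 0
#: (fully buried).  exposure = 1 − min(c / C_SAT, 1).
C_SAT = 2.0


class ToySystemError(ValueError):
    """Raised when requested geometry violates the construction invariants."""


@dataclass(frozen=True)
class MoveParams:
    """Rigid-body move rules for the toy ligand.

    Solvent-exposed poses (exposure above ``exposure_cutoff``) translate by
    ``exposed_translation`` Å; buried poses translate by a magnitude drawn
    uniformly from ``buried_translation_range``.  The translation direction
    is redrawn every ``direction_persistence`` steps; every step also applies
    a rotation by an angle uniform in ``rotation_range`` (degrees) about a
    random axis through the ligand centroid.
    """

    exposed_translation: float = 3.0
    buried_translation_range: Tuple[float, float] = (0.75, 1.5)
    exposure_cutoff: float = 0.6
    rotation_range: Tuple[float, float] = (20.0, 60.0)
    direction_persistence: int = 4

    def __post_init__(self) -> None:
        if self.buried_translation_range[0] > self.buried_translation_range[1]:
            raise ValueError("buried_translation_range must be ordered")
        if self.rotation_range[0] > self.rotation_range[1]:
            raise ValueError("rotation_range must be ordered")
        if self.direction_persistence < 1:
            raise ValueError("direction_persistence must be >= 1")


@dataclass
class ToySystem:
    """Synthetic receptor + ligand system with a two-well energy surface.

    The receptor is represented by two point sets.  ``receptor`` holds the
    sparse pseudo-Cα trace lining the binding channel, cavity and decoy
    sub-pocket — the contact reference, so the contact ratio grades from 0
    in the bulk through the intermediate bands at the channel mouth to
    well above 1 inside.  ``scaffold_coords`` is the dense excluded-volume
    body (outer wall plus decoy cup plus the Cα points themselves) that
    only enters the soft-core repulsion.

    The energy of a pose is

        E = −D_nat·exp(−RMSD_nat²/2w_nat²) − D_dec·exp(−RMSD_dec²/2w_dec²)
            + Σ_pairs k_rep·(1 − d/r_rep)²·[d < r_rep]
            + k_wall·(|x̄ − x_wall| − R_wall)²·[outside wall]

    where RMSD_nat/RMSD_dec are ligand RMSDs to the native and decoy poses,
    the repulsion runs over (ligand atom, scaffold point) pairs, and the
    harmonic wall confines the ligand centroid to a sphere centred midway
    between the native and initial poses.
    """

    receptor: ReceptorFrame
    scaffold_coords: np.ndarray
    native_pose: Conformation
    initial_pose: Conformation
    decoy_coords: np.ndarray
    native_depth: float
    native_width: float
    decoy_depth: float
    decoy_width: float
    repulsion_radius: float
    repulsion_strength: float
    kT: float
    wall_center: np.ndarray
    wall_radius: float
    wall_strength: float
    build_seed: int

    def __post_init__(self) -> None:
        # bulk fast path: beyond these centroid radii no pair can interact
        lig = float(np.max(np.linalg.norm(
            self.native_pose.ligand_coords - self.native_pose.centroid, axis=1)))
        self._scaffold_reach = (
            float(np.max(np.linalg.norm(self.scaffold_coords, axis=1)))
            + lig + self.repulsion_radius
        )
        self._contact_reach = (
            float(np.max(np.linalg.norm(self.receptor.calpha_coords, axis=1)))
            + lig + self.receptor.contact_cutoff
        )

    def energy_and_contacts(self, coords: np.ndarray) -> Tuple[float, float]:
        """Energy of a ligand coordinate set and its contact ratio.

        Contacts and repulsion both need ligand–receptor distances, so the
        two quantities are computed together.
        """
        n = coords.shape[0]
        msd_nat = float(np.sum((coords - self.native_pose.ligand_coords) ** 2)) / n
        msd_dec = float(np.sum((coords - self.decoy_coords) ** 2)) / n
        e = -self.native_depth * math.exp(-msd_nat / (2.0 * self.native_width**2))
        e -= self.decoy_depth * math.exp(-msd_dec / (2.0 * self.decoy_width**2))

        centroid = coords.mean(axis=0)
        dist0 = float(np.linalg.norm(centroid))

        c = 0.0
        if dist0 <= self._contact_reach:
            diff = coords[:, None, :] - self.receptor.calpha_coords[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            c = float(np.count_nonzero(d2 < self.receptor.contact_cutoff**2)) / n

        if dist0 <= self._scaffold_reach:
            diff = coords[:, None, :] - self.scaffold_coords[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            close = d2 < self.repulsion_radius**2
            if np.any(close):
                d = np.sqrt(d2[close])
                e += self.repulsion_strength * float(
                    np.sum((1.0 - d / self.repulsion_radius) ** 2)
                )

        excess = float(np.linalg.norm(centroid - self.wall_center)) - self.wall_radius
        if excess > 0:
            e += self.wall_strength * excess**2
        return e, c


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _ligand_template(radius: float) -> np.ndarray:
    """5-point rigid ligand: centroid plus four tetrahedral vertices."""
    s = radius / math.sqrt(3.0)
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * s
    return np.vstack([np.zeros(3), verts])


def build_toy_system(
    build_seed: int = 2017,
    *,
    pocket_radius: float = 13.0,
    aperture_deg: float = 22.0,
    n_shell: int = 700,
    cavity_radius: float = 5.5,
    n_cavity_calpha: int = 10,
    n_rim_calpha: int = 6,
    decoy_distance: float = 8.75,
    decoy_polar_deg: float = 60.0,
    cup_radius: float = 3.25,
    n_cup: int = 40,
    n_cup_calpha: int = 8,
    ligand_radius: float = 1.5,
    native_depth: float = 8.0,
    native_width: float = 3.0,
    decoy_depth: float = 5.0,
    decoy_width: float = 3.0,
    repulsion_radius: float = 2.2,
    repulsion_strength: float = 6.0,
    kT: float = 1.0,
    wall_radius: float = 18.0,
    wall_strength: float = 5.0,
    initial_distance: float = 20.0,
    initial_polar_deg: float = 90.0,
    contact_cutoff: float = 8.0,
) -> ToySystem:
    """Construct the default buried-pocket / decoy-site toy system.

    The excluded-volume scaffold is a dense spherical shell of radius
    ``pocket_radius`` centred on the native pose, with a cone of half-angle
    ``aperture_deg`` about +z removed to form the entry channel, plus a
    dense decoy cup around a metastable pose inside the vestibule, just off
    the channel path.  The pseudo-Cα contact set is sparse: a ring at the
    channel mouth, a lining around the cavity holding the native pose, and
    a subset of the decoy cup — so the contact ratio is 0 in the bulk,
    passes through the intermediate threshold bands on approach, and
    exceeds 1 inside the channel, cavity and decoy.

    The ligand starts in the bulk at ``initial_distance`` Å from the native
    pose, at polar angle ``initial_polar_deg`` from the channel axis
    (off-axis, so the entry channel must be found by diffusion), and its
    centroid is confined to a sphere of radius ``wall_radius`` centred
    midway between the native and initial poses.

    Deterministic in ``build_seed`` (a small jitter decorrelates the point
    lattices between seeds).  Raises :class:`ToySystemError` when the
    geometry violates the construction invariants (native pose buried with
    c > 1, initial pose solvent-exposed with c ≤ 0.5, energies ordered
    native < decoy < bulk).
    """
    if not 6.0 < pocket_radius <= 20.0:
        raise ToySystemError("pocket_radius must lie in (6, 20] Å")
    if not 10.0 <= aperture_deg <= 80.0:
        raise ToySystemError("aperture_deg must lie in [10, 80]")
    if not 2.0 < cavity_radius < pocket_radius - 2.0:
        raise ToySystemError("cavity_radius must lie in (2, pocket_radius - 2)")
    if initial_distance < 15.0:
        raise ToySystemError("initial_distance must be >= 15 Å")

    rng = np.random.default_rng(build_seed)
    template = _ligand_template(ligand_radius)

    # outer wall with the aperture cone removed (repulsion only)
    pts = _fibonacci_sphere(n_shell)
    pts = pts[pts[:, 2] < math.cos(math.radians(aperture_deg))]
    shell = pts * pocket_radius + rng.normal(scale=0.05, size=(len(pts), 3))

    # decoy cup inside the vestibule, opening toward the channel axis
    theta = math.radians(decoy_polar_deg)
    decoy_center = decoy_distance * np.array([math.sin(theta), 0.0, math.cos(theta)])
    opening = -decoy_center / np.linalg.norm(decoy_center)
    cup_pts = _fibonacci_sphere(3 * n_cup)
    cup_pts = cup_pts[cup_pts @ opening < 0.3][:n_cup]
    cup = decoy_center + cup_pts * cup_radius + rng.normal(scale=0.05, size=(len(cup_pts), 3))

    # sparse pseudo-Cα trace: mouth rim ring + cavity lining + decoy subset
    az = 2.0 * math.pi * (np.arange(n_rim_calpha) + 0.5) / n_rim_calpha
    rim_polar = math.radians(aperture_deg + 4.0)
    rim = pocket_radius * np.column_stack(
        [
            math.sin(rim_polar) * np.cos(az),
            math.sin(rim_polar) * np.sin(az),
            np.full(n_rim_calpha, math.cos(rim_polar)),
        ]
    )
    lining_pts = _fibonacci_sphere(3 * n_cavity_calpha)
    lining_pts = lining_pts[lining_pts[:, 2] < math.cos(math.radians(45.0))][:n_cavity_calpha]
    lining = lining_pts * cavity_radius
    stride = max(1, len(cup) // max(1, n_cup_calpha))
    cup_calpha = cup[::stride][:n_cup_calpha]
    rim_lining = np.vstack([rim, lining])
    rim_lining += rng.normal(scale=0.05, size=rim_lining.shape)
    calpha = np.vstack([rim_lining, cup_calpha])

    receptor = ReceptorFrame(calpha, contact_cutoff=contact_cutoff)
    # cup Cαs are cup points, already in the scaffold once
    scaffold = np.vstack([shell, cup, rim_lining])
    native = Conformation(template.copy())
    decoy_coords = template + decoy_center
    phi = math.radians(initial_polar_deg)
    initial_center = initial_distance * np.array([math.sin(phi), 0.0, math.cos(phi)])
    initial = Conformation(template + initial_center)
    wall_center = initial_center / 2.0

    system = ToySystem(
        receptor=receptor,
        scaffold_coords=scaffold,
        native_pose=native,
        initial_pose=initial,
        decoy_coords=decoy_coords,
        native_depth=native_depth,
        native_width=native_width,
        decoy_depth=decoy_depth,
        decoy_width=decoy_width,
        repulsion_radius=repulsion_radius,
        repulsion_strength=repulsion_strength,
        kT=kT,
        wall_center=wall_center,
        wall_radius=wall_radius,
        wall_strength=wall_strength,
        build_seed=build_seed,
    )

    e_nat, c_nat = system.energy_and_contacts(native.ligand_coords)
    e_dec, _ = system.energy_and_contacts(decoy_coords)
    e_bulk, c_ini = system.energy_and_contacts(initial.ligand_coords)
    if not e_nat < e_dec < e_bulk:
        raise ToySystemError(
            f"energy ordering violated: native {e_nat:.2f}, decoy {e_dec:.2f}, bulk {e_bulk:.2f}"
        )
    if c_nat <= 1.0:
        raise ToySystemError(f"native pose not buried: contact ratio {c_nat:.2f} <= 1")
    if c_ini > 0.5:
        raise ToySystemError(f"initial pose not solvent-exposed: contact ratio {c_ini:.2f} > 0.5")
    if float(np.linalg.norm(initial.centroid - native.centroid)) < 15.0:
        raise ToySystemError("initial pose closer than 15 Å to the native centroid")
    return system


def energy(conf: Conformation, system: ToySystem) -> float:
    """Energy of a snapshot (surrogate kcal/mol)."""
    if conf.n_atoms != system.native_pose.n_atoms:
        raise ValueError("conformation does not match the system's ligand template")
    return system.energy_and_contacts(conf.ligand_coords)[0]


def exposure(conf: Conformation, system: ToySystem) -> float:
    """Solvent-exposure surrogate in [0, 1]: 1 − min(c / 2, 1).

    1 in the bulk, 0 when deeply buried; monotone non-increasing in the
    contact ratio.  This gates the translation magnitude the way relative
    SASA gates it in all-atom engines.
    """
    c = conf.metrics.get("contact_ratio")
    if c is None:
        c = system.energy_and_contacts(conf.ligand_coords)[1]
    return 1.0 - min(float(c) / C_SAT, 1.0)


def metropolis_accept(delta_e: float, kT: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(−ΔE/kT))."""
    if delta_e <= 0:
        return True
    if kT <= 0:
        return False
    return rng.random() < math.exp(-delta_e / kT)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues' formula
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def mc_trajectory(
    seed_conf: Conformation,
    system: ToySystem,
    moves: MoveParams,
    length: int,
    rng: np.random.Generator,
) -> List[Conformation]:
    """Run ``length`` Metropolis steps from a seed pose.

    Each step proposes a rigid rotation about the ligand centroid plus a
    translation whose magnitude follows the exposure gating; the proposal is
    accepted with probability min(1, exp(−ΔE/kT)).  A rejected step emits a
    repeated snapshot so the trajectory has exactly ``length`` snapshots.
    Every snapshot carries the metrics ``"energy"``, ``"rmsd_to_native"``
    and ``"contact_ratio"``.
    """
    if length < 1:
        raise ValueError("trajectory length must be >= 1")
    coords = seed_conf.ligand_coords
    cur_e = seed_conf.metrics.get("energy")
    cur_c = seed_conf.metrics.get("contact_ratio")
    if cur_e is None or cur_c is None:
        cur_e, cur_c = system.energy_and_contacts(coords)

    native = system.native_pose.ligand_coords
    direction = None
    out: List[Conformation] = []
    for step in range(length):
        if step % moves.direction_persistence == 0:
            direction = _random_unit(rng)
        if 1.0 - min(cur_c / C_SAT, 1.0) > moves.exposure_cutoff:
            magnitude = moves.exposed_translation
        else:
            magnitude = rng.uniform(*moves.buried_translation_range)
        axis = _random_unit(rng)
        angle = math.radians(rng.uniform(*moves.rotation_range))
        centroid = coords.mean(axis=0)
        proposal = (coords - centroid) @ _rotation_matrix(axis, angle).T
        proposal += centroid + magnitude * direction
        prop_e, prop_c = system.energy_and_contacts(proposal)
        if metropolis_accept(prop_e - cur_e, system.kT, rng):
            coords, cur_e, cur_c = proposal, prop_e, prop_c
        out.append(
            Conformation(
                coords,
                step_index=step,
                metrics={
                    "energy": cur_e,
                    "rmsd_to_native": _rmsd(coords, native),
                    "contact_ratio": cur_c,
                },
            )
        )
    return out


def make_sampler(system: ToySystem, moves: Optional[MoveParams] = None):
    """Wrap a system as a sampler callable ``(seed, length, rng) -> trajectory``."""
    moves = moves or MoveParams()

    def sampler(seed_conf: Conformation, length: int, rng: np.random.Generator):
        return mc_trajectory(seed_conf, system, moves, length, rng)

    return sampler


def double_well_energy(
    x: float,
    depth_a: float = 3.0,
    depth_b: float = 1.5,
    x_a: float = -2.0,
    x_b: float = 2.0,
    width: float = 0.8,
) -> float:
    """1-D two-well reduction of the toy energy: two Gaussian wells on a line.

    Used to smoke-test detailed balance: a long Metropolis chain with
    symmetric proposals must occupy the wells in the ratio of their Boltzmann
    weights.
    """
    return -depth_a * math.exp(-((x - x_a) ** 2) / (2 * width**2)) - depth_b * math.exp(
        -((x - x_b) ** 2) / (2 * width**2)
    )
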