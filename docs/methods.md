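# Methods

## The adaptive exploration loop

`adaptivebind` implements iterative adaptive sampling for protein–ligand
binding as a multi-armed-bandit problem. One *epoch* consists of three
steps:

1. **Sampling** — a swarm of N short trajectories ("explorers") of l Monte
   Carlo steps each, run independently from their seed poses. The sampler
   is pluggable: any callable `(seed_conformation, length, rng) → list of
   conformations` satisfies the contract. The package ships a toy rigid-body
   Metropolis sampler (below).
2. **Clustering** — every new snapshot is fed, in (trajectory, step) order,
   to a single-pass *leader* clustering over ligand RMSD: a snapshot joins
   the first existing cluster (in creation order) whose centre is within
   that cluster's RMSD threshold, otherwise it founds a new cluster and
   becomes its immutable centre. The centroid distance, which never exceeds
   the RMSD for matched atom sets, prunes clusters that cannot match, so at
   most k·n comparisons are made for k clusters and n snapshots. The
   cluster list persists across epochs.
3. **Spawning** — each cluster is an arm and each seed a pull. Clusters
   receive a reward r and the N seeds for the next epoch are distributed
   with probability proportional to r (reward-proportional Thompson-style
   sampling), each seeded trajectory starting from its cluster's centre.

Rewards:

* **inversely proportional**: r = ρ/C, with ρ the cluster's spawning
  density and C its accumulated visit count (centre included). The 1/C
  factor drives the long-run population ratio of any two clusters to the
  ratio of their densities — a metric-free diffusion over the discretised
  landscape (verified by the population-balance test: a two-cluster chain
  starting 25:1 unbalanced reaches a 1:1 visit ratio within 5% after 200
  epochs).
* **metric guided**: with per-cluster extrema m_i,min/m_i,max of a chosen
  metric (e.g. the pose energy) and global extrema m_min/m_max, the reward
  is m_i,min − m_min when maximising and m_max − m_i,max when minimising,
  so the globally worst cluster scores zero. This extremum pairing is
  implemented exactly as published; pairing the reward with the
  per-cluster *best* value instead (maximise ↦ m_i,max, minimise ↦
  m_i,min) is available behind the `use_cluster_best` switch but is not
  the default, since the published definition is not obviously a typo and
  silent reinterpretation would be worse than an explicit option.
* **ε-greedy**: round-half-up((1−ε)·N) seeds follow the metric-guided
  reward and the remainder the inversely proportional one; the two partial
  plans are summed. ε defaults to 0.25 (no published value exists; a
  3:1 exploitation:diffusion split is a conventional middle ground).

Allocation is either stochastic (one multinomial draw with p_i = r_i/Σr)
or deterministic (largest-remainder apportionment of N·p_i, ties to the
lower cluster id). All-zero rewards fall back to uniform probabilities so
the degenerate first epoch still explores.

## Contact-dependent discretisation

Landscape ruggedness is assumed to grow with the number of protein–ligand
contacts. The contact ratio c counts (Cα, ligand-heavy-atom) pairs at
distance strictly below 8 Å, divided by the number of ligand heavy atoms;
c ≤ 0.5 marks solvent-exposed poses and c > 1 the protein frame. Cluster
RMSD thresholds follow a step function of c, by default

| c band        | threshold |
|---------------|-----------|
| c ≤ 0.5       | 5 Å       |
| 0.5 < c ≤ 0.75| 4 Å       |
| 0.75 < c ≤ 1  | 3 Å       |
| c > 1         | 2 Å       |

The 5 Å and 2 Å endpoints and their c bands are the published operating
points; the two interior bands interpolate them linearly and are
configurable (the full published table is not available in the source
text). Spawning densities default to ρ ∝ 1/V with the cluster volume taken
proportional to threshold³ and the widest threshold as reference (ρ = 1 in
the bulk up to ρ = 15.6 in the protein frame); a constant ρ = 1 mode and a
direct band lookup on c are also provided. Only relative densities matter.

RMSD is computed in the fixed receptor frame without superposition and
without ligand-symmetry correction: clustering operates on raw poses, and
symmetry handling is orthogonal to the method.

## The toy system

The benchmark needs a system that exhibits, at desk scale, the statistical
structure adaptive spawning exploits: slow diffusive search for a buried
site, a rugged high-contact region, and a metastable decoy. The shipped
`ToySystem` is built from two point sets:

* an **excluded-volume scaffold** (repulsion only): a dense spherical
  shell of radius 13 Å around the native pose with a 22° cone removed to
  form the entry channel, plus a dense cup of radius 3.25 Å around a decoy
  pose inside the vestibule, just off the channel path;
* a **pseudo-Cα contact set** (the `ReceptorFrame`): a sparse ring at the
  channel mouth, a sparse lining around the cavity and a subset of the
  decoy cup. Keeping the contact set sparse and localised makes the
  contact ratio grade the way the banding assumes — 0 in the bulk,
  through the intermediate bands on approach, ≫ 1 inside — which a single
  dense point cloud cannot do: with an 8 Å cutoff every pose near a small
  dense body counts as buried, including poses crawling the outside wall.

The ligand is a 5-point rigid body (centroid plus four tetrahedral offsets
at 1.5 Å), so RMSD, rotations and contacts are all non-trivial yet cheap.
Its energy is two Gaussian wells in RMSD (native: depth 8, width 3 Å;
decoy: depth 5, width 3 Å, in kT-scale surrogate units with kT = 1), a
soft-core quadratic repulsion of radius 2.2 Å against the scaffold, and a
harmonic wall confining the centroid to an 18 Å sphere centred midway
between the native pose and the start. The start lies 20 Å from the native
pose, perpendicular to the channel axis, so the channel must be found by
diffusion. The wall radius is 18 Å rather than a tighter sphere because
the channel mouth lies 16.4 Å from the wall centre; a smaller sphere would
wall off the frontal approach.

Monte Carlo moves are rigid translations plus rotations: translation
magnitude 3 Å while solvent-exposed, uniform in 0.75–1.5 Å when buried,
with the direction kept for four consecutive steps; rotation by an angle
uniform in 20°–60° about a random axis through the centroid; Metropolis
acceptance with min(1, exp(−ΔE/kT)). Exposure is the surrogate
1 − min(c/2, 1), monotone from 1 in the bulk to 0 when deeply buried; the
saturation constant 2 was chosen so that vestibule poses (c ≈ 2–15) are
fully buried while mouth-fringe poses are partially exposed. A rejected
step re-emits the previous pose so trajectories have exactly l snapshots
and step accounting stays exact.

**What the toy does not model:** force fields, receptor flexibility,
solvent, real SASA, ligand internal degrees of freedom, and any
thermodynamic observable. Passing benchmarks on it demonstrates that the
adaptive machinery (clustering, rewards, spawning, bookkeeping) behaves as
designed under the statistical conditions it targets — not that any
particular real receptor would show the same speed-up.

## Benchmarking and reproducibility

A binding event is the first snapshot with ligand RMSD to the native pose
below 2.5 Å; binding time is the 1-based per-trajectory MC step of that
snapshot, minimised over the swarm, with runs that never bind assigned the
3000-step cap. Adaptive and independent arms are compared on this axis at
matched master seeds: rng streams are derived per (epoch, trajectory) by a
counter-based split of the master seed, so before any feedback occurs the
two arms produce identical trajectories. The benchmark averages over ten
derived master seeds per cell.

Because all trajectories advance in lockstep epochs, the first-passage
step is final as soon as the epoch containing it completes; benchmark runs
therefore stop at the end of the first binding epoch, which changes no
reported number and saves most of the step budget. Interactive runs expose
the same behaviour through `stop_on_binding`.

At the shipped defaults (N = 32, l = 4, ten repeats) the independent
baseline binds in roughly 500–700 steps on average, the inversely
proportional adaptive strategy in roughly 160–230, and the energy-guided
ε-greedy strategy in between — a two- to four-fold speed-up, significant
at p < 0.05 by a one-sided Welch test; the exact values for any seed are
recomputed by `scripts/acceptance.py` and by the acceptance test suite.

## Numerical choices and edge cases

* Contact ties at exactly the cutoff are non-contacts (strict `<`).
* Thresholds and densities are fixed at cluster creation and immutable.
* The ε-greedy split skips an arm entirely when its share is zero, so the
  ε = 0 and ε = 1 limits are bit-identical to the pure strategies at the
  same seed.
* Largest-remainder ties go to the lower cluster id (stable sort).
* Seeds for a cluster always start from its centre conformation;
  within-cluster alternatives are out of scope.
* Degenerate inputs raise typed errors: mismatched atom counts
  (`SizeMismatchError`), missing metrics (`MissingMetricError`), malformed
  snapshot files (`SnapshotFormatError`), invalid geometry
  (`ToySystemError`), wrong-length sampler output
  (`SamplerContractError`), unknown config keys (`ConfigError`).
* All randomness flows through `numpy` Generators seeded from explicit
  integers; nothing reads global rng state.

## Known limitations

* Leader clustering is order-dependent by construction; permuting the
  input order may change the partition (the membership invariant always
  holds). Online and offline clustering agree only at matched order.
* The toy sampler's direction persistence resets at epoch boundaries
  (each epoch is an independent sampler call).
* The published metric-reward extremum pairing is used verbatim; see the
  `use_cluster_best` switch above.
* The PDB writer emits minimal fixed-column records (single chain per
  point set, carbon elements for pseudo-atoms); it is meant for
  visualisation and round-tripping, not archival deposition.
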