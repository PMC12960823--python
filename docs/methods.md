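# Methods

## The model

`bdpath` samples conformational transition pathways between two
experimentally determined states of a protein at Cα resolution. The protein
is a set of N beads (one per residue) joined by harmonic springs whose rest
lengths come from the current reference geometry — an elastic network model
(ENM). Motion is overdamped Brownian dynamics (BD), and the trajectory is
steered toward the target by importance sampling on a progress variable
computed from internal distances only.

### Elastic network

Two families of springs connect the beads:

* **sequence springs** between residues within `sequence_span` positions of
  each other on the same chain, with stiffness
  `sequence_constant / S**sequence_exponent` for separation S;
* **Cartesian springs** between any two residues closer than the cutoff
  `r_c` in the reference conformation, with stiffness
  `cartesian_constant * (reference_length / d0)**cartesian_exponent` for
  rest distance d0.

Defaults: `r_c = 8 Å`, `sequence_span = 3`, `sequence_constant = 60`,
`sequence_exponent = 2`, `cartesian_constant = 6`, `cartesian_exponent = 6`,
`reference_length = 3.8 Å` (all stiffnesses in kcal/mol·Å²). The functional
forms follow the MD-parametrized essential-dynamics ENM family; the scale
constants are configurable placeholders in that family's typical range and
can be overridden from the configuration file, since no single published
constant set is canonical for every system.

Sequence separation is measured by ordinal position within a chain (file
order), not by raw residue-number difference. Consequence: across a
numbering gap (missing residues) the flanking beads still receive a stiff
spring at their observed distance, which preserves the gap geometry instead
of treating an 8 Å span as a regular bond.

**Rigid blocks.** A block is a set of residues that should move
quasi-rigidly (e.g., the rotor of a rotary motor, selected per chain or per
residue span). Every pair inside a block is connected regardless of
distance, with a uniform stiffness of 1 kcal/mol·Å². Note the thermodynamic
consequence: with unit springs, equipartition gives an intra-block
pair-distance RMS fluctuation of roughly `sqrt(6·kB·T/(n·k))` for a block
of n beads, ≈ 0.25 Å for n = 60 at 300 K and < 0.1 Å only for blocks of
several hundred residues (the size at which the feature is typically
applied). The rigidity test therefore measures the time-averaged intra-block
distortion at low temperature, where the constraint mechanism is isolated
from soft-spring thermal noise, and separately verifies at 300 K that the
block shrinks distortion several-fold relative to the same run without it.

### Brownian dynamics

Beads follow the overdamped (Ermak–McCammon) position update

    Δr_i = (Δt/ζ)·F_i + sqrt(2 kB T Δt/ζ)·η_i ,

with η standard normal per coordinate. Inertia is dropped deliberately:
at the friction scales of interest the velocity degrees of freedom relax
far faster than any conformational motion, so masses never enter. Because
of this, the friction parameter is the per-bead drag ζ in
kcal·ps/(mol·Å²) (mobility 1/ζ), not a collision frequency in 1/ps — a
bare 1/ps frequency cannot form a mobility without a mass.

Defaults: `T = 300 K`, `ζ = 10 kcal·ps/(mol·Å²)`, `Δt = 0.02 ps`, giving a
free-diffusion RMS displacement of 0.049 Å per coordinate per step — small
enough that bonded springs (k ≤ 60 kcal/mol·Å², Δt·k/ζ = 0.12) are
integrated stably, large enough that transitions complete in minutes of
wall time at desk scale.

### Importance sampling on Γ

The progress variable is

    Γ_s = Σ_{i<j} (d_ij(s) − d_ij(target))²   [Å²]

summed over all pairs of *matched* residues (an optional cutoff-restricted
variant, off by default, limits the sum to target pairs within a given
distance for very large systems). Γ depends only on internal distances, so
the bias is invariant under rigid-body transformations of either
conformation — verified bitwise in the tests.

Every `bias_frequency = 10` BD steps, Γ is compared with the last accepted
value: the segment is kept iff Γ strictly decreased (ties reject), else
coordinates roll back to the last accepted checkpoint and fresh noise is
drawn. The run terminates when the superposed RMSD to the target over
matched residues drops to `convergence_rmsd = 1 Å` (the scale of the
model's thermal oscillations), when Γ reaches `gamma_epsilon`, or when
`max_checkpoints = 100 000` is exhausted.

Residue correspondence uses (chain ID, residue number, insertion code)
keys, so the two end states may differ in residue count or chain
composition; unmatched residues contribute no Γ terms and fluctuate freely
under the network and the bath.

### Pair-list updates

The spring pair list is rebuilt from current coordinates every
`rebuild_interval = 10` accepted checkpoints, and immediately whenever any
bead has moved more than r_c/4 since the last build. On a rebuild, newly
admitted pairs take their current distance as rest length, pairs that
persist keep their previous rest length (the potential stays continuous
for them), and rigid-block pairs are always retained with their original
rest lengths. The interval matters: because persisting springs keep stale
rest lengths, infrequent updates let a strict Γ ratchet stall against
frustrated springs after large local rearrangements; at 10-checkpoint
intervals the stall disappears in every seed we tested (15/15 convergent
on the standard hinge, versus 8/10 at a 25-checkpoint interval).

## Ensemble PCA

For an ensemble of n conformations over N common residues (superposed onto
a chosen reference), the positional covariance C (3N × 3N, 1/n
normalization, mean-centered) is diagonalized; eigenvalues are variances in
Å², descending. Structures are projected as
`p = (X − X_ref)·PC_m/|PC_m|` — anchored at the *reference structure*, not
the ensemble mean, while the covariance itself is mean-centered. The two
conventions are implemented exactly as defined and differ only by a
constant offset per component; both are deliberate. Each component's sign
is fixed so its largest-magnitude entry is positive, making projections
reproducible. Superposition is a proper-rotation Kabsch fit (reflections
forbidden, checked against a quaternion oracle in the tests), and
degenerate inputs — fewer than 3 fit beads, exact collinearity — raise
rather than returning an arbitrary rotation.

## Path metrics

* RMSD: `sqrt(1/N Σ |r_b − r_a|²)`, optionally after superposition.
* Collectivity κ: with f_i the normalized displacement magnitudes,
  `κ = exp(−Σ f_i ln f_i)/N ∈ [1/N, 1]`. Computed on the raw displacement
  field by default, so a uniform translation scores exactly 1 (superposing
  first would annihilate it).
* Consecutive Cα–Cα distances per chain (numbering-adjacent residues;
  insertion-code adjacency counts; larger numbering gaps are reported as
  chain breaks, never as distances). Outliers in summaries use the
  conventional 1.5 × IQR boxplot whisker rule.
* Subspace overlap |cos| and RMSIP over the top k × k block of two bases.
* Three-point angles (vertex at the middle residue) for tracking local
  opening/closing along a path.

## Synthetic study conditions

The fixtures module generates all test inputs; nothing external is needed.
Chains are α-helix-like curves (radius 2.3 Å, ~3.6 residues per turn) with
exactly 3.8 Å consecutive spacing — non-collinear, non-planar,
self-avoiding, and of constant packing density so pair-list size is linear
in N. Six motions with closed-form ground truth are available: hinge
(distal half rotated about the local radial axis at the pivot — the arms
splay without steric clash), shear, rotor, breathing, uniform translation
(κ = 1 calibration) and single-residue displacement (κ = 1/N calibration;
this one intentionally perturbs the two flanking bonds).

The standard transition condition is a 60-residue hinge at 70°, which
gives an 8.1 Å superposed end-state RMSD. Under default parameters this
converges to ≤ 1 Å for 15/15 tested seeds in 3–30 s per run on one CPU,
with midpoint-intermediate consecutive-distance medians within 3.8 ± 0.1 Å
and the full path inside the 3.3–4.3 Å envelope. The quasi-linear scaling
check uses chains of N = 250…4000 and measures the cost of a full biasing
cycle with the cutoff-restricted Γ (the all-pairs Γ is by construction
quadratic in N and is the reason that variant exists).

What these fixtures do *not* emulate: real secondary-structure packing,
side-chain sterics, heterogeneous contact density, or experimental noise in
the end states. Passing on them shows the sampler, metrics and PCA machinery
behave as specified under controlled geometry; it does not by itself
establish accuracy on experimental ensembles.

## Numerical choices and degenerate inputs

* Altloc resolution on PDB input: highest occupancy wins, ties broken by
  alphabetical altloc identifier; duplicate residue keys after resolution
  are an error.
* Coincident beads in a spring pair are an error naming the pair (they
  indicate corrupt input), never a silent skip.
* A tie Γ_s = Γ_{s−1} at a checkpoint is a rejection (strict inequality).
* Eigenvalues are clamped at zero from below (−1e−10 tolerance); PCA sign
  and degenerate-eigenvalue order are fixed deterministically.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical
  trajectories, and the resolved-configuration sidecar written next to
  every CLI run output suffices to reproduce it exactly.

## Known limitations

* The method gives no energetics or kinetics: paths are sequences of
  stereochemically plausible intermediates, not minimum free-energy paths,
  and checkpoint counts are not times.
* The shipped spring-constant scales are a documented default, not a fitted
  parametrization; quantitative work on real systems should calibrate them.
* Cα-only resolution: no side chains, no atomistic validation; intermediates
  need external reconstruction for all-atom applications.
* The strict Γ ratchet can in principle wedge in geometrically frustrated
  corners of very complex transitions; the frequent pair-list updates
  mitigate but do not formally exclude this (the checkpoint budget then
  reports a non-converged run honestly).
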