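"""Brownian-dynamics importance sampling of conformational transitions.

The sampler propagates the Cα elastic network with overdamped (position)
Langevin dynamics and biases it toward a target conformation through a
progress variable Γ, the sum of squared differences between current and
target internal pairwise distances:

    Γ_s = Σ_{i<j} (d_ij(s) − d_ij(target))²      [Å²]

Every ``bias_frequency`` BD steps a checkpoint compares Γ_s with the last
accepted value: the segment is kept if Γ_s strictly decreased and rolled
back otherwise (fresh noise is drawn after a rejection). Because Γ depends
only on internal distances, the bias is invariant under rigid-body motion
of either conformation. The run terminates when the RMSD to the target
(over matched residues, after optimal superposition) falls within thermal
oscillations, when Γ is close enough to zero, or when the checkpoint budget
is exhausted.

Residue correspondence between the two end states is established by
(chain, residue number, insertion code) keys, so the end states may have
different residue counts or chain compositions; unmatched residues carry no
bias terms and simply fluctuate under the elastic network and thermal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import pdist

from .structure_io import CalphaModel, match_residues
from .elastic_network import (ENMParams, SpringTopology, build_topology,
                              compute_forces, rebuild_pair_list)
from .ensemble_pca import kabsch_superpose

__all__ = [
    "BOLTZMANN_KCAL",
    "BDParams",
    "TargetDistances",
    "SamplerState",
    "CheckpointRecord",
    "TransitionPath",
    "progress_variable",
    "bd_step",
    "dims_checkpoint",
    "run_transition",
]

#: Boltzmann constant in kcal/(mol·K).
BOLTZMANN_KCAL = 0.0019872041


@dataclass(frozen=True)
class BDParams:
    """Brownian-dynamics and biasing parameters.

    Attributes
    ----------
    temperature:
        Bath temperature in K.
    friction:
        Per-bead drag coefficient ζ in kcal·ps/(mol·Å²). In the overdamped
        limit the bead mobility is 1/ζ, so one step displaces each bead by
        (Δt/ζ)·F plus Gaussian noise of per-coordinate standard deviation
        √(2 k_B T Δt / ζ).
    timestep:
        Δt in ps.
    bias_frequency:
        Number of BD steps between acceptance checkpoints (k).
    convergence_rmsd:
        Terminate when the superposed RMSD to the target over matched
        residues falls below this value (Å); ~1 Å is the scale of thermal
        oscillations of the model.
    gamma_epsilon:
        Alternative termination: Γ at or below this floor (Å²).
    max_checkpoints:
        Checkpoint budget before giving up.
    frame_stride:
        Save one trajectory frame every this many accepted checkpoints.
    rebuild_interval:
        Rebuild the spring pair list every this many accepted checkpoints;
        a rebuild is also forced whenever any bead has moved more than a
        quarter of the cutoff since the last build.
    gamma_pair_cutoff:
        Optional cutoff (Å) restricting which matched pairs enter Γ,
        measured in the target conformation. None (default) means all
        matched pairs, exactly as the progress variable is defined.
    seed:
        RNG seed making runs fully reproducible.
    """

    temperature: float = 300.0
    friction: float = 10.0
    timestep: float = 0.02
    bias_frequency: int = 10
    convergence_rmsd: float = 1.0
    gamma_epsilon: float = 1e-6
    max_checkpoints: int = 100_000
    frame_stride: int = 10
    rebuild_interval: int = 10
    gamma_pair_cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperature", "friction", "timestep", "convergence_rmsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.friction == 0 or self.timestep == 0:
            raise ValueError("friction and timestep must be positive")
        if self.bias_frequency < 1:
            raise ValueError("bias_frequency must be >= 1")
        if self.frame_stride < 1 or self.rebuild_interval < 1:
            raise ValueError("frame_stride and rebuild_interval must be >= 1")

    @property
    def noise_sigma(self) -> float:
        """Per-coordinate noise amplitude per step, √(2 k_B T Δt/ζ), in Å."""
        return float(np.sqrt(2.0 * BOLTZMANN_KCAL * self.temperature
                             * self.timestep / self.friction))


@dataclass
class TargetDistances:
    """Target internal distances for the matched residues.

    ``indices`` are bead indices into the *simulated* model (start-state
    ordering). When ``pair_index`` is None the progress variable runs over
    all matched pairs; otherwise only over the listed pairs (cutoff mode).
    """

    indices: np.ndarray
    distances: np.ndarray
    pair_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.distances <= 0):
            raise ValueError("target distances must be positive")


def make_target_distances(start: CalphaModel, target: CalphaModel,
                          pair_cutoff: float | None = None) -> TargetDistances:
    """Build the Γ reference from two end states via key correspondence."""
    cmap = match_residues(start, target)
    if cmap.n_matched == 0:
        raise ValueError("no residues match between start and target")
    if cmap.n_matched < 2:
        raise ValueError("need at least 2 matched residues to define a bias")
    idx_start = cmap.indices_a()
    coords_t = target.positions[cmap.indices_b()]
    if pair_cutoff is None:
        return TargetDistances(idx_start, pdist(coords_t))
    from scipy.spatial import cKDTree
    tree = cKDTree(coords_t)
    pairs = np.array(sorted((min(i, j), max(i, j))
                            for i, j in tree.query_pairs(pair_cutoff)), dtype=int)
    if pairs.size == 0:
        raise ValueError("no matched pair within the Γ cutoff")
    dist = np.linalg.norm(coords_t[pairs[:, 1]] - coords_t[pairs[:, 0]], axis=1)
    return TargetDistances(idx_start, dist, pairs.reshape(-1, 2))


def progress_variable(positions: np.ndarray, target: TargetDistances) -> float:
    """Γ = Σ (d_ij − d_ij^target)² in Å² over the biased pairs.

    Invariant under any rigid-body transform of ``positions`` because only
    internal distances enter.
    """
    coords = np.asarray(positions, dtype=float)[target.indices]
    if target.pair_index is None:
        d = pdist(coords)
    else:
        d = np.linalg.norm(coords[target.pair_index[:, 1]]
                           - coords[target.pair_index[:, 0]], axis=1)
    return float(np.sum((d - target.distances) ** 2))


@dataclass
class SamplerState:
    """Mutable state of the sampler between checkpoints."""

    positions: np.ndarray
    rng: np.random.Generator
    step: int = 0
    checkpoint_count: int = 0
    last_accepted_positions: np.ndarray | None = None
    last_accepted_gamma: float = np.inf

    def __post_init__(self) -> None:
        self.positions = np.array(self.positions, dtype=float)
        if self.last_accepted_positions is None:
            self.last_accepted_positions = self.positions.copy()


def bd_step(state: SamplerState, topology: SpringTopology, params: BDParams) -> SamplerState:
    """One overdamped Langevin (Ermak–McCammon) position update, in place.

    Δr = (Δt/ζ)·F + √(2 k_B T Δt/ζ)·η with η standard normal per coordinate.
    """
    forces = compute_forces(topology, state.positions)
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces))[0, 0])
        raise FloatingPointError(f"non-finite force on bead {bad} at step {state.step}")
    mobility_dt = params.timestep / params.friction
    new = state.positions + mobility_dt * forces
    if params.temperature > 0:
        new += params.noise_sigma * state.rng.standard_normal(state.positions.shape)
    if not np.all(np.isfinite(new)):
        bad = int(np.argwhere(~np.isfinite(new))[0, 0])
        raise FloatingPointError(f"non-finite position for bead {bad} at step {state.step}")
    state.positions = new
    state.step += 1
    return state


def dims_checkpoint(state: SamplerState, target: TargetDistances,
                    params: BDParams) -> tuple[SamplerState, bool]:
    """Importance-sampling checkpoint: keep the segment iff Γ decreased.

    Strict inequality: a tie is rejected. On rejection the coordinates are
    rolled back to the last accepted ones; the RNG is not rewound, so the
    next segment sees fresh noise.
    """
    gamma = progress_variable(state.positions, target)
    if not np.isfinite(gamma):
        raise FloatingPointError("progress variable diverged (non-finite Γ)")
    state.checkpoint_count += 1
    if gamma < state.last_accepted_gamma:
        state.last_accepted_positions = state.positions.copy()
        state.last_accepted_gamma = gamma
        return state, True
    state.positions = state.last_accepted_positions.copy()
    return state, False


@dataclass
class CheckpointRecord:
    """One row of the per-checkpoint log."""

    checkpoint: int
    step: int
    gamma: float
    rmsd_to_target: float
    accepted: bool


@dataclass
class TransitionPath:
    """Result of a transition run: accepted frames plus diagnostics."""

    frames: list[CalphaModel]
    rmsd_to_target: np.ndarray
    gamma: np.ndarray
    converged: bool
    termination_reason: str  # "rmsd" | "gamma" | "budget" | "start"
    n_checkpoints: int = 0
    n_accepted: int = 0
    log: list[CheckpointRecord] = field(default_factory=list)

    @property
    def final_rmsd(self) -> float:
        return float(self.rmsd_to_target[-1])

    def write_log_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["checkpoint", "step", "gamma_A2", "rmsd_to_target_A", "accepted"])
            for rec in self.log:
                writer.writerow([rec.checkpoint, rec.step, f"{rec.gamma:.6f}",
                                 f"{rec.rmsd_to_target:.6f}", int(rec.accepted)])


def _rmsd_to_target(positions: np.ndarray, target_coords: np.ndarray,
                    matched_idx: np.ndarray) -> float:
    mobile = positions[matched_idx]
    if mobile.shape[0] < 3:
        diff = mobile - target_coords
        return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    _, rmsd = kabsch_superpose(mobile, target_coords)
    return rmsd


def run_transition(start: CalphaModel, target: CalphaModel,
                   enm_params: ENMParams = ENMParams(),
                   bd_params: BDParams = BDParams(),
                   rigid_blocks: Iterable[Iterable[int]] | None = None,
                   ) -> TransitionPath:
    """Sample a transition pathway from ``start`` toward ``target``.

    The loop is: ``bias_frequency`` BD steps, then an accept/reject
    checkpoint on Γ, rebuilding the spring pair list on its schedule.
    Forward and backward runs are independent simulations. Fully
    reproducible for a given ``bd_params.seed``.
    """
    cmap = match_residues(start, target)
    if cmap.n_matched == 0:
        raise ValueError("start and target share no residue keys")
    tgt = make_target_distances(start, target, bd_params.gamma_pair_cutoff)
    matched_idx = cmap.indices_a()
    target_coords = target.positions[cmap.indices_b()]

    topology = build_topology(start, enm_params, rigid_blocks)
    rng = np.random.default_rng(bd_params.seed)
    state = SamplerState(start.positions.copy(), rng)
    state.last_accepted_gamma = progress_variable(state.positions, tgt)

    def snapshot() -> CalphaModel:
        return start.with_positions(state.last_accepted_positions)

    frames = [snapshot()]
    rmsd0 = _rmsd_to_target(state.positions, target_coords, matched_idx)
    frame_rmsd = [rmsd0]
    frame_gamma = [state.last_accepted_gamma]
    log: list[CheckpointRecord] = [
        CheckpointRecord(0, 0, state.last_accepted_gamma, rmsd0, True)]

    if rmsd0 <= bd_params.convergence_rmsd:
        return TransitionPath(frames, np.array(frame_rmsd), np.array(frame_gamma),
                              True, "start", 0, 0, log)
    if state.last_accepted_gamma <= bd_params.gamma_epsilon:
        return TransitionPath(frames, np.array(frame_rmsd), np.array(frame_gamma),
                              True, "gamma", 0, 0, log)

    accepted_total = 0
    accepted_since_rebuild = 0
    positions_at_build = state.positions.copy()
    move_threshold = 0.25 * enm_params.cutoff
    converged = False
    reason = "budget"
    last_rmsd = rmsd0

    while state.checkpoint_count < bd_params.max_checkpoints:
        for _ in range(bd_params.bias_frequency):
            bd_step(state, topology, bd_params)
        state, accepted = dims_checkpoint(state, tgt, bd_params)
        if accepted:
            accepted_total += 1
            accepted_since_rebuild += 1
            last_rmsd = _rmsd_to_target(state.positions, target_coords, matched_idx)
            log.append(CheckpointRecord(state.checkpoint_count, state.step,
                                        state.last_accepted_gamma, last_rmsd, True))
            if accepted_total % bd_params.frame_stride == 0:
                frames.append(snapshot())
                frame_rmsd.append(last_rmsd)
                frame_gamma.append(state.last_accepted_gamma)
            if last_rmsd <= bd_params.convergence_rmsd:
                converged, reason = True, "rmsd"
                break
            if state.last_accepted_gamma <= bd_params.gamma_epsilon:
                converged, reason = True, "gamma"
                break
            moved = np.max(np.linalg.norm(state.positions - positions_at_build, axis=1))
            if accepted_since_rebuild >= bd_params.rebuild_interval or moved > move_threshold:
                topology = rebuild_pair_list(topology, state.positions)
                positions_at_build = state.positions.copy()
                accepted_since_rebuild = 0
        else:
            log.append(CheckpointRecord(state.checkpoint_count, state.step,
                                        state.last_accepted_gamma, last_rmsd, False))

    # always include the final accepted conformation as the last frame
    if frame_gamma[-1] > state.last_accepted_gamma:
        frames.append(snapshot())
        frame_rmsd.append(last_rmsd)
        frame_gamma.append(state.last_accepted_gamma)

    return TransitionPath(frames, np.array(frame_rmsd), np.array(frame_gamma),
                          converged, reason, state.checkpoint_count,
                          accepted_total, log)
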