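"""Coarse-grained elastic network: topology, spring constants, forces.

A protein is modelled as Cα beads joined by harmonic springs whose rest
lengths come from a reference conformation. Two spring families are used,
following MD-parametrized elastic-network practice:

* sequence springs between residues close in sequence on the same chain,
  with stiffness decaying as an inverse power of the sequence separation;
* Cartesian springs between residues within a spatial cutoff ``r_c``,
  with stiffness decaying as an inverse power of the pair distance.

Rigid blocks are sets of residues that must move quasi-rigidly: every pair
inside a block is connected regardless of distance, with a uniform spring
constant (1 kcal/mol·Å² by default), which preserves the internal geometry
of the block during large rotations.

For a system of N beads the all-pairs force sum costs (N² − N)/2 pair
evaluations per step; restricting the sum to the cutoff pair list makes the
cost grow roughly linearly with N at fixed packing density.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import CalphaModel

__all__ = [
    "ENMParams",
    "SpringTopology",
    "build_topology",
    "spring_constant",
    "compute_forces",
    "potential_energy",
    "rebuild_pair_list",
    "all_pairs_interaction_count",
    "parse_rigid_blocks",
]


@dataclass(frozen=True)
class ENMParams:
    """Elastic-network parameters.

    Attributes
    ----------
    cutoff:
        Spatial cutoff r_c in Å for Cartesian springs (default 8 Å).
    sequence_span:
        Residue separations up to this value (same chain) are treated as
        sequence ("bonded") springs.
    sequence_constant:
        Stiffness scale of sequence springs in kcal/mol·Å²; a pair at
        separation S gets sequence_constant / S**sequence_exponent.
    sequence_exponent:
        Decay exponent of the sequence rule (dimensionless).
    cartesian_constant:
        Stiffness scale of Cartesian springs in kcal/mol·Å²; a pair at rest
        distance d0 gets cartesian_constant * (reference_length/d0)**cartesian_exponent.
    cartesian_exponent:
        Decay exponent of the Cartesian rule (dimensionless).
    reference_length:
        Length scale of the Cartesian rule in Å (the ideal Cα–Cα spacing).
    rigid_spring_constant:
        Uniform stiffness of intra-rigid-block springs in kcal/mol·Å².
    """

    cutoff: float = 8.0
    sequence_span: int = 3
    sequence_constant: float = 60.0
    sequence_exponent: float = 2.0
    cartesian_constant: float = 6.0
    cartesian_exponent: float = 6.0
    reference_length: float = 3.8
    rigid_spring_constant: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cutoff", "sequence_constant", "cartesian_constant",
                     "reference_length", "rigid_spring_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sequence_span < 0:
            raise ValueError("sequence_span must be >= 0")


@dataclass
class SpringTopology:
    """Pair list with per-pair stiffness and rest lengths.

    ``pairs`` is an (M, 2) integer array with i < j in every row and no
    duplicates. ``rigid_mask`` flags pairs that belong to a rigid block;
    those are kept regardless of distance on pair-list rebuilds.
    """

    pairs: np.ndarray
    stiffness: np.ndarray
    rest_lengths: np.ndarray
    rigid_mask: np.ndarray
    rigid_blocks: list[frozenset[int]]
    source_positions: np.ndarray
    params: ENMParams

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def n_beads(self) -> int:
        return self.source_positions.shape[0]


def all_pairs_interaction_count(n: int) -> int:
    """Number of pair interactions in the all-pairs force sum: (N² − N)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return (n * n - n) // 2


def spring_constant(sequence_separation: int, d0: float, params: ENMParams,
                    same_chain: bool = True) -> float:
    """Stiffness of a single spring in kcal/mol·Å².

    Sequence neighbors (separation <= sequence_span on the same chain) use
    the inverse-power sequence rule; every other pair uses the Cartesian
    distance rule, which is monotonically non-increasing in d0.
    """
    if d0 <= 0:
        raise ValueError("rest length must be positive")
    if same_chain and 1 <= sequence_separation <= params.sequence_span:
        return params.sequence_constant / sequence_separation ** params.sequence_exponent
    return params.cartesian_constant * (params.reference_length / d0) ** params.cartesian_exponent


def _chain_arrays(model: CalphaModel) -> tuple[np.ndarray, np.ndarray]:
    """Integer chain id per bead and the bead's ordinal position in its chain."""
    chain_of = np.empty(model.n_residues, dtype=int)
    pos_in_chain = np.empty(model.n_residues, dtype=int)
    chain_ids: dict[str, int] = {}
    counters: dict[str, int] = {}
    for i, (cid, _, _) in enumerate(model.residue_keys):
        if cid not in chain_ids:
            chain_ids[cid] = len(chain_ids)
            counters[cid] = 0
        chain_of[i] = chain_ids[cid]
        pos_in_chain[i] = counters[cid]
        counters[cid] += 1
    return chain_of, pos_in_chain


def _normalize_blocks(rigid_blocks: Iterable[Iterable[int]] | None,
                      n: int) -> list[frozenset[int]]:
    blocks: list[frozenset[int]] = []
    seen: set[int] = set()
    for block in rigid_blocks or ():
        fs = frozenset(int(i) for i in block)
        if not fs:
            continue
        if any(i < 0 or i >= n for i in fs):
            raise ValueError("rigid block references a bead index out of range")
        if fs & seen:
            raise ValueError("rigid blocks must be disjoint")
        seen |= fs
        blocks.append(fs)
    return blocks


def _assemble(model_positions: np.ndarray, chain_of: np.ndarray,
              pos_in_chain: np.ndarray, params: ENMParams,
              blocks: list[frozenset[int]],
              rest_override: dict[tuple[int, int], float] | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collect pairs (sequence + cutoff + rigid), stiffness and rest lengths."""
    n = model_positions.shape[0]
    pair_set: set[tuple[int, int]] = set()

    # (a) spatial cutoff pairs
    tree = cKDTree(model_positions)
    for i, j in tree.query_pairs(params.cutoff):
        pair_set.add((min(i, j), max(i, j)))

    # (b) sequence neighbors within span on the same chain
    if params.sequence_span >= 1:
        order = np.lexsort((pos_in_chain, chain_of))
        for span in range(1, params.sequence_span + 1):
            a = order[:-span] if span else order
            b = order[span:]
            ok = (chain_of[a] == chain_of[b]) & (pos_in_chain[b] - pos_in_chain[a] == span)
            for i, j in zip(a[ok], b[ok]):
                pair_set.add((min(i, j), max(i, j)))

    # (c) all intra-rigid-block pairs, regardless of distance
    rigid_set: set[tuple[int, int]] = set()
    for block in blocks:
        members = sorted(block)
        for a_idx, i in enumerate(members):
            for j in members[a_idx + 1:]:
                rigid_set.add((i, j))
    pair_set |= rigid_set

    pairs = np.array(sorted(pair_set), dtype=int).reshape(-1, 2)
    if pairs.shape[0] == 0:
        raise ValueError("empty pair list: no residue pair within cutoff or sequence span")
    ii, jj = pairs[:, 0], pairs[:, 1]
    delta = model_positions[jj] - model_positions[ii]
    rest = np.linalg.norm(delta, axis=1)
    if rest_override:
        for k, (i, j) in enumerate(map(tuple, pairs)):
            if (i, j) in rest_override:
                rest[k] = rest_override[(i, j)]
    if np.any(rest <= 0):
        bad = pairs[rest <= 0][0]
        raise ValueError(f"coincident beads in pair {(int(bad[0]), int(bad[1]))}")

    rigid_mask = np.array([(i, j) in rigid_set for i, j in map(tuple, pairs)], dtype=bool)
    same_chain = chain_of[ii] == chain_of[jj]
    seq_sep = np.where(same_chain, np.abs(pos_in_chain[jj] - pos_in_chain[ii]), 0)
    is_seq = same_chain & (seq_sep >= 1) & (seq_sep <= params.sequence_span)

    k = np.empty(pairs.shape[0])
    k[is_seq] = params.sequence_constant / seq_sep[is_seq].astype(float) ** params.sequence_exponent
    k[~is_seq] = params.cartesian_constant * (
        params.reference_length / rest[~is_seq]) ** params.cartesian_exponent
    k[rigid_mask] = params.rigid_spring_constant
    return pairs, k, rest, rigid_mask


def build_topology(model: CalphaModel, params: ENMParams = ENMParams(),
                   rigid_blocks: Iterable[Iterable[int]] | None = None) -> SpringTopology:
    """Build the spring topology of a reference conformation.

    The pair list contains (a) all pairs within the spatial cutoff,
    (b) sequence neighbors within ``sequence_span`` on the same chain, and
    (c) every pair inside a rigid block, cutoff-free. Rest lengths are the
    distances in ``model``; intra-block pairs get the uniform rigid stiffness.
    """
    chain_of, pos_in_chain = _chain_arrays(model)
    blocks = _normalize_blocks(rigid_blocks, model.n_residues)
    pairs, k, rest, rigid_mask = _assemble(
        model.positions, chain_of, pos_in_chain, params, blocks)
    topo = SpringTopology(pairs, k, rest, rigid_mask, blocks,
                          model.positions.copy(), params)
    topo._chain_of = chain_of  # cached for rebuilds
    topo._pos_in_chain = pos_in_chain
    return topo


def rebuild_pair_list(topology: SpringTopology, positions: np.ndarray) -> SpringTopology:
    """Rebuild the pair list from current positions.

    Newly admitted pairs take their current distance as rest length;
    pairs that persist from the previous list keep their previous rest
    length (the potential stays continuous for them); rigid-block pairs are
    always retained with their original rest lengths.
    """
    positions = np.asarray(positions, dtype=float)
    previous = {tuple(p): r for p, r in zip(topology.pairs, topology.rest_lengths)}
    pairs, k, rest, rigid_mask = _assemble(
        positions, topology._chain_of, topology._pos_in_chain, topology.params,
        topology.rigid_blocks, rest_override=previous)
    new = SpringTopology(pairs, k, rest, rigid_mask, topology.rigid_blocks,
                         positions.copy(), topology.params)
    new._chain_of = topology._chain_of
    new._pos_in_chain = topology._pos_in_chain
    return new


def compute_forces(topology: SpringTopology, positions: np.ndarray) -> np.ndarray:
    """Harmonic forces on every bead, in kcal/mol·Å.

    Each pair contributes a force of magnitude k_ij (d_ij − d0_ij) along the
    pair axis, applied antisymmetrically, so the total force is zero.
    """
    positions = np.asarray(positions, dtype=float)
    ii, jj = topology.pairs[:, 0], topology.pairs[:, 1]
    delta = positions[jj] - positions[ii]
    dist = np.linalg.norm(delta, axis=1)
    if np.any(dist == 0):
        bad = topology.pairs[dist == 0][0]
        raise ValueError(f"coincident beads in pair {(int(bad[0]), int(bad[1]))}")
    if not np.all(np.isfinite(dist)):
        bad = topology.pairs[~np.isfinite(dist)][0]
        raise FloatingPointError(
            f"non-finite distance for pair {(int(bad[0]), int(bad[1]))}")
    scale = topology.stiffness * (dist - topology.rest_lengths) / dist
    fpair = scale[:, None] * delta  # force on i, toward j when stretched
    n = positions.shape[0]
    forces = np.zeros((n, 3))
    for c in range(3):
        forces[:, c] = (np.bincount(ii, weights=fpair[:, c], minlength=n)
                        - np.bincount(jj, weights=fpair[:, c], minlength=n))
    return forces


def potential_energy(topology: SpringTopology, positions: np.ndarray) -> float:
    """Total harmonic energy Σ ½ k (d − d0)² in kcal/mol; zero at the source."""
    positions = np.asarray(positions, dtype=float)
    ii, jj = topology.pairs[:, 0], topology.pairs[:, 1]
    dist = np.linalg.norm(positions[jj] - positions[ii], axis=1)
    if np.any(dist == 0):
        bad = topology.pairs[dist == 0][0]
        raise ValueError(f"coincident beads in pair {(int(bad[0]), int(bad[1]))}")
    return float(0.5 * np.sum(topology.stiffness * (dist - topology.rest_lengths) ** 2))


def parse_rigid_blocks(text_or_path: str | Path, model: CalphaModel) -> list[frozenset[int]]:
    """Parse a rigid-block definition into bead-index sets.

    One block per line; each line is a whitespace/comma-separated list of
    selectors, either ``chainID`` (the whole chain) or ``chainID:start-end``
    (an inclusive residue-number span). Lines starting with '#' are ignored.
    """
    if isinstance(text_or_path, Path) or (
            isinstance(text_or_path, str) and "\n" not in text_or_path
            and Path(str(text_or_path)).exists()):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    blocks: list[frozenset[int]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        members: set[int] = set()
        for token in line.replace(",", " ").split():
            if ":" in token:
                cid, span = token.split(":", 1)
                lo, hi = span.split("-")
                lo_i, hi_i = int(lo), int(hi)
                members |= {i for i, (c, num, _) in enumerate(model.residue_keys)
                            if c == cid and lo_i <= num <= hi_i}
            else:
                members |= {i for i, (c, _, _) in enumerate(model.residue_keys)
                            if c == token}
        if not members:
            raise ValueError(f"rigid-block selector matched no residues: {line!r}")
        blocks.append(frozenset(members))
    return blocks
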