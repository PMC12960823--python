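"""Metrics for conformational changes and path quality.

* RMSD between two Cα models, optionally after optimal superposition:
  RMSD = √(1/N Σ |r_i(b) − r_i(a)|²).
* Collectivity degree κ — an entropy measure of how many residues take part
  in a displacement field. With normalized displacement magnitudes
  f_i = |Δr_i| / Σ_j |Δr_j|,

      κ = (1/N) · exp(−Σ_i f_i ln f_i) ,

  which ranges from 1/N (a single residue moves) to 1 (all residues move by
  the same amount).
* Consecutive Cα–Cα distances within each chain, the basic stereochemical
  check of coarse-grained intermediates (ideal value ~3.8 Å).
* Subspace overlap and RMSIP between sets of direction vectors (e.g.,
  experimental PCs vs. essential-dynamics eigenvectors).
* Three-point angles between named residues, for tracking local
  opening/closing motions along a path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import CalphaModel, ResidueKey, match_residues
from .ensemble_pca import kabsch_superpose, PCABasis

__all__ = [
    "rmsd",
    "collectivity",
    "ConsecutiveDistances",
    "consecutive_ca_distances",
    "ca_distance_stats",
    "subspace_overlap",
    "rmsip",
    "three_point_angle",
]


def _paired_positions(a: CalphaModel, b: CalphaModel) -> tuple[np.ndarray, np.ndarray]:
    if a.residue_keys == b.residue_keys:
        return a.positions, b.positions
    cmap = match_residues(a, b)
    if cmap.n_matched == 0:
        raise ValueError("models share no residue keys")
    if cmap.unmatched_a or cmap.unmatched_b:
        raise ValueError(
            "residue keys differ; reduce both models to their common residues first")
    return a.positions[cmap.indices_a()], b.positions[cmap.indices_b()]


def rmsd(a: CalphaModel, b: CalphaModel, superpose: bool = True) -> float:
    """Root-mean-square deviation between two models in Å.

    With ``superpose=True`` (default) the optimal rigid superposition is
    applied first, so the value measures the conformational change only.
    """
    pa, pb = _paired_positions(a, b)
    if superpose:
        _, value = kabsch_superpose(pb, pa)
        return value
    diff = pb - pa
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def collectivity(a: CalphaModel, b: CalphaModel, superpose: bool = False) -> float:
    """Collectivity degree κ of the displacement field between two models.

    By default the raw displacement field is used (no superposition), so a
    uniform translation scores exactly κ = 1. κ is invariant to a global
    rescaling of all displacements.
    """
    pa, pb = _paired_positions(a, b)
    if superpose:
        pb, _ = kabsch_superpose(pb, pa)
    mags = np.linalg.norm(pb - pa, axis=1)
    total = mags.sum()
    if total == 0:
        raise ValueError("all displacements are zero; collectivity is undefined")
    f = mags / total
    nonzero = f > 0
    entropy = -float(np.sum(f[nonzero] * np.log(f[nonzero])))
    return float(np.exp(entropy) / len(mags))


@dataclass
class ConsecutiveDistances:
    """Distances between sequence-adjacent Cα beads, chain by chain."""

    by_chain: dict[str, np.ndarray]
    breaks: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)

    @property
    def all(self) -> np.ndarray:
        arrays = [v for v in self.by_chain.values() if v.size]
        return np.concatenate(arrays) if arrays else np.array([])


def consecutive_ca_distances(frame: CalphaModel) -> ConsecutiveDistances:
    """Cα–Cα distances between consecutive residues within each chain.

    Two residues are consecutive when their numbers differ by one, or when
    the numbers are equal and the insertion codes differ (inserted
    residues). Larger numbering gaps are chain breaks, reported separately
    and never turned into distances.
    """
    by_chain: dict[str, list[float]] = {}
    breaks: list[tuple[ResidueKey, ResidueKey]] = []
    for t in range(frame.n_residues - 1):
        ka = frame.residue_keys[t]
        kb = frame.residue_keys[t + 1]
        if ka[0] != kb[0]:
            continue
        delta = kb[1] - ka[1]
        adjacent = delta == 1 or (delta == 0 and ka[2] != kb[2])
        if not adjacent:
            breaks.append((ka, kb))
            continue
        d = float(np.linalg.norm(frame.positions[t + 1] - frame.positions[t]))
        by_chain.setdefault(ka[0], []).append(d)
    return ConsecutiveDistances({c: np.array(v) for c, v in by_chain.items()}, breaks)


def ca_distance_stats(distances: np.ndarray) -> dict:
    """Min / median / max plus boxplot-whisker outliers (1.5 × IQR rule)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to summarize")
    q1, q3 = np.percentile(d, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "min": float(d.min()),
        "median": float(np.median(d)),
        "max": float(d.max()),
        "q1": float(q1),
        "q3": float(q3),
        "outliers": d[(d < lo) | (d > hi)],
    }


def subspace_overlap(v: np.ndarray, w: np.ndarray) -> float:
    """|cosine| between two direction vectors, in [0, 1]."""
    v = np.asarray(v, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if v.shape != w.shape:
        raise ValueError("vectors must have equal dimensionality")
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("overlap with a zero vector is undefined")
    return float(abs(v @ w) / (nv * nw))


def _vectors(basis, k: int) -> np.ndarray:
    if isinstance(basis, PCABasis):
        mat = basis.eigenvectors
    else:
        mat = np.asarray(basis, dtype=float)
    if k > mat.shape[1]:
        raise ValueError(f"requested {k} vectors but only {mat.shape[1]} available")
    cols = mat[:, :k]
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero vector in basis")
    return cols / norms


def rmsip(basis_a, basis_b, k: int) -> float:
    """Root mean square inner product of the top k×k block of two bases.

    RMSIP = √(1/k Σ_i Σ_j (a_i·b_j)²); equals 1 when the two k-dimensional
    subspaces coincide (invariant to ordering or mixing within the subspace).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    a = _vectors(basis_a, k)
    b = _vectors(basis_b, k)
    if a.shape[0] != b.shape[0]:
        raise ValueError("bases must have equal dimensionality")
    inner = a.T @ b
    return float(np.sqrt(np.sum(inner ** 2) / k))


def three_point_angle(frame: CalphaModel, key_i: ResidueKey, key_j: ResidueKey,
                      key_k: ResidueKey) -> float:
    """Angle (degrees) at residue ``key_j`` formed with ``key_i`` and ``key_k``."""
    index = frame.key_index()
    points = []
    for key in (key_i, key_j, key_k):
        if key not in index:
            raise KeyError(f"residue {key} not present in the model")
        points.append(frame.positions[index[key]])
    a, b, c = points
    v1 = a - b
    v2 = c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("coincident points; angle is undefined")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
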