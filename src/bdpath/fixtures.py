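"""Synthetic two-state Cα systems with known ground truth.

Real transition benchmarks require curated experimental structures; for
development and testing this module generates idealized Cα models instead:
gently curved chains with exact 3.8 Å consecutive spacing (a straight chain
would be collinear and break superposition), deformed by simple rigid
motions with closed-form ground truth:

* ``hinge``      — rotate the distal half of the chain about an axis
                   through a pivot bead (domain hinge-bending);
* ``shear``      — translate one whole chain parallel to another
                   (sliding-interface motions);
* ``rotor``      — rotate one chain rigidly about the assembly symmetry
                   axis (rotary machines);
* ``breathing``  — translate every chain radially away from the symmetry
                   axis (uniform expansion);
* ``uniform_translation`` — displace every bead by the same vector
                   (κ = 1 calibration);
* ``single_residue``      — displace exactly one bead (κ = 1/N
                   calibration; this one intentionally perturbs the two
                   bonds flanking the moved bead).

Rigid motions preserve the exact consecutive spacing in both end states, so
stereochemistry along a sampled path has a clean 3.8 Å baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import CalphaModel, ResidueKey
from . import path_metrics

__all__ = [
    "FixtureSpec",
    "TwoStatePair",
    "make_chain",
    "make_two_state",
    "make_ensemble",
    "degrade_model",
]

MOTIONS = ("hinge", "shear", "rotor", "breathing", "uniform_translation",
           "single_residue")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic two-state system.

    ``amplitude`` is in degrees for the rotational motions (hinge, rotor)
    and in Å for the translational ones (shear, breathing,
    uniform_translation, single_residue).
    """

    n_residues: int = 60
    chains: int = 1
    motion: str = "hinge"
    amplitude: float = 70.0  # 70° on the default 60-residue chain ≈ 8 Å RMSD
    spacing: float = 3.8
    curvature: float = 1.745  # helix turn per residue, radians (~3.6 res/turn)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.motion not in MOTIONS:
            raise ValueError(f"unknown motion {self.motion!r}; choose from {MOTIONS}")
        if self.n_residues < 2 or self.chains < 1:
            raise ValueError("need at least 2 residues and 1 chain")
        if self.motion in ("shear", "rotor", "breathing") and self.chains < 2:
            raise ValueError(f"{self.motion} motion needs at least 2 chains")


@dataclass
class TwoStatePair:
    """A start/target pair plus its closed-form ground truth."""

    start: CalphaModel
    target: CalphaModel
    rmsd: float
    kappa: float


def _rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(degrees)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def make_chain(n_residues: int, spacing: float = 3.8, curvature: float = 1.745,
               origin: np.ndarray | None = None, radius: float = 2.3) -> np.ndarray:
    """A gently helical 3D chain with exact consecutive spacing.

    Beads lie on a helix of the given radius whose turn angle per residue is
    ``curvature`` (radians); the rise per residue is chosen so every
    consecutive distance is exactly ``spacing``. A helix is non-collinear,
    non-planar, never self-intersects, and keeps the local packing density
    independent of chain length.
    """
    chord = 2.0 * radius * np.sin(curvature / 2.0)
    if chord >= spacing:
        raise ValueError("curvature too tight for the requested spacing")
    rise = np.sqrt(spacing ** 2 - chord ** 2)
    t = np.arange(n_residues)
    pos = np.column_stack([radius * np.cos(curvature * t),
                           radius * np.sin(curvature * t),
                           rise * t])
    pos -= pos[0]
    if origin is not None:
        pos += origin
    return pos


_HELIX_RADIUS = 2.3


def _base_model(spec: FixtureSpec) -> CalphaModel:
    chain_names = [chr(ord("A") + c) for c in range(spec.chains)]
    positions = []
    keys: list[ResidueKey] = []
    base = make_chain(spec.n_residues, spec.spacing, spec.curvature,
                      radius=_HELIX_RADIUS)
    if spec.chains > 1:
        # chains sit on a ring about the z (assembly) axis, far enough apart
        # that neighbouring helices keep a ≥ 6 Å gap
        separation = 2.0 * _HELIX_RADIUS + 6.0
        axis_ring = separation / (2.0 * np.sin(np.pi / spec.chains))
        base = base + np.array([axis_ring + _HELIX_RADIUS, 0.0, 0.0])
    for c, cid in enumerate(chain_names):
        rot = _rotation(np.array([0.0, 0.0, 1.0]), 360.0 * c / spec.chains) \
            if spec.chains > 1 else np.eye(3)
        positions.append(base @ rot.T)
        keys.extend((cid, r + 1, "") for r in range(spec.n_residues))
    return CalphaModel(np.vstack(positions), keys,
                       ["ALA"] * (spec.n_residues * spec.chains))


def _apply_motion(spec: FixtureSpec, start: CalphaModel) -> np.ndarray:
    pos = start.positions.copy()
    n_per = spec.n_residues
    if spec.motion == "uniform_translation":
        pos += np.array([spec.amplitude, 0.0, 0.0])
    elif spec.motion == "single_residue":
        pos[n_per // 2] += np.array([0.0, 0.0, spec.amplitude])
    elif spec.motion == "hinge":
        pivot_index = n_per // 2  # hinge in the first chain
        pivot = pos[pivot_index].copy()
        # bend about the local radial direction at the pivot, which splays
        # the two arms apart without driving them through each other
        axis = np.array([pivot[0], pivot[1], 0.0])
        if np.linalg.norm(axis) == 0:
            axis = np.array([1.0, 0.0, 0.0])
        rot = _rotation(axis, spec.amplitude)
        distal = np.arange(pivot_index, n_per)
        pos[distal] = (pos[distal] - pivot) @ rot.T + pivot
    elif spec.motion == "shear":
        # slide the last chain along the assembly axis
        sel = np.arange((spec.chains - 1) * n_per, spec.chains * n_per)
        pos[sel] += np.array([0.0, 0.0, spec.amplitude])
    elif spec.motion == "rotor":
        sel = np.arange((spec.chains - 1) * n_per, spec.chains * n_per)
        rot = _rotation(np.array([0.0, 0.0, 1.0]), spec.amplitude)
        pos[sel] = pos[sel] @ rot.T
    elif spec.motion == "breathing":
        for c in range(spec.chains):
            sel = np.arange(c * n_per, (c + 1) * n_per)
            center = pos[sel].mean(axis=0)
            radial = np.array([center[0], center[1], 0.0])
            norm = np.linalg.norm(radial)
            direction = radial / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            pos[sel] += spec.amplitude * direction
    return pos


def make_two_state(spec: FixtureSpec) -> TwoStatePair:
    """Generate a start/target pair with ground-truth RMSD and κ.

    The ground truth is computed on the raw displacement field (the motion
    exactly as constructed, without re-superposition), matching the
    conventions of :func:`bdpath.path_metrics.rmsd` with ``superpose=False``
    and :func:`bdpath.path_metrics.collectivity`.
    """
    start = _base_model(spec)
    target_pos = _apply_motion(spec, start)
    target = start.with_positions(target_pos)
    if spec.amplitude == 0:
        return TwoStatePair(start, target, 0.0, float("nan"))
    truth_rmsd = path_metrics.rmsd(start, target, superpose=False)
    truth_kappa = path_metrics.collectivity(start, target)
    # guard against self-intersection: beads from different segments should
    # not be driven into each other by the chosen amplitude
    from scipy.spatial.distance import pdist
    if pdist(target_pos).min() < 0.5 * spec.spacing:
        raise ValueError("amplitude drives beads into collision; reduce it")
    return TwoStatePair(start, target, truth_rmsd, truth_kappa)


def make_ensemble(spec: FixtureSpec, n_members: int,
                  mode_variances: Sequence[float] = (4.0, 1.0),
                  noise_sigma: float = 0.0, seed: int = 0,
                  return_modes: bool = False):
    """Synthetic conformational ensemble: base + Σ aₘ·modeₘ + noise.

    Mode shapes are smooth orthonormal displacement fields; the amplitudes
    aₘ are drawn as independent Gaussians with the given variances, so a
    PCA of the ensemble should recover the modes and their variances.
    Reproducible for a given seed. With ``return_modes=True`` the
    ground-truth (3N, n_modes) mode matrix is returned alongside the
    members, for parameter-recovery checks.
    """
    if n_members < 2:
        raise ValueError("an ensemble needs at least 2 members")
    base = _base_model(spec)
    n3 = base.n_residues * 3
    # smooth sinusoidal fields, orthonormalized
    raw = np.zeros((n3, len(mode_variances)))
    t = np.arange(base.n_residues)
    for m in range(len(mode_variances)):
        field = np.zeros((base.n_residues, 3))
        field[:, m % 3] = np.sin((m + 1) * np.pi * (t + 0.5) / base.n_residues)
        raw[:, m] = field.ravel()
    modes, _ = np.linalg.qr(raw)
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        amps = rng.normal(0.0, np.sqrt(np.asarray(mode_variances, dtype=float)))
        disp = (modes * amps).sum(axis=1).reshape(-1, 3)
        coords = base.positions + disp
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        members.append(base.with_positions(coords))
    if return_modes:
        return members, modes
    return members


def degrade_model(model: CalphaModel, drop_keys, seed: int = 0) -> CalphaModel:
    """Remove residues from a model (emulating missing density).

    ``drop_keys`` is either an explicit iterable of residue keys or an
    integer count of random residues to drop (chosen with ``seed``).
    """
    if isinstance(drop_keys, int):
        if drop_keys < 0:
            raise ValueError("cannot drop a negative number of residues")
        rng = np.random.default_rng(seed)
        idx = rng.choice(model.n_residues, size=drop_keys, replace=False)
        drop = {model.residue_keys[i] for i in idx}
    else:
        drop = set(drop_keys)
    keep = [i for i, key in enumerate(model.residue_keys) if key not in drop]
    if len(keep) < 2:
        raise ValueError("dropping these residues leaves fewer than 2 beads")
    return model.subset(keep)
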