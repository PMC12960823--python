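"""Ensemble principal component analysis and optimal superposition.

Structural ensembles (n conformations × 3N Cα coordinates, already
superposed onto a reference) are decomposed into principal components by
eigendecomposition of the positional covariance matrix

    C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩ ,   C = U Δ Uᵀ ,

with the average taken over the n structures. Eigenvalues (variances, Å²)
are sorted in descending order; the leading eigenvectors are the dominant
collective motions of the ensemble. Structures are placed in PC space by
projecting their displacement from the *reference structure* (not the
ensemble mean) onto each unit-normalized component:

    p_{l,m} = (X_l − X_ref) · PC_m / |PC_m| .

Note the deliberate asymmetry: the covariance is mean-centered while the
projection is reference-anchored. Both conventions are implemented exactly
as defined; with the reference close to the mean they differ only by a
constant offset per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import CalphaModel, Ensemble

__all__ = [
    "PCABasis",
    "kabsch_superpose",
    "superpose_ensemble",
    "ensemble_pca",
    "project",
    "project_many",
    "variance_fraction",
]


@dataclass
class PCABasis:
    """Principal components of a superposed structural ensemble.

    ``eigenvectors`` has unit-norm 3N-dimensional columns (PC1 first);
    ``eigenvalues`` are the corresponding variances in Å², descending.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    mean_coordinates: np.ndarray
    reference_coordinates: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted in descending order")
        self.eigenvalues = np.maximum(self.eigenvalues, 0.0)

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def _as_coords(x) -> np.ndarray:
    if isinstance(x, CalphaModel):
        return x.positions
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 3)
    return arr


def kabsch_superpose(mobile, reference, matched_index_mask=None):
    """Optimal rigid superposition (rotation + translation, no reflection).

    Finds the proper rigid transform minimizing the RMSD of ``mobile`` onto
    ``reference`` over the masked beads, applies it to *all* beads of
    ``mobile``, and returns ``(transformed, rmsd)`` where the RMSD is over
    the masked beads. Accepts (N, 3) arrays or :class:`CalphaModel`s (a
    model input returns a model).

    Raises
    ------
    ValueError
        For fewer than 3 masked beads or an exactly collinear selection,
        where the rotation is not uniquely determined.
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    if matched_index_mask is None:
        sel = np.arange(mob.shape[0])
    else:
        sel = np.asarray(matched_index_mask)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 matched beads")
    p = mob[sel]
    q = ref[sel]
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    # collinear selections leave the rotation about the line undetermined
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("matched beads are collinear; superposition is degenerate")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transformed = (mob - p.mean(axis=0)) @ rot.T + q.mean(axis=0)
    diff = transformed[sel] - q
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    if isinstance(mobile, CalphaModel):
        return mobile.with_positions(transformed), rmsd
    return transformed, rmsd


def superpose_ensemble(ensemble: Ensemble) -> Ensemble:
    """Superpose every ensemble member onto the reference row."""
    ref = ensemble.coordinate_matrix[ensemble.reference_index].reshape(-1, 3)
    rows = []
    for row in ensemble.coordinate_matrix:
        aligned, _ = kabsch_superpose(row.reshape(-1, 3), ref)
        rows.append(aligned.ravel())
    return Ensemble(np.array(rows), list(ensemble.residue_keys),
                    ensemble.reference_index, list(ensemble.member_ids))


def ensemble_pca(ensemble: Ensemble) -> PCABasis:
    """Principal components of a (pre-superposed) coordinate ensemble.

    The covariance uses the ensemble mean and a 1/n normalization; the sum
    of the eigenvalues equals the trace of the covariance. Each component's
    sign is fixed so that its largest-magnitude entry is positive, making
    projections reproducible across runs.
    """
    x = ensemble.coordinate_matrix
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 conformations")
    mean = x.mean(axis=0)
    centered = x - mean
    # SVD of the centered matrix: eigenvalues of C = XcᵀXc/n are s²/n.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / n
    eigenvectors = vt.T
    # deterministic sign convention
    for m in range(eigenvectors.shape[1]):
        col = eigenvectors[:, m]
        if col[np.argmax(np.abs(col))] < 0:
            eigenvectors[:, m] = -col
    reference = x[ensemble.reference_index]
    return PCABasis(eigenvectors, eigenvalues, mean, reference.copy())


def project(conformation, basis: PCABasis, m: int) -> float:
    """Projection (Å) of a conformation on the m-th PC (1-based).

    Computes (X_l − X_ref)·PC_m/|PC_m|, anchored at the reference structure.
    The conformation must already be superposed onto the same reference.
    """
    if not 1 <= m <= basis.n_components:
        raise ValueError(f"PC index {m} out of range 1..{basis.n_components}")
    x = _as_coords(conformation).ravel()
    if x.shape[0] != basis.reference_coordinates.shape[0]:
        raise ValueError("conformation size does not match the PCA basis")
    pc = basis.eigenvectors[:, m - 1]
    return float((x - basis.reference_coordinates) @ pc / np.linalg.norm(pc))


def project_many(conformations, basis: PCABasis, n_components: int = 2) -> np.ndarray:
    """Projections of several conformations on the top components.

    Returns an (n_conformations, n_components) array.
    """
    rows = []
    for conf in conformations:
        rows.append([project(conf, basis, m) for m in range(1, n_components + 1)])
    return np.array(rows)


def variance_fraction(basis: PCABasis, top_k: int) -> float:
    """Fraction of total ensemble variance captured by the top k PCs."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    total = float(np.sum(basis.eigenvalues))
    if total <= 0:
        raise ValueError("ensemble has zero total variance")
    return float(np.sum(basis.eigenvalues[:top_k]) / total)
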