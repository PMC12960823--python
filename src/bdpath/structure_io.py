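"""Read and write Cα-only protein models.

The whole package works on one bead per residue (the Cα atom). This module
parses PDB files into :class:`CalphaModel` objects, establishes residue
correspondence between two models by (chain, residue number, insertion code)
keys, assembles common-residue coordinate ensembles for PCA, and writes
multi-model PDB trajectories.

Residue numbering is taken from the file as-is; no renumbering is ever
performed. Chains are concatenated in file order to form the flat bead index.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import gemmi

__all__ = [
    "ResidueKey",
    "CalphaModel",
    "CorrespondenceMap",
    "Ensemble",
    "PDBParseError",
    "read_calpha_model",
    "read_trajectory",
    "match_residues",
    "reduce_to_common",
    "write_multimodel_pdb",
    "write_correspondence_csv",
]

#: (chain_id, residue_number, insertion_code); insertion code "" when absent.
ResidueKey = tuple[str, int, str]


class PDBParseError(ValueError):
    """Raised when a PDB source cannot be turned into a valid Cα model."""


@dataclass
class CalphaModel:
    """One bead per residue: coordinates plus identifying residue keys.

    Parameters
    ----------
    positions:
        (N, 3) array of Cα coordinates in Å.
    residue_keys:
        Length-N list of (chain_id, residue_number, insertion_code) tuples,
        unique within the model.
    labels:
        Optional length-N list of 3-letter amino-acid codes.
    """

    positions: np.ndarray
    residue_keys: list[ResidueKey]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = self.positions.shape[0]
        if n < 2:
            raise ValueError(f"a CalphaModel needs at least 2 residues, got {n}")
        if len(self.residue_keys) != n:
            raise ValueError("positions and residue_keys must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("coordinates must be finite")
        if len(set(self.residue_keys)) != n:
            seen: set[ResidueKey] = set()
            for key in self.residue_keys:
                if key in seen:
                    raise ValueError(f"duplicate residue key {key}")
                seen.add(key)
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels must match the number of residues")

    @property
    def n_residues(self) -> int:
        return self.positions.shape[0]

    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in file order."""
        out: list[str] = []
        for cid, _, _ in self.residue_keys:
            if not out or out[-1] != cid:
                if cid not in out:
                    out.append(cid)
        return out

    def key_index(self) -> dict[ResidueKey, int]:
        return {key: i for i, key in enumerate(self.residue_keys)}

    def with_positions(self, positions: np.ndarray) -> "CalphaModel":
        """Copy of this model with replaced coordinates."""
        return CalphaModel(np.array(positions, dtype=float), list(self.residue_keys),
                           None if self.labels is None else list(self.labels))

    def subset(self, indices: Sequence[int]) -> "CalphaModel":
        idx = list(indices)
        return CalphaModel(
            self.positions[idx],
            [self.residue_keys[i] for i in idx],
            None if self.labels is None else [self.labels[i] for i in idx],
        )


@dataclass
class CorrespondenceMap:
    """Residue pairing between two models by identical residue keys."""

    matched_pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    def indices_a(self) -> np.ndarray:
        return np.array([i for i, _ in self.matched_pairs], dtype=int)

    def indices_b(self) -> np.ndarray:
        return np.array([j for _, j in self.matched_pairs], dtype=int)


@dataclass
class Ensemble:
    """n conformations × 3N flattened coordinates over common residues."""

    coordinate_matrix: np.ndarray
    residue_keys: list[ResidueKey]
    reference_index: int = 0
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinate_matrix = np.asarray(self.coordinate_matrix, dtype=float)
        n, width = self.coordinate_matrix.shape
        if n < 2:
            raise ValueError("an ensemble needs at least 2 conformations")
        if width != 3 * len(self.residue_keys):
            raise ValueError("coordinate matrix width must equal 3 x number of residues")
        if not 0 <= self.reference_index < n:
            raise ValueError("reference_index out of range")
        if not self.member_ids:
            self.member_ids = [f"model_{i}" for i in range(n)]

    @property
    def n_members(self) -> int:
        return self.coordinate_matrix.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def member_model(self, index: int) -> CalphaModel:
        coords = self.coordinate_matrix[index].reshape(-1, 3)
        return CalphaModel(coords, list(self.residue_keys))


def _source_to_structure(source: str | Path) -> tuple[gemmi.Structure, str]:
    """Accept a filesystem path or raw PDB text."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and os.path.exists(source)):
        name = str(source)
        structure = gemmi.read_structure(name, format=gemmi.CoorFormat.Pdb)
    else:
        name = "<string>"
        structure = gemmi.read_pdb_string(str(source))
    return structure, name


def _model_from_gemmi(model: gemmi.Model, name: str) -> CalphaModel:
    # Candidate CA atoms per residue key; altlocs resolved afterwards.
    candidates: dict[ResidueKey, list[tuple[str, float, tuple[float, float, float], str]]] = {}
    order: list[ResidueKey] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A":
                continue
            icode = residue.seqid.icode.strip()
            key: ResidueKey = (chain.name, residue.seqid.num, icode)
            for atom in residue:
                if atom.name != "CA":
                    continue
                altloc = atom.altloc if atom.altloc not in ("\x00", " ") else ""
                if key not in candidates:
                    candidates[key] = []
                    order.append(key)
                candidates[key].append(
                    (altloc, atom.occ, (atom.pos.x, atom.pos.y, atom.pos.z), residue.name)
                )
    if not candidates:
        raise PDBParseError(f"{name}: no Cα ATOM records found")
    positions = []
    labels = []
    for key in order:
        cands = candidates[key]
        altlocs = [c[0] for c in cands]
        if len(set(altlocs)) != len(altlocs):
            raise PDBParseError(
                f"{name}: duplicate Cα for residue {key} after altloc resolution"
            )
        # Highest occupancy wins; ties broken by alphabetical altloc id
        # (blank altloc sorts first).
        best = min(cands, key=lambda c: (-c[1], c[0]))
        positions.append(best[2])
        labels.append(best[3])
    if len(order) < 2:
        raise PDBParseError(f"{name}: fewer than 2 Cα residues")
    return CalphaModel(np.array(positions, dtype=float), order, labels)


def read_calpha_model(source: str | Path) -> CalphaModel:
    """Parse a PDB file or PDB text into a Cα-only model.

    Only ATOM records with atom name CA are considered; HETATM records are
    ignored. When the file contains several MODEL blocks, the first one is
    used. Alternate locations are resolved by keeping the highest-occupancy
    conformer (ties broken by alphabetical altloc identifier).
    """
    structure, name = _source_to_structure(source)
    if len(structure) == 0:
        raise PDBParseError(f"{name}: no coordinate models in file")
    return _model_from_gemmi(structure[0], name)


def read_trajectory(source: str | Path) -> list[CalphaModel]:
    """Parse every MODEL block of a multi-model PDB into a list of models."""
    structure, name = _source_to_structure(source)
    if len(structure) == 0:
        raise PDBParseError(f"{name}: no coordinate models in file")
    return [_model_from_gemmi(model, name) for model in structure]


def match_residues(model_a: CalphaModel, model_b: CalphaModel) -> CorrespondenceMap:
    """Pair residues of two models that share a (chain, number, icode) key.

    Matched pairs follow the order of ``model_a``. Zero overlap is not an
    error: the map simply has no matched pairs, and callers decide.
    """
    index_b = model_b.key_index()
    matched: list[tuple[int, int]] = []
    unmatched_a: list[int] = []
    matched_b: set[int] = set()
    for i, key in enumerate(model_a.residue_keys):
        j = index_b.get(key)
        if j is None:
            unmatched_a.append(i)
        else:
            matched.append((i, j))
            matched_b.add(j)
    unmatched_b = [j for j in range(model_b.n_residues) if j not in matched_b]
    return CorrespondenceMap(matched, unmatched_a, unmatched_b)


def reduce_to_common(models: Sequence[CalphaModel], reference_index: int = 0) -> Ensemble:
    """Restrict models to residues present in every one of them.

    Returns an :class:`Ensemble` whose rows contain exactly the intersection
    of residue keys across all models, ordered as in the reference model.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to build an ensemble")
    if not 0 <= reference_index < len(models):
        raise ValueError("reference_index out of range")
    common = set(models[0].residue_keys)
    for model in models[1:]:
        common &= set(model.residue_keys)
    if not common:
        raise ValueError("no residues are common to all models")
    reference = models[reference_index]
    ordered = [key for key in reference.residue_keys if key in common]
    rows = []
    for model in models:
        index = model.key_index()
        rows.append(model.positions[[index[key] for key in ordered]].ravel())
    return Ensemble(np.array(rows), ordered, reference_index)


def write_multimodel_pdb(frames: Sequence[CalphaModel], path: str | Path) -> None:
    """Write frames as a multi-model PDB trajectory (MODEL blocks from 1).

    All frames must share residue keys. Coordinates are written with the
    standard 3-decimal PDB precision, so a read/write round trip preserves
    them to 1e-3 Å.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    keys = frames[0].residue_keys
    for k, frame in enumerate(frames[1:], start=2):
        if frame.residue_keys != keys:
            raise ValueError(f"frame {k} has residue keys differing from frame 1")
    structure = gemmi.Structure()
    structure.name = "bdpath trajectory"
    for m, frame in enumerate(frames, start=1):
        model = gemmi.Model(m)
        chain: gemmi.Chain | None = None
        for i, (cid, num, icode) in enumerate(frame.residue_keys):
            if chain is None or chain.name != cid:
                if chain is not None:
                    model.add_chain(chain)
                chain = gemmi.Chain(cid)
            residue = gemmi.Residue()
            residue.name = frame.labels[i] if frame.labels else "ALA"
            residue.seqid = gemmi.SeqId(num, icode if icode else " ")
            residue.het_flag = "A"
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            x, y, z = frame.positions[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            residue.add_atom(atom)
            chain.add_residue(residue)
        if chain is not None:
            model.add_chain(chain)
        structure.add_model(model)
    structure.write_pdb(str(path))


def write_correspondence_csv(cmap: CorrespondenceMap, model_a: CalphaModel,
                             model_b: CalphaModel, path: str | Path) -> None:
    """Write a residue-correspondence report as CSV."""
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["status", "index_a", "index_b", "chain", "resnum", "icode"])
        for i, j in cmap.matched_pairs:
            cid, num, icode = model_a.residue_keys[i]
            writer.writerow(["matched", i, j, cid, num, icode])
        for i in cmap.unmatched_a:
            cid, num, icode = model_a.residue_keys[i]
            writer.writerow(["only_a", i, "", cid, num, icode])
        for j in cmap.unmatched_b:
            cid, num, icode = model_b.residue_keys[j]
            writer.writerow(["only_b", "", j, cid, num, icode])
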