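"""Structure-aware post-processing of residue predictions.

Predicted membrane-interacting residues that are counted as false
positives often sit directly beside annotated interfacial residues in the
3-D structure — on the same loop, facing the same bilayer.  Two
operations exploit the coordinates:

* :func:`reclassify_fp` recounts a false positive as a true positive when
  any of its heavy atoms lies within a cutoff (default 3 Å, the range of
  direct intermolecular contacts) of any heavy atom of an annotated
  membrane-interacting residue.  This can only raise precision.
* :func:`estimate_membrane_plane` fits a least-squares plane through the
  alpha-carbons of the annotated residues — a putative bilayer surface
  for visual inspection.

Distances use heavy atoms only; deposited structures typically lack
hydrogens.  The cutoff test is inclusive (distance ≤ radius).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .metrics import ConfusionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "MembranePlane",
    "read_structure",
    "write_pdb",
    "min_residue_distance",
    "reclassify_fp",
    "estimate_membrane_plane",
]

_HYDROGEN = ("H", "D")


@dataclass
class StructureModel:
    """Heavy-atom coordinates of one chain, indexed like the sequence.

    ``atoms_by_position`` maps 0-based residue position to an (n_atoms, 3)
    float array in Å; ``atom_names`` and ``residue_names`` parallel it.
    ``resolved_mask`` flags which sequence positions have coordinates.
    """

    protein_id: str
    atoms_by_position: dict[int, np.ndarray]
    atom_names: dict[int, list[str]]
    residue_names: dict[int, str]
    length: int

    def __post_init__(self) -> None:
        for pos, xyz in self.atoms_by_position.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
                raise ValueError(
                    f"position {pos}: need an (n_atoms, 3) array, got {arr.shape}"
                )
            self.atoms_by_position[pos] = arr
        if self.atoms_by_position:
            if min(self.atoms_by_position) < 0 or max(self.atoms_by_position) >= self.length:
                raise ValueError("atom positions out of sequence bounds")

    @property
    def resolved_mask(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=np.int8)
        mask[sorted(self.atoms_by_position)] = 1
        return mask

    def alpha_carbons(self, positions: Sequence[int]) -> np.ndarray:
        """CA coordinates for the given resolved positions (first atom fallback)."""
        coords = []
        for pos in positions:
            names = self.atom_names[pos]
            idx = names.index("CA") if "CA" in names else 0
            coords.append(self.atoms_by_position[pos][idx])
        return np.asarray(coords, dtype=float)


@dataclass(frozen=True)
class MembranePlane:
    """Putative bilayer plane: anchor point, unit normal, fit RMS (Å)."""

    point: np.ndarray
    normal: np.ndarray
    inlier_rms: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")

    def signed_distance(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.point) @ self.normal


def read_structure(
    path: str | Path,
    chain: str,
    protein_id: str | None = None,
    length: int | None = None,
) -> StructureModel:
    """Parse the heavy atoms of one chain from a PDB-format file.

    Alternate locations collapse to the highest-occupancy conformer;
    hydrogens and HETATM records are dropped.  Residue numbers are taken
    as 1-based sequence positions, so numbering gaps (unresolved
    stretches) leave zeros in ``resolved_mask``.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id or Path(path).stem, str(path))
    model = next(structure.get_models())
    available = [c.id for c in model.get_chains()]
    if chain not in available:
        raise KeyError(f"chain {chain!r} not in {path}; available: {available}")

    atoms_by_pos: dict[int, np.ndarray] = {}
    names_by_pos: dict[int, list[str]] = {}
    res_names: dict[int, str] = {}
    for residue in model[chain]:
        if not is_aa(residue, standard=False) or residue.id[0].strip():
            continue  # skip HETATM / waters
        pos = residue.id[1] - 1
        # collapse altlocs: keep highest occupancy per atom name
        best: dict[str, tuple[float, np.ndarray]] = {}
        for atom in residue.get_unpacked_list():
            if atom.element in _HYDROGEN:
                continue
            occ = atom.get_occupancy() or 1.0
            name = atom.get_name()
            if name not in best or occ > best[name][0]:
                best[name] = (occ, np.asarray(atom.coord, dtype=float))
        if not best:
            continue
        names_by_pos[pos] = list(best)
        atoms_by_pos[pos] = np.asarray([v[1] for v in best.values()])
        res_names[pos] = residue.get_resname()

    if not atoms_by_pos:
        raise ValueError(f"chain {chain!r} in {path} has no heavy atoms")
    n = length if length is not None else max(atoms_by_pos) + 1
    return StructureModel(
        protein_id or Path(path).stem, atoms_by_pos, names_by_pos, res_names, n
    )


def write_pdb(path: str | Path, structure: StructureModel, chain: str = "A") -> None:
    """Write a minimal single-chain PDB file that round-trips through
    :func:`read_structure`."""
    serial = 1
    with open(path, "w", encoding="utf-8") as fh:
        for pos in sorted(structure.atoms_by_position):
            resname = structure.residue_names.get(pos, "GLY")
            for name, (x, y, z) in zip(
                structure.atom_names[pos], structure.atoms_by_position[pos]
            ):
                element = name.strip()[0]
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}"
                    f"{pos + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def min_residue_distance(structure: StructureModel, i: int, j: int) -> float:
    """Minimum heavy-atom pair distance (Å) between residues i and j."""
    for pos in (i, j):
        if pos not in structure.atoms_by_position:
            raise ValueError(
                f"residue position {pos} is unresolved in {structure.protein_id!r}"
            )
    a = structure.atoms_by_position[i]
    b = structure.atoms_by_position[j]
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def reclassify_fp(
    true_labels,
    predicted_labels,
    structure: StructureModel,
    radius: float = 3.0,
) -> tuple[ConfusionMatrix, np.ndarray, np.ndarray]:
    """Recount false positives near annotated residues as true positives.

    A false-positive residue is reclassified when the minimum heavy-atom
    distance to any annotated membrane-interacting (label 1) residue is
    at most ``radius``.  TN/FN counts are untouched, so precision can
    only increase.  Unresolved false positives stay unadjusted (logged).

    Returns the adjusted confusion matrix, a per-residue reclassification
    flag vector, and the per-FP minimum distance (NaN where undefined).
    """
    t = np.asarray(true_labels, dtype=np.int8)
    p = np.asarray(predicted_labels, dtype=np.int8)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if len(t) != structure.length:
        raise ValueError(
            f"label length {len(t)} != structure length {structure.length}"
        )
    if radius < 0:
        raise ValueError(f"radius must be nonnegative, got {radius}")

    ibs_positions = [
        pos for pos in np.flatnonzero(t == 1) if pos in structure.atoms_by_position
    ]
    ibs_atoms = (
        np.vstack([structure.atoms_by_position[pos] for pos in ibs_positions])
        if ibs_positions
        else np.empty((0, 3))
    )
    tree = cKDTree(ibs_atoms) if len(ibs_atoms) else None

    flags = np.zeros(len(t), dtype=np.int8)
    min_dist = np.full(len(t), np.nan)
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    for pos in np.flatnonzero((t == 0) & (p == 1)):
        if pos not in structure.atoms_by_position:
            logger.warning(
                "%s: false positive at position %d is unresolved; left unadjusted",
                structure.protein_id,
                pos,
            )
            continue
        if tree is None:
            continue
        d, _ = tree.query(structure.atoms_by_position[pos], k=1)
        dmin = float(np.min(d))
        min_dist[pos] = dmin
        if dmin <= radius:
            flags[pos] = 1
            tp += 1
            fp -= 1
    return ConfusionMatrix(tp, fp, fn, tn), flags, min_dist


def estimate_membrane_plane(
    structure: StructureModel,
    ibs_labels,
    normal_mode: str = "least-variance",
) -> MembranePlane:
    """Fit the putative membrane plane through annotated IBS alpha-carbons.

    The plane passes through the centroid of the resolved IBS CA
    coordinates; with the default ``normal_mode="least-variance"`` the
    normal is the direction of least coordinate variance (ordinary
    total-least-squares plane).  ``normal_mode="principal-axis"`` instead
    returns the first principal axis as the normal, for the alternative
    reading where the bilayer is drawn perpendicular to the IBS spread.
    """
    labels = np.asarray(ibs_labels, dtype=np.int8)
    if len(labels) != structure.length:
        raise ValueError("label vector length differs from structure length")
    positions = [
        pos for pos in np.flatnonzero(labels == 1) if pos in structure.atoms_by_position
    ]
    if len(positions) < 3:
        raise ValueError(
            f"need >= 3 resolved IBS residues to fit a plane, got {len(positions)}"
        )
    coords = structure.alpha_carbons(positions)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("IBS alpha-carbons are collinear; plane is undefined")
    if normal_mode == "least-variance":
        normal = vt[2]
    elif normal_mode == "principal-axis":
        normal = vt[0]
    else:
        raise ValueError(f"unknown normal_mode {normal_mode!r}")
    normal = normal / np.linalg.norm(normal)
    # deterministic sign: positive z component, tie-broken by y then x
    for k in (2, 1, 0):
        if abs(normal[k]) > 1e-12:
            if normal[k] < 0:
                normal = -normal
            break
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return MembranePlane(point=centroid, normal=normal, inlier_rms=rms)
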