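"""Reading, writing and basic geometry of receptor and peptide-pose structures.

The receptor is a trypsin-like serine protease read from a single-model PDB
file with author residue numbering; the catalytic triad (His, Asp, Ser) and
the S1-pocket aspartate are declared at read time and validated against the
atoms actually present. Docked peptide binding modes arrive as multi-model
PDB files, one MODEL per pose, and are renumbered into substrate (author)
coordinates via an integer offset.

All distance criteria downstream operate on heavy atoms only: hydrogens are
dropped at ingest. Alternate locations beyond the first are ignored with a
warning, and insertion codes are rejected because the author-numbering
contract assumes plain integer residue numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from scipy.spatial.distance import cdist

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    PoseFormatError,
    StructureError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "Atom",
    "ProteaseReceptor",
    "PeptidePose",
    "PoseSet",
    "read_receptor",
    "read_pose_ensemble",
    "write_pose_ensemble",
    "write_receptor",
    "min_group_distance",
    "BACKBONE_ATOMS",
]


@dataclass(frozen=True)
class Atom:
    """One heavy atom with author residue numbering."""

    name: str
    element: str
    coords: tuple[float, float, float]
    residue_number: int
    residue_name: str
    chain_id: str = "A"

    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class ProteaseReceptor:
    """Protease structure with annotated catalytic triad and S1 anchor.

    ``triad`` holds the author numbers of the catalytic histidine, aspartate
    and serine (in that order); ``s1_anchor`` is the aspartate at the bottom
    of the S1 pocket whose carboxylate forms the salt bridge with the
    substrate's P1 arginine/lysine.
    """

    atoms: list[Atom]
    triad: tuple[int, int, int] = (296, 345, 441)
    s1_anchor: int = 435
    numbering_scheme: str = "author"

    def __post_init__(self) -> None:
        present = {a.residue_number for a in self.atoms}
        for label, resnum in zip(("triad His", "triad Asp", "triad Ser"), self.triad):
            if resnum not in present:
                raise ConfigurationError(
                    f"{label} residue {resnum} not found in receptor"
                )
        if self.s1_anchor not in present:
            raise ConfigurationError(
                f"S1 anchor residue {self.s1_anchor} not found in receptor"
            )
        if not self.atom_names(self.triad[2]) >= {"OG"}:
            raise StructureError(
                f"catalytic serine {self.triad[2]} lacks the OG hydroxyl oxygen"
            )
        if not self.atom_names(self.s1_anchor) >= {"OD1", "OD2"}:
            raise StructureError(
                f"S1 aspartate {self.s1_anchor} lacks carboxylate oxygens OD1/OD2"
            )

    def residue_atoms(self, residue_number: int) -> list[Atom]:
        return [a for a in self.atoms if a.residue_number == residue_number]

    def atom_names(self, residue_number: int) -> set[str]:
        return {a.name for a in self.residue_atoms(residue_number)}

    def atom_coords(self, residue_number: int, names: Iterable[str]) -> np.ndarray:
        wanted = set(names)
        pts = [a.coords for a in self.residue_atoms(residue_number) if a.name in wanted]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    @property
    def s1_carboxylate(self) -> np.ndarray:
        """Coordinates of the S1 aspartate's OD1/OD2 oxygens, shape (2, 3)."""
        return self.atom_coords(self.s1_anchor, ("OD1", "OD2"))

    @property
    def catalytic_og(self) -> np.ndarray:
        """Coordinates of the catalytic serine's OG oxygen, shape (3,)."""
        return self.atom_coords(self.triad[2], ("OG",))[0]


@dataclass
class PeptidePose:
    """One docked binding mode, residue-numbered in substrate coordinates."""

    pose_id: int
    peptide_label: str
    atoms: list[Atom]
    source: str = ""
    engine_score: float | None = None

    def __post_init__(self) -> None:
        resnums = self.residue_numbers()
        if resnums and resnums != list(range(resnums[0], resnums[-1] + 1)):
            raise PoseFormatError(
                f"pose {self.pose_id}: residue numbers {resnums} are not contiguous"
            )
        for resnum in resnums:
            names = {a.name for a in self.atoms if a.residue_number == resnum}
            missing = set(BACKBONE_ATOMS) - names
            if missing:
                raise PoseFormatError(
                    f"pose {self.pose_id}: residue {resnum} lacks backbone "
                    f"atom(s) {sorted(missing)}"
                )

    def residue_numbers(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms})

    def residue_atoms(self, residue_number: int) -> list[Atom]:
        return [a for a in self.atoms if a.residue_number == residue_number]

    def atom_coords(self, residue_number: int, names: Iterable[str]) -> np.ndarray:
        wanted = set(names)
        pts = [
            a.coords
            for a in self.atoms
            if a.residue_number == residue_number and a.name in wanted
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PeptidePose":
        """Return a rigidly transformed copy (x' = R x + t)."""
        rot = np.asarray(rotation, dtype=float)
        tra = np.asarray(translation, dtype=float)
        new_atoms = [
            Atom(
                name=a.name,
                element=a.element,
                coords=tuple(rot @ a.xyz() + tra),
                residue_number=a.residue_number,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
            )
            for a in self.atoms
        ]
        return PeptidePose(
            pose_id=self.pose_id,
            peptide_label=self.peptide_label,
            atoms=new_atoms,
            source=self.source,
            engine_score=self.engine_score,
        )


@dataclass
class PoseSet:
    """An ordered ensemble of binding modes of one peptide window."""

    receptor_ref: str
    peptide_label: str
    poses: list[PeptidePose] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = {tuple(p.residue_numbers()) for p in self.poses}
        if len(spans) > 1:
            raise PoseFormatError(
                f"ensemble '{self.peptide_label}': poses disagree on residue "
                f"spans {sorted(spans)}"
            )
        labels = {p.peptide_label for p in self.poses}
        if len(labels) > 1:
            raise PoseFormatError(
                f"ensemble mixes peptide labels {sorted(labels)}"
            )

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


# ---------------------------------------------------------------------------
# PDB ingest / emit (biotite does the parsing; we only validate + convert)
# ---------------------------------------------------------------------------

def _array_to_atoms(array: struc.AtomArray, residue_offset: int = 0) -> list[Atom]:
    if np.any(array.ins_code != ""):
        bad = sorted(set(array.res_id[array.ins_code != ""].tolist()))
        raise StructureError(
            f"insertion codes are not supported (residues {bad}); "
            "renumber the structure to plain author numbers"
        )
    atoms: list[Atom] = []
    for i in range(array.array_length()):
        element = str(array.element[i]).upper()
        if element in ("H", "D"):
            continue
        atoms.append(
            Atom(
                name=str(array.atom_name[i]),
                element=element,
                coords=tuple(float(x) for x in array.coord[i]),
                residue_number=int(array.res_id[i]) + residue_offset,
                residue_name=str(array.res_name[i]),
                chain_id=str(array.chain_id[i]) or "A",
            )
        )
    return atoms


def _atoms_to_array(atoms: Sequence[Atom]) -> struc.AtomArray:
    array = struc.AtomArray(len(atoms))
    array.coord = np.asarray([a.coords for a in atoms], dtype=np.float32)
    array.chain_id = np.asarray([a.chain_id for a in atoms])
    array.res_id = np.asarray([a.residue_number for a in atoms])
    array.res_name = np.asarray([a.residue_name for a in atoms])
    array.atom_name = np.asarray([a.name for a in atoms])
    array.element = np.asarray([a.element for a in atoms])
    array.hetero = np.zeros(len(atoms), dtype=bool)
    return array


def read_receptor(
    path: str | Path,
    triad: tuple[int, int, int] = (296, 345, 441),
    s1_anchor: int = 435,
    numbering_scheme: str = "author",
) -> ProteaseReceptor:
    """Read a single-model receptor PDB and annotate its functional residues.

    Raises :class:`ConfigurationError` if a named triad/S1 residue is absent
    and :class:`StructureError` if the serine OG or aspartate OD1/OD2 atoms
    are missing.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # altloc/occupancy notices
        array = pdb_file.get_structure(model=1, altloc="first")
    return ProteaseReceptor(
        atoms=_array_to_atoms(array),
        triad=tuple(triad),
        s1_anchor=s1_anchor,
        numbering_scheme=numbering_scheme,
    )


def read_pose_ensemble(
    path: str | Path,
    peptide_label: str,
    residue_offset: int = 0,
    receptor_ref: str = "",
) -> PoseSet:
    """Read a multi-model PDB pose ensemble into a :class:`PoseSet`.

    ``residue_offset`` shifts the file's (typically 1-based) residue numbers
    into substrate author numbering; pose ids follow MODEL order starting
    at 1.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise EmptyInputError(f"{path}: no MODEL records / atoms found")
    poses = []
    for model in range(1, n_models + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            array = pdb_file.get_structure(model=model, altloc="first")
        try:
            pose = PeptidePose(
                pose_id=model,
                peptide_label=peptide_label,
                atoms=_array_to_atoms(array, residue_offset=residue_offset),
                source=f"{path}#model{model}",
            )
        except PoseFormatError as err:
            raise PoseFormatError(f"{path}: {err}") from err
        poses.append(pose)
    return PoseSet(receptor_ref=receptor_ref or str(path), peptide_label=peptide_label,
                   poses=poses)


def write_pose_ensemble(
    poses: Sequence[PeptidePose], path: str | Path, residue_offset: int = 0
) -> None:
    """Write poses as a multi-model PDB (one MODEL per pose, file order).

    ``residue_offset`` is added to each residue number on output, mirroring
    the ingest convention (pass the negative ingest offset to round-trip).
    """
    if not poses:
        raise EmptyInputError("cannot write an empty pose ensemble")
    arrays = []
    for pose in poses:
        array = _atoms_to_array(pose.atoms)
        array.res_id = array.res_id + residue_offset
        arrays.append(array)
    try:
        stack = struc.stack(arrays)
    except Exception as err:  # heterogeneous atom sets
        raise PoseFormatError(
            f"poses have inconsistent atom sets and cannot share one file: {err}"
        ) from err
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_receptor(receptor: ProteaseReceptor, path: str | Path) -> None:
    """Write the receptor as a single-model PDB."""
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_atoms_to_array(receptor.atoms))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Geometry primitive
# ---------------------------------------------------------------------------

def min_group_distance(
    atoms_a: Sequence[Atom] | np.ndarray, atoms_b: Sequence[Atom] | np.ndarray
) -> float:
    """Minimum pairwise Euclidean distance (Å) between two atom groups.

    Accepts lists of :class:`Atom` or plain (n, 3) coordinate arrays; the
    result is symmetric in its arguments.
    """
    xa = _as_coords(atoms_a)
    xb = _as_coords(atoms_b)
    if xa.size == 0 or xb.size == 0:
        raise EmptyInputError("min_group_distance requires two non-empty atom groups")
    return float(cdist(xa, xb).min())


def _as_coords(group: Sequence[Atom] | np.ndarray) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return group.reshape(-1, 3).astype(float)
    return np.asarray([a.coords for a in group], dtype=float).reshape(-1, 3)
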