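"""Structure ingestion, superposition and monomer construction.

Coordinates are stored in nanometres throughout the package; PDB I/O
performs the Å↔nm conversion at the boundary.  Author residue numbering
is preserved end-to-end so that residue references such as 56, 143, 168
or 217 always mean the crystal-structure numbering.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Atom",
    "ResidueRecord",
    "Structure",
    "SuperpositionResult",
    "StructureError",
    "read_structure",
    "write_structure",
    "superpose",
    "apply_transform",
    "rmsd_no_fit",
    "build_monomer_os_cth",
    "ca_distance",
    "map_numbering",
]

#: one-letter codes used when aligning residue numbering across constructs
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), nm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class ResidueRecord:
    auth_seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def has_ca(self) -> bool:
        return any(a.name == "CA" for a in self.atoms)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(
            f"atom {name!r} not found in residue {self.name} {self.auth_seq_id}"
        )

    @property
    def ca(self) -> np.ndarray:
        return self.atom("CA").position


@dataclass
class Structure:
    """A single protein chain: ordered residues with coordinates in nm."""

    chain_id: str
    residues: list[ResidueRecord]
    title: str = ""

    def __post_init__(self) -> None:
        ids = [r.auth_seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise StructureError(
                f"residue auth_seq_ids not strictly increasing in chain {self.chain_id}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def auth_ids(self) -> list[int]:
        return [r.auth_seq_id for r in self.residues]

    def residue(self, auth_seq_id: int) -> ResidueRecord:
        for r in self.residues:
            if r.auth_seq_id == auth_seq_id:
                return r
        raise StructureError(
            f"residue {auth_seq_id} not present in chain {self.chain_id}"
        )

    def has_residue(self, auth_seq_id: int) -> bool:
        return any(r.auth_seq_id == auth_seq_id for r in self.residues)

    def ca_coords(self, auth_ids: list[int] | None = None) -> np.ndarray:
        """Cα coordinates (nm) for ``auth_ids`` (default: all residues)."""
        if auth_ids is None:
            auth_ids = self.auth_ids
        return np.array([self.residue(i).ca for i in auth_ids], dtype=float)

    def sequence_one_letter(self) -> str:
        return "".join(_THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        res = [
            ResidueRecord(
                r.auth_seq_id,
                r.name,
                [
                    Atom(a.name, a.element, rotation @ a.position + translation)
                    for a in r.atoms
                ],
            )
            for r in self.residues
        ]
        return Structure(self.chain_id, res, self.title)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), nm
    rmsd: float  # post-fit Cα RMSD over the selection, nm
    n_atoms_used: int


def _structure_from_atom_array(arr: struc.AtomArray, chain_id: str, title: str) -> Structure:
    mask = arr.chain_id == chain_id
    if not mask.any():
        raise StructureError(f"chain {chain_id!r} not found")
    arr = arr[mask]
    residues: list[ResidueRecord] = []
    for start, stop in zip(*_residue_slices(arr)):
        sub = arr[start:stop]
        atoms = [
            Atom(sub.atom_name[k], sub.element[k], sub.coord[k] / 10.0)
            for k in range(len(sub))
            if sub.element[k] != "H"
        ]
        rec = ResidueRecord(int(sub.res_id[0]), str(sub.res_name[0]), atoms)
        if not rec.has_ca:
            warnings.warn(
                f"residue {rec.name} {rec.auth_seq_id} has no CA atom; flagged",
                stacklevel=3,
            )
        residues.append(rec)
    return Structure(chain_id, residues, title)


def _residue_slices(arr: struc.AtomArray) -> tuple[np.ndarray, np.ndarray]:
    starts = struc.get_residue_starts(arr)
    return starts, np.append(starts[1:], len(arr))


def read_structure(
    source: str | Path,
    model_index: int = 0,
    chain: str | None = None,
    keep_hetero: bool = False,
) -> Structure:
    """Read one chain of a PDB file (or PDB text) into a :class:`Structure`.

    Coordinates are converted Å→nm.  Only the first altloc is kept and
    hydrogens are dropped.  ``source`` may be a path or raw PDB text.

    Parameters
    ----------
    model_index : 0-based model index for multi-model files.
    chain : chain identifier; default is the first chain in the file.
    keep_hetero : keep HETATM residues (waters/ligands are dropped by default).
    """
    text: str
    p = Path(str(source))
    if "\n" in str(source):
        text = str(source)
    else:
        if not p.exists():
            raise StructureError(f"no such file: {source}")
        text = p.read_text()
    try:
        pdb_file = pdb.PDBFile.read(io.StringIO(text))
        n_models = pdb_file.get_model_count()
        if not (0 <= model_index < n_models):
            raise StructureError(
                f"model_index {model_index} out of range (file has {n_models} models)"
            )
        arr = pdb_file.get_structure(model=model_index + 1, altloc="first")
    except StructureError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"malformed PDB input: {exc}") from exc
    if not keep_hetero:
        arr = arr[struc.filter_amino_acids(arr)]
    if len(arr) == 0:
        raise StructureError("no protein atoms in input")
    if chain is None:
        chain = str(arr.chain_id[0])
    title = ""
    for line in text.splitlines():
        if line.startswith("TITLE"):
            title += line[10:].rstrip()
    return _structure_from_atom_array(arr, chain, title)


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a single-model PDB file (nm→Å)."""
    n = sum(len(r.atoms) for r in s.residues)
    arr = struc.AtomArray(n)
    k = 0
    for r in s.residues:
        for a in r.atoms:
            arr.chain_id[k] = s.chain_id
            arr.res_id[k] = r.auth_seq_id
            arr.res_name[k] = r.name
            arr.atom_name[k] = a.name
            arr.element[k] = a.element
            arr.coord[k] = a.position * 10.0
            k += 1
    arr.hetero[:] = False
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def rmsd_no_fit(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD between two matched coordinate sets, without fitting (nm)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 1:
        raise StructureError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform: ``R @ mobile + t ≈ target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def superpose(
    mobile: Structure,
    target: Structure,
    selection: set[int] | None = None,
) -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``target`` over Cα atoms.

    ``selection`` is a set of author residue ids shared by both structures
    (default: all shared ids).  The returned RMSD is the post-fit Cα RMSD
    over the selection.
    """
    shared = [i for i in mobile.auth_ids if target.has_residue(i)]
    if selection is not None:
        shared = [i for i in shared if i in set(selection)]
    if len(shared) < 3:
        raise StructureError(
            f"superposition needs >= 3 shared residues, got {len(shared)}"
        )
    a = mobile.ca_coords(shared)
    b = target.ca_coords(shared)
    rot, trans = _kabsch(a, b)
    rmsd = rmsd_no_fit(a @ rot.T + trans, b)
    return SuperpositionResult(rot, trans, rmsd, len(shared))


def apply_transform(s: Structure, result: SuperpositionResult) -> Structure:
    return s.transformed(result.rotation, result.translation)


def ca_distance(s: Structure, res_i: int, res_j: int) -> float:
    """Cα–Cα distance (nm) between two residues given by author ids."""
    return float(np.linalg.norm(s.residue(res_i).ca - s.residue(res_j).ca))


def build_monomer_os_cth(
    open_truncated: Structure,
    dimer_open_chain_a: Structure,
    dimer_open_chain_b: Structure,
    graft_range: tuple[int, int] = (212, 225),
) -> Structure:
    """Graft the domain-swapped C-terminal segment onto a truncated monomer.

    The open-state truncated structure is superposed onto chain A of the
    domain-swapped open-state dimer; the loop+helix segment of chain B
    (author residues ``graft_range``, inclusive) is then appended so that
    the result is a single chain carrying the C-terminal helix docked as
    in the dimer.  All output coordinates are in the chain-A frame.
    """
    lo, hi = graft_range
    if lo > hi:
        return Structure(open_truncated.chain_id, list(open_truncated.residues),
                         open_truncated.title)
    graft_ids = [i for i in dimer_open_chain_b.auth_ids if lo <= i <= hi]
    if not graft_ids:
        raise StructureError(
            f"graft residues {lo}-{hi} missing from chain {dimer_open_chain_b.chain_id}"
        )
    shared = [i for i in open_truncated.auth_ids if dimer_open_chain_a.has_residue(i)]
    if len(shared) < 50:
        raise StructureError(
            f"open structure shares only {len(shared)} residues with chain A; need >= 50"
        )
    fit = superpose(open_truncated, dimer_open_chain_a)
    core = apply_transform(open_truncated, fit)
    last_core = core.residues[-1].auth_seq_id
    if max(core.auth_ids) >= lo:
        raise StructureError(
            f"core already contains residues >= {lo}; cannot graft {lo}-{hi}"
        )
    residues = list(core.residues) + [
        ResidueRecord(
            r.auth_seq_id,
            r.name,
            [Atom(a.name, a.element, a.position.copy()) for a in r.atoms],
        )
        for r in dimer_open_chain_b.residues
        if lo <= r.auth_seq_id <= hi
    ]
    out = Structure(core.chain_id, residues, open_truncated.title)
    if out.has_residue(last_core) and out.has_residue(graft_ids[0]):
        gap = ca_distance(out, last_core, graft_ids[0])
        if gap > 0.6:
            warnings.warn(
                f"chain break: CA({last_core})-CA({graft_ids[0]}) = {gap:.3f} nm > 0.6 nm",
                stacklevel=2,
            )
    return out


def map_numbering(a: Structure, b: Structure) -> dict[int, int]:
    """Map author residue ids of ``a`` onto ``b`` by pairwise sequence alignment.

    Needed when comparing constructs whose numbering differs by point
    insertions (e.g. an engineered insertion in a loop).  Returns a dict
    ``auth_id_in_a -> auth_id_in_b`` over aligned, non-gap positions.
    """
    import biotite.sequence as seq
    import biotite.sequence.align as align

    sa = seq.ProteinSequence(a.sequence_one_letter().replace("X", "A"))
    sb = seq.ProteinSequence(b.sequence_one_letter().replace("X", "A"))
    matrix = align.SubstitutionMatrix.std_protein_matrix()
    ali = align.align_optimal(sa, sb, matrix, gap_penalty=(-10, -1))[0]
    ids_a, ids_b = a.auth_ids, b.auth_ids
    mapping: dict[int, int] = {}
    for ia, ib in ali.trace:
        if ia >= 0 and ib >= 0:
            mapping[ids_a[ia]] = ids_b[ib]
    return mapping
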