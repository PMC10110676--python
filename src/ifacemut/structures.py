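"""Macromolecular structure data model and PDB I/O.

The in-memory model is deliberately small: atoms with coordinates, grouped
into residues identified by author numbering, grouped into chains.  All
geometry, surface-area and interface logic in this package operates on these
objects.  Parsing and serialisation of the wwPDB fixed-column format are
delegated to :mod:`biotite.structure.io.pdb`; only protein atoms are kept
(waters and hetero ligands are dropped on read), and for alternate-location
groups the highest-occupancy conformer is retained.

Residue numbering is the author numbering read from the file and is never
rewritten: downstream rules cite residues such as R148 and A219 by exactly
these numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.sequence import ProteinSequence

from .errors import EmptyStructureError, FormatError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueKey",
    "read_structure",
    "write_structure",
    "subset",
    "drop_residue_range",
]

#: (chain_id, seq_number, insertion_code) — unique within a Structure.
ResidueKey = tuple[str, int, str]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: coordinates must be 3 finite values")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    aa: str  # one-letter code, 'X' for non-canonical
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        if not self.residues:
            raise EmptyStructureError(f"structure {self.id!r} has no residues")
        seen: set[ResidueKey] = set()
        for res in self.residues:
            if res.key in seen:
                raise ValueError(f"duplicate residue key {res.key}")
            seen.add(res.key)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for res in self.residues:
            if res.chain_id not in out:
                out.append(res.chain_id)
        return out

    @property
    def atoms(self) -> list[Atom]:
        return [a for res in self.residues for a in res.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues)

    def residue(self, key: ResidueKey | tuple[str, int]) -> Residue:
        """Look up a residue by key; a 2-tuple implies an empty insertion code."""
        if len(key) == 2:
            key = (key[0], key[1], "")
        for res in self.residues:
            if res.key == key:
                return res
        raise KeyError(f"no residue {key} in structure {self.id!r}")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


def _three_to_one(res_name: str) -> str:
    try:
        one = ProteinSequence.convert_letter_3to1(res_name.capitalize())
    except Exception:
        return "X"
    return one if one in CANONICAL_AA else "X"


def _one_to_three(aa: str) -> str:
    if aa not in CANONICAL_AA:
        return "UNK"
    return ProteinSequence.convert_letter_1to3(aa).upper()


def read_structure(path, format: str = "pdb") -> Structure:
    """Read a protein structure from a PDB file.

    Keeps every protein ATOM/HETATM record (waters and other hetero ligands
    are dropped), preserves chain identifiers and author residue numbering,
    and keeps only the highest-occupancy alternate conformer.
    """
    if format != "pdb":
        raise FormatError(f"unsupported format {format!r}; only 'pdb' is supported")
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:  # biotite raises assorted exceptions on bad files
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc

    arr = arr[struc.filter_amino_acids(arr)]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path}: no protein atoms found")

    residues: list[Residue] = []
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for begin, end in zip(starts[:-1], starts[1:]):
        ins = str(arr.ins_code[begin]).strip()
        res = Residue(
            chain_id=str(arr.chain_id[begin]),
            seq_number=int(arr.res_id[begin]),
            insertion_code=ins,
            aa=_three_to_one(str(arr.res_name[begin])),
        )
        for i in range(begin, end):
            res.atoms.append(
                Atom(
                    serial=int(arr.atom_id[i]),
                    name=str(arr.atom_name[i]),
                    element=str(arr.element[i]).capitalize(),
                    coord=arr.coord[i].astype(float),
                    occupancy=float(arr.occupancy[i]),
                )
            )
        residues.append(res)

    import os

    sid = os.path.splitext(os.path.basename(str(path)))[0]
    return Structure(id=sid, residues=residues)


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as a minimal, valid PDB file."""
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.add_annotation("occupancy", dtype=float)
    arr.add_annotation("atom_id", dtype=int)
    i = 0
    for res in structure.residues:
        for atom in res.atoms:
            arr.chain_id[i] = res.chain_id
            arr.res_id[i] = res.seq_number
            arr.ins_code[i] = res.insertion_code
            arr.res_name[i] = _one_to_three(res.aa)
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element.upper()
            arr.hetero[i] = False
            arr.coord[i] = atom.coord
            arr.occupancy[i] = atom.occupancy
            arr.atom_id[i] = atom.serial
            i += 1
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def _copy_residue(res: Residue) -> Residue:
    return Residue(
        chain_id=res.chain_id,
        seq_number=res.seq_number,
        insertion_code=res.insertion_code,
        aa=res.aa,
        atoms=[replace(a, coord=a.coord.copy()) for a in res.atoms],
    )


def subset(
    structure: Structure,
    chains: set[str] | list[str] | str,
    residue_range: tuple[int, int] | None = None,
) -> Structure:
    """Return a new Structure limited to the given chains (and residue range).

    ``residue_range`` is inclusive on both ends and applies to author residue
    numbers in every selected chain.  The input structure is not modified.
    """
    if isinstance(chains, str):
        chains = {chains}
    chains = set(chains)
    present = set(structure.chains)
    unknown = chains - present
    if unknown:
        raise KeyError(f"chain(s) {sorted(unknown)} not in structure (has {sorted(present)})")
    kept = []
    for res in structure.residues:
        if res.chain_id not in chains:
            continue
        if residue_range is not None:
            lo, hi = residue_range
            if not (lo <= res.seq_number <= hi):
                continue
        kept.append(_copy_residue(res))
    if not kept:
        raise EmptyStructureError(
            f"subset of {structure.id!r} (chains {sorted(chains)}, range {residue_range}) is empty"
        )
    return Structure(id=f"{structure.id}_subset", residues=kept)


def drop_residue_range(structure: Structure, chain: str, start: int, end: int) -> Structure:
    """Remove residues ``start..end`` (inclusive) of one chain.

    This is the truncation used to strip a disordered terminus before docking
    (e.g. removing residues 709–851 of a C terminus); residues of other chains
    are untouched.
    """
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not in structure")
    kept = [
        _copy_residue(res)
        for res in structure.residues
        if not (res.chain_id == chain and start <= res.seq_number <= end)
    ]
    if not kept:
        raise EmptyStructureError("truncation removed every residue")
    return Structure(id=f"{structure.id}_trunc", residues=kept)
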