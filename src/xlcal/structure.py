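"""Minimal macromolecular structure model with PDB I/O and geometric queries.

The data model is deliberately small: chains of residues of atoms, with
author numbering preserved verbatim (crosslink positions are stated in
full-protein coordinates, so renumbering would silently corrupt restraint
mapping). Only ATOM records of standard amino acids are modelled; HETATM
records (waters, ligands) are ignored.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "get_atom",
    "atom_distance",
]

# 3-letter codes of the 20 standard amino acids
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class PDBParseError(ValueError):
    """Raised for malformed PDB input; carries the offending line number."""


@dataclass
class Atom:
    """A single atom: label, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue identified by (chain_id, seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def get(self, atom_name: str) -> Optional[Atom]:
        """Return the named atom, None if absent; error on duplicates."""
        hits = [a for a in self.atoms if a.name == atom_name]
        if len(hits) > 1:
            raise ValueError(
                f"residue {self.chain_id}{self.seq_number}: ambiguous atom {atom_name!r} "
                f"({len(hits)} matches after altloc collapse)"
            )
        return hits[0] if hits else None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")


@dataclass
class StructureModel:
    """Chains -> ordered residues -> atoms. The substrate for restraints, RMSD and SASA."""

    model_id: str
    chains: dict[str, list[Residue]]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("StructureModel requires at least one chain")
        for cid, residues in self.chains.items():
            nums = [r.seq_number for r in residues]
            if any(b < a for a, b in zip(nums, nums[1:])):
                raise ValueError(f"chain {cid}: residue seq_numbers must be nondecreasing")

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def get_residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> Optional[Residue]:
        for res in self.chains.get(chain_id, []):
            if res.seq_number == seq_number and res.insertion_code == insertion_code:
                return res
        return None

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain, 'X' for non-standard residues."""
        return "".join(r.one_letter for r in self.chains[chain_id])

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)


def _collapse_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
        elif policy == "highest_occupancy":
            # ties resolve to first in file order (max is stable)
            out.append(max(group, key=lambda a: a.occupancy))
        elif policy == "first":
            out.append(group[0])
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
    return out


def _prescan_pdb(text: str) -> None:
    """Validate ATOM/HETATM coordinate fields so errors carry line numbers."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record truncated ({len(line)} chars)")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparsable coordinate field {line[lo:hi]!r}"
                ) from None


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> StructureModel:
    """Read the first MODEL of a PDB file into a StructureModel.

    HETATM records and non-standard residues are skipped; alternate
    locations are collapsed according to ``altloc_policy``
    (``highest_occupancy`` or ``first``).
    """
    path = Path(path)
    text = path.read_text()
    _prescan_pdb(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    gmodel = st[0]
    chains: dict[str, list[Residue]] = {}
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.het_flag != "A" or gres.name not in STANDARD_AA:
                continue
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=ga.altloc if ga.altloc != "\0" else "",
                    bfactor=ga.b_iso,
                )
                for ga in gres
            ]
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_number=gres.seqid.num,
                    res_name=gres.name,
                    atoms=_collapse_altlocs(atoms, altloc_policy),
                    insertion_code=(gres.seqid.icode or "").strip(),
                )
            )
        if residues:
            chains[gchain.name] = residues
    if not chains:
        raise PDBParseError(f"{path}: no standard-residue ATOM records")
    return StructureModel(model_id=path.stem, chains=chains, source=str(path))


def _format_atom_name(name: str) -> str:
    # Names of <4 chars start in column 14 (single-letter element convention)
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write fixed-column PDB ATOM records (%8.3f coordinates, TER between chains)."""
    if model.n_atoms() == 0:
        raise ValueError("refusing to write a model with no atoms")
    lines = []
    serial = 1
    for chain_id, residues in model.chains.items():
        if len(chain_id) != 1:
            raise ValueError(f"PDB dialect requires 1-character chain ids, got {chain_id!r}")
        last = None
        for res in residues:
            for atom in res.atoms:
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:>5d} {_format_atom_name(atom.name)}{atom.altloc or ' '}"
                    f"{res.res_name:>3s} {chain_id}{res.seq_number:>4d}{res.insertion_code or ' '}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
            last = res
        if last is not None:
            lines.append(
                f"TER   {serial:>5d}      {last.res_name:>3s} {chain_id}{last.seq_number:>4d}"
            )
            serial += 1
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def get_atom(
    model: StructureModel, chain: str, seq_number: int, atom_name: str
) -> Optional[Atom]:
    """Return the unique matching atom or None when chain/residue/atom is absent.

    Absence is data (truncated side chains are common in predicted models),
    so it never raises; only a duplicate atom name after altloc collapse does.
    """
    res = model.get_residue(chain, seq_number)
    if res is None:
        return None
    return res.get(atom_name)


def atom_distance(a: Atom, b: Atom) -> float:
    """Euclidean distance between two atoms in Å."""
    return float(np.linalg.norm(a.coords - b.coords))
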