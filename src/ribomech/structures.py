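"""Hierarchical structure model, PDB input/output, and residue selections.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of chains, each an ordered list of :class:`Residue` objects carrying
:class:`Atom` records (name, position, B-factor, element). Residues are
classified as amino acid, nucleotide, or other, by name against standard
dictionaries with an atom-name fallback for modified nucleosides. Parsing and
writing of the PDB format are delegated to Biopython; this module only adapts
its hierarchy to the flat model the downstream coarse-graining expects.

Selections address residues in author numbering, exactly as structural papers
cite them (e.g. nucleotide A2451 of 23S rRNA). A selection string is a
semicolon- or comma-separated list of terms ``CHAIN``, ``CHAIN:SEQ`` or
``CHAIN:START-END`` with inclusive endpoints; internally ranges are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .errors import SelectionError, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "ResidueClass",
    "Structure",
    "Selection",
    "SelectionTerm",
    "PTC_SEQ_IDS",
    "ptc_selection",
    "read_structure",
    "write_structure",
    "resolve_selection",
]

#: 23S rRNA nucleotides forming the peptidyl transferase center, author numbering.
PTC_SEQ_IDS: tuple[int, ...] = (2451, 2452, 2506, 2585, 2602)

AMINO_ACID_NAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
    TYR VAL MSE SEC PYL""".split()
)

NUCLEOTIDE_NAMES = frozenset(
    """A C G U I N DA DC DG DT DI DU
    PSU H2U 1MA 2MG M2G 7MG 5MU 5MC 4SU OMC OMG OMU 1MG 6MA YG""".split()
)

# Old-style PDB files prime-mark sugar atoms with '*'.
_C4P_ALIASES = ("C4'", "C4*")


class ResidueClass(str, Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"
    OTHER = "other"


@dataclass
class Atom:
    """A single atom: name, Cartesian position (Å), B-factor (Å²), element."""

    name: str
    position: np.ndarray
    bfactor: float = 0.0
    element: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    res_class: ResidueClass
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        """Return the named atom, honouring the C4'/C4* alias, or None."""
        names = _C4P_ALIASES if name in _C4P_ALIASES else (name,)
        for a in self.atoms:
            if a.name in names:
                return a
        return None


def classify_residue(res_name: str, atom_names: Iterable[str] = ()) -> ResidueClass:
    """Classify by residue name; fall back to node-atom content for modified
    nucleosides whose names are not in the dictionary."""
    name = res_name.strip().upper()
    if name in AMINO_ACID_NAMES:
        return ResidueClass.AMINO_ACID
    if name in NUCLEOTIDE_NAMES:
        return ResidueClass.NUCLEOTIDE
    names = set(atom_names)
    if "P" in names and "C2" in names and names.intersection(_C4P_ALIASES):
        return ResidueClass.NUCLEOTIDE
    return ResidueClass.OTHER


@dataclass
class Structure:
    """Ordered chains of residues plus source metadata."""

    chains: list[tuple[str, list[Residue]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain identifiers: {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(chain_id)

    def iter_residues(self) -> Iterator[Residue]:
        for _, residues in self.chains:
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(res) for _, res in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | Sequence[float] | None = None) -> "Structure":
        """Return a rigidly transformed copy (positions x -> R x + t)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        chains = []
        for cid, residues in self.chains:
            new_res = []
            for r in residues:
                atoms = [replace(a, position=R @ a.position + t) for a in r.atoms]
                new_res.append(replace(r, atoms=atoms))
            chains.append((cid, new_res))
        return Structure(chains, metadata=dict(self.metadata))


@dataclass(frozen=True)
class SelectionTerm:
    """One selection term: a whole chain, or a half-open seq-id range on it."""

    chain_id: str
    start: int | None = None
    end: int | None = None  # half-open

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise SelectionError("range term needs both start and end")
        if self.start is not None and self.end <= self.start:
            raise SelectionError(f"empty range [{self.start}, {self.end})")

    def matches(self, residue: Residue) -> bool:
        if residue.chain_id != self.chain_id:
            return False
        if self.start is None:
            return True
        return self.start <= residue.seq_id < self.end

    def __str__(self) -> str:
        if self.start is None:
            return self.chain_id
        if self.end == self.start + 1:
            return f"{self.chain_id}:{self.start}"
        return f"{self.chain_id}:{self.start}-{self.end - 1}"


@dataclass(frozen=True)
class Selection:
    terms: tuple[SelectionTerm, ...]

    @classmethod
    def from_string(cls, text: str) -> "Selection":
        """Parse ``"A:1030-1124; B; C:2451"`` (inclusive endpoints)."""
        terms: list[SelectionTerm] = []
        for raw in text.replace(";", ",").split(","):
            tok = raw.strip()
            if not tok:
                continue
            if ":" not in tok:
                terms.append(SelectionTerm(tok))
                continue
            chain, _, rng = tok.partition(":")
            chain = chain.strip()
            rng = rng.strip()
            if "-" in rng.lstrip("-"):
                lo, _, hi = rng.rpartition("-")
                start, stop = int(lo), int(hi)
            else:
                start = stop = int(rng)
            terms.append(SelectionTerm(chain, start, stop + 1))
        if not terms:
            raise SelectionError(f"no selection terms in {text!r}")
        return cls(tuple(terms))

    @classmethod
    def whole_chains(cls, *chain_ids: str) -> "Selection":
        return cls(tuple(SelectionTerm(cid) for cid in chain_ids))

    @classmethod
    def seq_ids(cls, chain_id: str, ids: Iterable[int]) -> "Selection":
        return cls(tuple(SelectionTerm(chain_id, i, i + 1) for i in ids))

    def resolve(self, structure: Structure) -> tuple[list[Residue], list[SelectionTerm]]:
        """Matched residues in structure order, plus the terms matching nothing."""
        matched: list[Residue] = []
        hit = [False] * len(self.terms)
        for residue in structure.iter_residues():
            for k, term in enumerate(self.terms):
                if term.matches(residue):
                    matched.append(residue)
                    hit[k] = True
                    break
        unmatched = [t for t, h in zip(self.terms, hit) if not h]
        return matched, unmatched

    def __str__(self) -> str:
        return ", ".join(str(t) for t in self.terms)


def ptc_selection(chain_id: str) -> Selection:
    """The five peptidyl-transferase-center nucleotides on the given 23S chain."""
    return Selection.seq_ids(chain_id, PTC_SEQ_IDS)


def resolve_selection(structure: Structure, sel: Selection) -> list[Residue]:
    """Resolve a selection; log unmatched terms; error if nothing matches."""
    matched, unmatched = sel.resolve(structure)
    for term in unmatched:
        logger.warning("selection term %s matched no residues", term)
    if not matched:
        raise SelectionError(f"selection {sel} matched nothing in the structure")
    return matched


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    The first MODEL is used (logged when more exist); the highest-occupancy
    altloc conformer is kept; waters and non-polymer HETATM residues (ions,
    ligands) are dropped. Residues with unrecognized names that still look
    polymeric (ATOM records) are kept with class ``other`` and logged.
    """
    if format != "pdb":
        raise StructureError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        parsed = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Biopython raises assorted types on bad input
        raise StructureError(f"cannot parse {path} as PDB: {exc}") from exc

    models = list(parsed.get_models())
    if not models:
        raise StructureError(f"{path}: no coordinate models")
    if len(models) > 1:
        logger.info("%s: %d models present, using the first", path, len(models))
    model = models[0]

    chains: list[tuple[str, list[Residue]]] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_id, icode = bio_res.id
            if hetflag == "W":
                continue
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child  # highest occupancy
                atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        position=np.array(bio_atom.coord, dtype=float),
                        bfactor=float(bio_atom.bfactor or 0.0),
                        element=(bio_atom.element or "").strip(),
                        occupancy=float(bio_atom.occupancy or 1.0),
                    )
                )
            if not atoms:
                continue
            res_class = classify_residue(bio_res.resname, (a.name for a in atoms))
            if res_class is ResidueClass.OTHER:
                if hetflag != " ":
                    continue  # ion / ligand
                logger.warning(
                    "residue %s %s%d not in dictionaries; kept with class 'other'",
                    bio_res.resname.strip(), bio_chain.id, seq_id,
                )
            residues.append(
                Residue(
                    chain_id=bio_chain.id,
                    seq_id=seq_id,
                    res_name=bio_res.resname.strip(),
                    res_class=res_class,
                    atoms=atoms,
                    icode=icode.strip(),
                )
            )
        if residues:
            chains.append((bio_chain.id, residues))

    if not chains:
        raise StructureError(f"{path}: no polymer residues found")
    return Structure(chains, metadata={"source": str(path), "id": path.stem})


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a PDB file (coordinates to 3 decimals)."""
    if structure.n_residues == 0:
        raise StructureError("refusing to write an empty structure")
    builder = StructureBuilder()
    builder.init_structure(structure.metadata.get("id", "MODL"))
    builder.init_model(0)
    serial = 1
    for chain_id, residues in structure.chains:
        builder.init_chain(chain_id)
        builder.init_seg("    ")
        for res in residues:
            builder.init_residue(res.res_name, " ", res.seq_id, res.icode or " ")
            for atom in res.atoms:
                fullname = atom.name if len(atom.name) >= 4 else (" " + atom.name).ljust(4)
                builder.init_atom(
                    atom.name,
                    atom.position.astype(np.float64),
                    float(atom.bfactor),
                    float(atom.occupancy),
                    " ",
                    fullname,
                    serial_number=serial,
                    element=atom.element or None,
                )
                serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    try:
        io.save(str(path))
    except OSError as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc
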