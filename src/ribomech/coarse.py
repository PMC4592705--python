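"""Mixed-resolution coarse-graining of protein/RNA structures.

Each amino acid contributes one node at its Cα; each nucleotide contributes
three nodes at P (backbone), C4′ (pentose) and C2 (base). Because an average
amino acid weighs ~110 Da and a nucleotide ~330 Da, every node stands for a
nominal 110 Da regardless of chemistry, and the geometric center of a node
set equals its center of mass under this convention.

Node order is deterministic: chains in structure order, residues by position
within the chain, and P < C4′ < C2 within a nucleotide. Residues missing a
mapped atom (e.g. a 5′-terminal nucleotide without P) contribute only the
nodes that exist; no coordinates are synthesized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CoarseGrainError, MissingAtomWarning
from .structures import Residue, ResidueClass, Selection, Structure

logger = logging.getLogger(__name__)

__all__ = ["Node", "NodeSet", "NOMINAL_NODE_MASS", "coarse_grain", "nodes_of",
           "select_node_indices"]

#: Nominal mass represented by every coarse-grained node, Da.
NOMINAL_NODE_MASS = 110.0

#: Node atoms per nucleotide, in emission order.
NUCLEOTIDE_NODE_ATOMS = ("P", "C4'", "C2")


@dataclass(frozen=True)
class Node:
    """One coarse-grained node (a view into a :class:`NodeSet`)."""

    position: np.ndarray
    source: tuple[str, int, str]  # (chain_id, seq_id, atom_name)
    component: str
    nominal_mass: float
    bfactor: float


@dataclass
class NodeSet:
    """Ordered coarse-grained nodes stored as flat arrays."""

    positions: np.ndarray          # (N, 3) Å
    sources: list[tuple[str, int, str]]
    components: list[str]
    bfactors: np.ndarray           # (N,) Å²; NaN when absent
    _component_index: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.bfactors = np.asarray(self.bfactors, dtype=float).reshape(-1)
        if not (len(self.sources) == len(self.components) == self.N == len(self.bfactors)):
            raise CoarseGrainError("inconsistent node array lengths")

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.N

    @property
    def nominal_masses(self) -> np.ndarray:
        return np.full(self.N, NOMINAL_NODE_MASS)

    @property
    def component_index(self) -> dict[str, np.ndarray]:
        if self._component_index is None:
            idx: dict[str, list[int]] = {}
            for i, label in enumerate(self.components):
                idx.setdefault(label, []).append(i)
            self._component_index = {k: np.array(v, dtype=int) for k, v in idx.items()}
        return self._component_index

    def node(self, i: int) -> Node:
        return Node(self.positions[i].copy(), self.sources[i], self.components[i],
                    NOMINAL_NODE_MASS, float(self.bfactors[i]))

    def subset(self, indices: Iterable[int]) -> "NodeSet":
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        return NodeSet(
            self.positions[idx].copy(),
            [self.sources[i] for i in idx],
            [self.components[i] for i in idx],
            self.bfactors[idx].copy(),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "NodeSet":
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return NodeSet(self.positions @ R.T + t, list(self.sources),
                       list(self.components), self.bfactors.copy())

    def to_frame(self) -> pd.DataFrame:
        chains, seqs, atoms = zip(*self.sources) if self.sources else ((), (), ())
        return pd.DataFrame(
            {
                "index": np.arange(self.N),
                "chain": chains,
                "seq_id": seqs,
                "atom": atoms,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "component": self.components,
                "bfactor": self.bfactors,
            }
        )


def _residue_nodes(res: Residue) -> list[tuple[str, np.ndarray, float]]:
    """(atom_name, position, bfactor) tuples this residue maps to."""
    out = []
    if res.res_class is ResidueClass.AMINO_ACID:
        ca = res.atom("CA")
        if ca is None:
            warnings.warn(
                f"amino acid {res.res_name} {res.chain_id}{res.seq_id} lacks CA; skipped",
                MissingAtomWarning, stacklevel=3,
            )
        else:
            out.append(("CA", ca.position, ca.bfactor))
    elif res.res_class is ResidueClass.NUCLEOTIDE:
        for name in NUCLEOTIDE_NODE_ATOMS:
            atom = res.atom(name)
            if atom is None:
                warnings.warn(
                    f"nucleotide {res.res_name} {res.chain_id}{res.seq_id} lacks {name};"
                    " emitting remaining nodes",
                    MissingAtomWarning, stacklevel=3,
                )
            else:
                out.append((name, atom.position, atom.bfactor))
    return out


def coarse_grain(
    structure: Structure,
    component_map: Mapping[str, Selection] | None = None,
    default_component: str = "core",
) -> NodeSet:
    """Map a structure to its node representation.

    ``component_map`` labels residues via selections (label -> Selection);
    overlapping labels are an error; unlabeled residues get
    ``default_component``. Residues of class ``other`` are not mappable and
    are skipped (counted in the log).
    """
    label_of: dict[tuple[str, int, str], str] = {}
    if component_map:
        for label, sel in component_map.items():
            matched, unmatched = sel.resolve(structure)
            for term in unmatched:
                logger.warning("component %r: term %s matched nothing", label, term)
            for res in matched:
                key = (res.chain_id, res.seq_id, res.icode)
                if key in label_of and label_of[key] != label:
                    raise CoarseGrainError(
                        f"residue {key} claimed by both {label_of[key]!r} and {label!r}"
                    )
                label_of[key] = label

    positions: list[np.ndarray] = []
    sources: list[tuple[str, int, str]] = []
    components: list[str] = []
    bfactors: list[float] = []
    n_other = 0
    for res in structure.iter_residues():
        if res.res_class is ResidueClass.OTHER:
            n_other += 1
            continue
        label = label_of.get((res.chain_id, res.seq_id, res.icode), default_component)
        for atom_name, pos, b in _residue_nodes(res):
            positions.append(pos)
            sources.append((res.chain_id, res.seq_id, atom_name))
            components.append(label)
            bfactors.append(b)
    if n_other:
        logger.info("skipped %d residues of class 'other'", n_other)
    if not positions:
        raise CoarseGrainError("structure contains no mappable residues")
    return NodeSet(np.array(positions), sources, components, np.array(bfactors))


def nodes_of(nodeset: NodeSet, component: str) -> np.ndarray:
    """Ascending node indices belonging to a component label."""
    try:
        return nodeset.component_index[component].copy()
    except KeyError:
        raise LookupError(
            f"unknown component {component!r}; have {sorted(nodeset.component_index)}"
        ) from None


def select_node_indices(nodeset: NodeSet, sel: Selection) -> np.ndarray:
    """Node indices whose source residue matches the selection."""
    idx = [
        i
        for i, (chain, seq, _atom) in enumerate(nodeset.sources)
        if any(
            t.chain_id == chain and (t.start is None or t.start <= seq < t.end)
            for t in sel.terms
        )
    ]
    return np.array(idx, dtype=int)
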