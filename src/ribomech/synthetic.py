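"""Seeded synthetic PDB fixtures with analytic ground truth.

Real ribosome coordinate files mix amino-acid chains (Cα present) with
nucleotide chains (P, C2, C4′ present), carry experimental B-factor columns,
and hang asymmetric protein "appendages" (L9 on one side, the L12 stalk on
the other) off a globular rRNA core. The generators here emulate exactly
those structural features on idealized geometry — helical traces and jittered
globular lattices — so that centers of mass, node counts and (on tiny
systems) spectra have known answers. They make no attempt at sequence
realism, base pairing or sterics.

Every generator is a pure function of its seed: the same seed yields
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coarse import NUCLEOTIDE_NODE_ATOMS
from .errors import FixtureError
from .structures import (
    Atom,
    Residue,
    ResidueClass,
    Selection,
    Structure,
    write_structure,
)

__all__ = [
    "Appendage",
    "FixtureSpec",
    "make_toy_protein_chain",
    "make_toy_rna_chain",
    "make_balanced_assembly",
    "write_fixture",
]

_PROTEIN_NAMES = ("ALA", "GLY", "SER", "VAL", "LEU", "THR")
_RNA_NAMES = ("A", "U", "G", "C")


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``direction`` (Rodrigues)."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise FixtureError("zero direction vector")
    d = d / n
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_toy_protein_chain(
    n_residues: int,
    seed: int = 0,
    chain_id: str = "A",
    center: np.ndarray | None = None,
    direction: np.ndarray = (0.0, 0.0, 1.0),
    bfactor: float = 30.0,
    jitter: float = 0.0,
    start_seq: int = 1,
) -> Structure:
    """Cα-only α-helical trace with ~3.8 Å steps, centered at ``center``."""
    if n_residues < 1:
        raise FixtureError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues)
    ang = np.deg2rad(99.6) * t
    pts = np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * t])
    pts = pts - pts.mean(axis=0)
    pts = pts @ _rotation_to(np.asarray(direction)).T
    if center is not None:
        pts = pts + np.asarray(center, dtype=float)
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, pts.shape)
    residues = [
        Residue(
            chain_id, start_seq + i, _PROTEIN_NAMES[i % len(_PROTEIN_NAMES)],
            ResidueClass.AMINO_ACID,
            [Atom("CA", pts[i], bfactor=bfactor, element="C")],
        )
        for i in range(n_residues)
    ]
    return Structure([(chain_id, residues)], metadata={"id": "toyp", "seed": seed})


def make_toy_rna_chain(
    n_nucleotides: int,
    seed: int = 0,
    chain_id: str = "A",
    center: np.ndarray | None = None,
    direction: np.ndarray = (0.0, 0.0, 1.0),
    bfactor: float = 30.0,
    jitter: float = 0.0,
    start_seq: int = 1,
) -> Structure:
    """Helical single-strand RNA trace with P, C4′ and C2 per nucleotide.

    Consecutive P–P separations land near 6 Å (A-form-like), so a 15 Å
    cutoff yields a connected elastic network.
    """
    if n_nucleotides < 1:
        raise FixtureError("n_nucleotides must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_nucleotides)
    theta = np.deg2rad(32.7) * t
    z = 2.81 * t
    e_r = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    e_t = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)])
    e_z = np.array([0.0, 0.0, 1.0])
    p = 9.4 * e_r + z[:, None] * e_z
    c4 = p - 1.2 * e_r + 1.0 * e_t + 0.8 * e_z
    c2 = p - 4.5 * e_r + 0.8 * e_t + 1.2 * e_z
    coords = np.stack([p, c4, c2], axis=1)  # (n, 3 atoms, 3)
    coords = coords - coords.reshape(-1, 3).mean(axis=0)
    coords = coords @ _rotation_to(np.asarray(direction)).T
    if center is not None:
        coords = coords + np.asarray(center, dtype=float)
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    residues = []
    for i in range(n_nucleotides):
        atoms = [
            Atom(name, coords[i, k], bfactor=bfactor,
                 element="P" if name == "P" else "C")
            for k, name in enumerate(NUCLEOTIDE_NODE_ATOMS)
        ]
        residues.append(
            Residue(chain_id, start_seq + i, _RNA_NAMES[i % len(_RNA_NAMES)],
                    ResidueClass.NUCLEOTIDE, atoms)
        )
    return Structure([(chain_id, residues)], metadata={"id": "toyr", "seed": seed})


@dataclass(frozen=True)
class Appendage:
    """A labeled peripheral component hung off the core at a given offset."""

    label: str
    direction: tuple[float, float, float]
    offset: float          # Å from core center; must exceed core radius
    n_residues: int
    chain_type: str = "protein"  # or "rna"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a balanced core+appendages assembly.

    Defaults emulate the 50S mass-balance geometry at toy scale: a globular
    RNA-like core with a central low-B island standing in for the PTC, and
    two equal protein appendages on opposite sides standing in for L9 and
    the outermost L12 dimer.
    """

    seed: int = 0
    core_nucleotides: int = 60
    core_radius: float = 22.0
    appendages: tuple[Appendage, ...] = (
        Appendage("L9", (1.0, 0.0, 0.0), 40.0, 30),
        Appendage("L12", (-1.0, 0.0, 0.0), 40.0, 30),
    )
    bfactor_plan: dict = field(
        default_factory=lambda: {"core": 40.0, "ptc": 8.0, "appendage": 60.0}
    )
    ptc_size: int = 5
    jitter: float = 0.25

    def validate(self) -> None:
        if self.core_nucleotides < self.ptc_size or self.ptc_size < 1:
            raise FixtureError("need at least ptc_size core nucleotides")
        labels = [a.label for a in self.appendages]
        if len(labels) != len(set(labels)) or "core" in labels:
            raise FixtureError("appendage labels must be unique and not 'core'")
        for a in self.appendages:
            if a.offset <= self.core_radius:
                raise FixtureError(
                    f"appendage {a.label!r} offset {a.offset} Å does not clear the"
                    f" core radius {self.core_radius} Å (components would overlap)"
                )
            if a.n_residues < 1 or a.chain_type not in ("protein", "rna"):
                raise FixtureError(f"bad appendage spec {a!r}")


def make_balanced_assembly(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Build the assembly and its closed-form ground truth.

    Ground-truth CMs come from centroid arithmetic on the node-atom
    coordinates the generator placed — wild type as the count-weighted mean
    of component centroids, each deletion as (N·CM − n_c·c_c)/(N − n_c) —
    independently of the coarse-graining/analysis pipeline.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # Globular core: nucleotide anchors quasi-uniform in a ball, each residue
    # carrying P at the anchor and C4'/C2 at short randomized local offsets.
    n = spec.core_nucleotides
    u = rng.random(n)
    radii = spec.core_radius * np.cbrt(u)
    vecs = rng.normal(size=(n, 3))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    anchors = radii[:, None] * vecs
    core_residues = []
    core_coords = []
    # PTC stand-in: the ptc_size anchors closest to the core center.
    order = np.argsort(np.linalg.norm(anchors, axis=1))
    ptc_rows = set(order[: spec.ptc_size].tolist())
    ptc_seq_ids = sorted(int(r) + 1 for r in ptc_rows)
    for i in range(n):
        frame = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        pos = {
            "P": anchors[i],
            "C4'": anchors[i] + 1.8 * frame[0],
            "C2": anchors[i] + 3.4 * frame[1],
        }
        b = spec.bfactor_plan.get("ptc" if i in ptc_rows else "core", 40.0)
        atoms = [
            Atom(name, pos[name] + rng.normal(0.0, spec.jitter, 3), bfactor=b,
                 element="P" if name == "P" else "C")
            for name in NUCLEOTIDE_NODE_ATOMS
        ]
        core_coords.extend(a.position for a in atoms)
        core_residues.append(
            Residue("A", i + 1, _RNA_NAMES[i % len(_RNA_NAMES)],
                    ResidueClass.NUCLEOTIDE, atoms)
        )
    chains = [("A", core_residues)]
    centroids = {"core": np.mean(core_coords, axis=0)}
    counts = {"core": len(core_coords)}

    chain_ids = {}
    b_app_default = spec.bfactor_plan.get("appendage", 60.0)
    for k, app in enumerate(spec.appendages):
        cid = chr(ord("B") + k)
        chain_ids[app.label] = cid
        d = np.asarray(app.direction, dtype=float)
        d /= np.linalg.norm(d)
        center = app.offset * d
        maker = make_toy_protein_chain if app.chain_type == "protein" else make_toy_rna_chain
        sub = maker(
            app.n_residues,
            seed=int(rng.integers(2**31)),
            chain_id=cid,
            center=center,
            direction=d,
            bfactor=spec.bfactor_plan.get(app.label, b_app_default),
            jitter=spec.jitter,
        )
        residues = sub.chain(cid)
        chains.append((cid, residues))
        coords = [a.position for r in residues for a in r.atoms]
        centroids[app.label] = np.mean(coords, axis=0)
        counts[app.label] = len(coords)

    structure = Structure(chains, metadata={"id": "fixture", "seed": spec.seed})

    total = sum(counts.values())
    cm_wt = sum(counts[c] * centroids[c] for c in counts) / total
    deletion_cms = {}
    for app in spec.appendages:
        nl = counts[app.label]
        deletion_cms[app.label] = (total * cm_wt - nl * centroids[app.label]) / (total - nl)
    if len(spec.appendages) >= 2:
        a1, a2 = spec.appendages[0].label, spec.appendages[1].label
        nd = counts[a1] + counts[a2]
        deletion_cms[f"{a1}+{a2}"] = (
            total * cm_wt - counts[a1] * centroids[a1] - counts[a2] * centroids[a2]
        ) / (total - nd)

    ground_truth = {
        "seed": spec.seed,
        "component_centroids": {k: v.tolist() for k, v in centroids.items()},
        "component_node_counts": counts,
        "wild_type_cm": cm_wt.tolist(),
        "deletion_cms": {k: v.tolist() for k, v in deletion_cms.items()},
        "chain_ids": chain_ids,
        "component_map": {label: cid for label, cid in chain_ids.items()},
        "ptc_chain": "A",
        "ptc_seq_ids": ptc_seq_ids,
        "bfactor_plan": dict(spec.bfactor_plan),
    }
    return structure, ground_truth


def component_selections(ground_truth: dict) -> dict[str, Selection]:
    """Label -> whole-chain Selection map recorded in a fixture's ground truth."""
    return {
        label: Selection.whole_chains(cid)
        for label, cid in ground_truth["component_map"].items()
    }


def ptc_selection_of(ground_truth: dict) -> Selection:
    return Selection.seq_ids(ground_truth["ptc_chain"], ground_truth["ptc_seq_ids"])


def write_fixture(structure: Structure, ground_truth: dict, outdir: str | Path,
                  stem: str = "fixture") -> tuple[Path, Path]:
    """Write the PDB (with a seed REMARK) and its sidecar ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_path = outdir / f"{stem}.pdb"
    json_path = outdir / f"{stem}.ground_truth.json"
    write_structure(structure, pdb_path)
    seed = structure.metadata.get("seed", ground_truth.get("seed"))
    body = pdb_path.read_text()
    pdb_path.write_text(f"REMARK 250 RIBOMECH FIXTURE SEED {seed}\n" + body)
    json_path.write_text(json.dumps(ground_truth, indent=2) + "\n")
    return pdb_path, json_path
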