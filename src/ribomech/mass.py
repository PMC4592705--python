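"""Center-of-mass analysis under ribosomal-protein deletions, and PTC rigidity.

With every node representing the same nominal 110 Da, the center of mass of
any node subset is the geometric center of its positions. Deleting a labeled
component (an r-protein such as L9, or an L12 dimer plus the L10 C-terminal
segment it binds) therefore displaces the CM strictly away from the deleted
component's centroid, and deleting two components on opposite sides of the
core partially compensates — the mass-balance logic this module quantifies.

The PTC rigidity summary compares B-factors (experimental, or predicted from
an ANM covariance) of the peptidyl-transferase-center nucleotides against the
whole node set: mean PTC B, overall median B, and the PTC nodes' mid-rank
percentile. For visualization exports, values are clamped to a fixed window
(0–70 Å² by convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coarse import NodeSet, nodes_of, select_node_indices
from .errors import DeletionError, MissingBFactorError, SelectionError
from .structures import Selection

logger = logging.getLogger(__name__)

__all__ = [
    "DeletionSpec",
    "CMEntry",
    "CMReport",
    "PTCSummary",
    "center_of_mass",
    "apply_deletion",
    "cm_shift_report",
    "ptc_rigidity_summary",
]


@dataclass(frozen=True)
class DeletionSpec:
    """A named in-silico deletion: component labels and/or residue selections."""

    name: str
    components: tuple[str, ...] = ()
    selections: tuple[Selection, ...] = ()

    def resolve(self, nodeset: NodeSet) -> np.ndarray:
        """Ascending indices of the nodes this spec removes."""
        idx: set[int] = set()
        for label in self.components:
            idx.update(nodes_of(nodeset, label).tolist())
        for sel in self.selections:
            hit = select_node_indices(nodeset, sel)
            if len(hit) == 0:
                raise DeletionError(f"deletion {self.name!r}: selection {sel} matched no nodes")
            idx.update(hit.tolist())
        return np.array(sorted(idx), dtype=int)


@dataclass
class CMEntry:
    name: str
    cm: np.ndarray
    n_nodes: int
    shift_from_wt: float
    distance_to_ptc: float
    direction_dot: float | None  # (CM_mut−CM_wt)·(c_removed−CM_wt); None for WT


@dataclass
class CMReport:
    entries: list[CMEntry]
    shifts: dict[tuple[str, str], float]
    ptc_centroid: np.ndarray

    def entry(self, name: str) -> CMEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": [e.name for e in self.entries],
                "n_nodes": [e.n_nodes for e in self.entries],
                "cm_x": [e.cm[0] for e in self.entries],
                "cm_y": [e.cm[1] for e in self.entries],
                "cm_z": [e.cm[2] for e in self.entries],
                "shift_from_wt": [e.shift_from_wt for e in self.entries],
                "distance_to_ptc": [e.distance_to_ptc for e in self.entries],
                "direction_dot": [e.direction_dot for e in self.entries],
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ptc_centroid": self.ptc_centroid.tolist(),
            "variants": [
                {
                    "name": e.name,
                    "cm": e.cm.tolist(),
                    "n_nodes": e.n_nodes,
                    "shift_from_wt": e.shift_from_wt,
                    "distance_to_ptc": e.distance_to_ptc,
                    "direction_dot": e.direction_dot,
                }
                for e in self.entries
            ],
            "pairwise_shifts": {f"{a}|{b}": v for (a, b), v in self.shifts.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def center_of_mass(
    nodeset: NodeSet,
    components: Iterable[str] | None = None,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Geometric center of the selected nodes (equal nominal masses).

    ``masses`` switches to a mass-weighted mean for callers supplying true
    per-node masses; with the default uniform convention both agree.
    """
    if components is None:
        idx = np.arange(nodeset.N)
    else:
        parts = [nodes_of(nodeset, c) for c in components]
        idx = np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=int)
    if len(idx) == 0:
        raise SelectionError("center of mass of an empty node selection")
    pos = nodeset.positions[idx]
    if masses is None:
        return pos.mean(axis=0)
    w = np.asarray(masses, dtype=float)[idx]
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def apply_deletion(
    nodeset: NodeSet,
    spec: DeletionSpec,
    protect: np.ndarray | Sequence[int] | None = None,
) -> NodeSet:
    """Return a new NodeSet without the nodes the spec removes.

    ``protect`` lists indices that must survive (the PTC, so that distances
    to it remain measurable); overlap is a refusal error. Node order is
    preserved; the input is untouched.
    """
    removed = spec.resolve(nodeset)
    if protect is not None and len(removed):
        clash = np.intersect1d(removed, np.asarray(protect, dtype=int))
        if len(clash):
            raise DeletionError(
                f"deletion {spec.name!r} would remove {len(clash)} protected (PTC) node(s)"
            )
    keep = np.setdiff1d(np.arange(nodeset.N), removed)
    return nodeset.subset(keep)


def cm_shift_report(
    nodeset: NodeSet,
    variants: Sequence[DeletionSpec],
    ptc: Selection,
    wild_type_name: str = "wild_type",
) -> CMReport:
    """CM positions, pairwise shifts, and PTC distances for deletion variants.

    The PTC centroid is the geometric center of the PTC nucleotides' nodes in
    the wild-type set (deletions never touch it). ``direction_dot`` records
    (CM_mut − CM_wt)·(c_removed − CM_wt); a negative value means the CM moved
    away from the deleted material, as centroid arithmetic demands.
    """
    ptc_idx = select_node_indices(nodeset, ptc)
    if len(ptc_idx) == 0:
        raise SelectionError(f"PTC selection {ptc} matched no nodes")
    ptc_centroid = nodeset.positions[ptc_idx].mean(axis=0)

    cm_wt = center_of_mass(nodeset)
    entries = [
        CMEntry(wild_type_name, cm_wt, nodeset.N, 0.0,
                float(np.linalg.norm(cm_wt - ptc_centroid)), None)
    ]
    cms = {wild_type_name: cm_wt}
    for spec in variants:
        removed = spec.resolve(nodeset)
        mutant = apply_deletion(nodeset, spec, protect=ptc_idx)
        cm = center_of_mass(mutant)
        dot = None
        if len(removed):
            c_removed = nodeset.positions[removed].mean(axis=0)
            dot = float(np.dot(cm - cm_wt, c_removed - cm_wt))
        entries.append(
            CMEntry(
                spec.name,
                cm,
                mutant.N,
                float(np.linalg.norm(cm - cm_wt)),
                float(np.linalg.norm(cm - ptc_centroid)),
                dot,
            )
        )
        cms[spec.name] = cm

    names = list(cms)
    shifts = {
        (a, b): float(np.linalg.norm(cms[a] - cms[b]))
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    return CMReport(entries, shifts, ptc_centroid)


@dataclass
class PTCSummary:
    ptc_mean_b: float
    median_b: float
    ptc_percentile_rank: float   # mid-rank percent, averaged over PTC nodes
    n_ptc_nodes: int
    clamped: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "ptc_mean_b": self.ptc_mean_b,
            "median_b": self.median_b,
            "ptc_percentile_rank": self.ptc_percentile_rank,
            "n_ptc_nodes": self.n_ptc_nodes,
        }


def _midrank_percentile(values: np.ndarray, all_values: np.ndarray) -> float:
    n = len(all_values)
    ranks = [
        (np.count_nonzero(all_values < v) + 0.5 * np.count_nonzero(all_values == v)) / n
        for v in values
    ]
    return 100.0 * float(np.mean(ranks))


def ptc_rigidity_summary(
    nodeset: NodeSet,
    ptc: Selection,
    source: str = "experimental",
    covariance=None,
    bfactors: np.ndarray | None = None,
    clamp: tuple[float, float] = (0.0, 70.0),
    export_clamped: bool = False,
) -> PTCSummary:
    """Is the PTC rigid relative to the rest of the assembly?

    ``source="experimental"`` uses the B-factors carried by the nodes (copied
    from the source atoms); ``source="predicted"`` derives B from a supplied
    ANM :class:`~ribomech.enm.CovarianceMatrix`. The summary reports the mean
    PTC B-factor, the median over all nodes, and the PTC nodes' mid-rank
    percentile (below 50 % means rigid side of the distribution). With
    ``export_clamped`` the per-node values clipped to ``clamp`` are attached
    for color-mapping exports.
    """
    if source == "experimental":
        b = nodeset.bfactors
        if np.any(~np.isfinite(b)):
            raise MissingBFactorError(
                "nodes carry no experimental B-factors; use source='predicted'"
                " with a covariance"
            )
    elif source == "predicted":
        if bfactors is not None:
            b = np.asarray(bfactors, dtype=float)
        elif covariance is not None:
            from .enm import predicted_fluctuations

            _, b = predicted_fluctuations(covariance)
        else:
            raise MissingBFactorError(
                "source='predicted' requires a covariance matrix or a"
                " precomputed B-factor array"
            )
    else:
        raise MissingBFactorError(f"unknown B-factor source {source!r}")

    ptc_idx = select_node_indices(nodeset, ptc)
    if len(ptc_idx) == 0:
        raise SelectionError(f"PTC selection {ptc} matched no nodes")
    clamped = np.clip(b, clamp[0], clamp[1]) if export_clamped else None
    return PTCSummary(
        ptc_mean_b=float(np.mean(b[ptc_idx])),
        median_b=float(np.median(b)),
        ptc_percentile_rank=_midrank_percentile(b[ptc_idx], b),
        n_ptc_nodes=int(len(ptc_idx)),
        clamped=clamped,
    )
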