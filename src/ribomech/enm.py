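"""Anisotropic network model: Hessian, normal modes, thermal covariances.

The elastic energy is harmonic in the pair distances,

    E = γ/2 Σ_{i<j} (R_ij − R⁰_ij)²   for pairs with R⁰_ij < R_c,

with a uniform spring constant γ and a hard distance cutoff R_c (default
15 Å, appropriate for the mixed Cα / P-C4′-C2 node scheme). The 3N×3N
Hessian of this energy has off-diagonal 3×3 blocks −γ û ûᵀ (û the unit
inter-node vector) and diagonal blocks that enforce zero block-row sums, so
six eigenvalues vanish for a connected network — the rigid translations and
rotations. Thermal fluctuations follow from the pseudo-inverse,

    ⟨ΔR ΔRᵀ⟩ = (k_B T / γ) Σ_{k > n_zero} λ_k⁻¹ V_k V_kᵀ,

truncatable to the lowest non-zero modes. Per-node mean-square fluctuations
convert to crystallographic B-factors via B = (8π²/3)⟨Δr²⟩.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .coarse import NodeSet
from .errors import (
    DegenerateGeometryError,
    DisconnectedNetworkWarning,
    InsufficientModesError,
    NumericalError,
    UndefinedCorrelationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ENMParameters",
    "Hessian",
    "ModeSet",
    "CovarianceMatrix",
    "build_hessian",
    "compute_modes",
    "covariance",
    "predicted_fluctuations",
    "mode_fluctuations",
    "cross_correlation",
    "write_nmd",
    "BOLTZMANN_KCAL",
]

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
BOLTZMANN_KCAL = 1.987204259e-3

#: Above this node count the dense full-spectrum path is refused by default.
DENSE_LIMIT = 3000


@dataclass(frozen=True)
class ENMParameters:
    """γ in energy Å⁻² (default 1 kcal mol⁻¹ Å⁻²), cutoff in Å, T in K.

    Mode shapes and relative fluctuations do not depend on γ; absolute
    fluctuation magnitudes carry the k_B T/γ prefactor (Å² with defaults).
    """

    gamma: float = 1.0
    cutoff: float = 15.0
    temperature: float = 300.0
    kB: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def scale(self) -> float:
        """Covariance prefactor k_B T / γ."""
        return self.kB * self.temperature / self.gamma


@dataclass
class Hessian:
    """3N×3N ANM force-constant matrix (sparse CSR) plus its contact list."""

    matrix: sp.csr_matrix
    params: ENMParameters
    N: int
    contacts: np.ndarray  # (n_pairs, 2) node index pairs, i < j

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    @property
    def n_components(self) -> int:
        """Connected components of the contact graph."""
        adj = sp.coo_matrix(
            (np.ones(len(self.contacts)), (self.contacts[:, 0], self.contacts[:, 1])),
            shape=(self.N, self.N),
        )
        n, _ = csgraph.connected_components(adj, directed=False)
        return n


@dataclass
class ModeSet:
    """Ascending eigenvalues, orthonormal eigenvectors, zero-mode count."""

    eigenvalues: np.ndarray    # (m,) ascending
    eigenvectors: np.ndarray   # (3N, m)
    n_zero: int
    params: ENMParameters

    @property
    def frequencies(self) -> np.ndarray:
        """√λ_k, with numerically negative zero-mode values clipped to 0."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def N(self) -> int:
        return self.eigenvectors.shape[0] // 3


@dataclass
class CovarianceMatrix:
    C: np.ndarray              # (3N, 3N)
    scale: float               # k_B T / γ
    modes_used: tuple[int, int]  # half-open eigenvalue-index range

    @property
    def N(self) -> int:
        return self.C.shape[0] // 3


def build_hessian(nodes: NodeSet | np.ndarray, params: ENMParameters | None = None) -> Hessian:
    """Assemble the ANM Hessian for a node set.

    Pairs interact iff their equilibrium separation is strictly below the
    cutoff. Coincident nodes (pair distance ≤ 1e-6 Å) are an error; nodes
    with no contact at the given cutoff trigger a connectivity warning.
    """
    params = params or ENMParameters()
    pos = nodes.positions if isinstance(nodes, NodeSet) else np.asarray(nodes, dtype=float)
    N = pos.shape[0]
    if N < 2:
        raise DegenerateGeometryError("need at least two nodes")

    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=params.cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        if np.any(d <= 1e-6):
            bad = pairs[d <= 1e-6][0]
            raise DegenerateGeometryError(f"nodes {bad[0]} and {bad[1]} coincide")
        keep = d < params.cutoff  # strict Heaviside: R_c − R_ij > 0
        pairs, d = pairs[keep], d[keep]
    else:
        d = np.empty(0)

    degree = np.zeros(N, dtype=int)
    if len(pairs):
        np.add.at(degree, pairs.ravel(), 1)
    if np.any(degree == 0):
        warnings.warn(
            f"{int((degree == 0).sum())} node(s) have no contact within "
            f"{params.cutoff} Å", DisconnectedNetworkWarning, stacklevel=2,
        )

    # Off-diagonal blocks −γ û ûᵀ assembled in COO triplets; diagonal blocks
    # accumulate +γ û ûᵀ so each block row sums to zero.
    npair = len(pairs)
    blocks = np.zeros((npair, 3, 3))
    if npair:
        u = (pos[pairs[:, 1]] - pos[pairs[:, 0]]) / d[:, None]
        blocks = params.gamma * np.einsum("pa,pb->pab", u, u)

    rows, cols, vals = [], [], []
    a3 = np.arange(3)
    off_r = np.repeat(a3, 3)  # 0 0 0 1 1 1 2 2 2
    off_c = np.tile(a3, 3)
    for p in range(npair):
        i, j = pairs[p]
        b = blocks[p].ravel()
        rows.extend((3 * i + off_r, 3 * j + off_r, 3 * i + off_r, 3 * j + off_r))
        cols.extend((3 * j + off_c, 3 * i + off_c, 3 * i + off_c, 3 * j + off_c))
        vals.extend((-b, -b, b, b))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    H = sp.coo_matrix((vals, (rows, cols)), shape=(3 * N, 3 * N)).tocsr()
    return Hessian(H, params, N, pairs.astype(int).reshape(-1, 2))


def _zero_tolerance(eigenvalues: np.ndarray, lam_max: float) -> float:
    return max(1e-8 * lam_max, 1e-10)


def compute_modes(hessian: Hessian, m: int | str = "all") -> ModeSet:
    """Eigendecompose the Hessian; ``m`` is a mode count or ``"all"``.

    Dense full-spectrum decomposition below ``DENSE_LIMIT`` nodes; a
    shift-inverted sparse solver for the lowest ``m`` modes above it. A
    zero-mode count above six raises a disconnected-network warning carrying
    the component count.
    """
    N = hessian.N
    want_all = m == "all"
    if want_all and N > DENSE_LIMIT:
        raise NumericalError(
            f"full spectrum for N={N} nodes exceeds the dense limit; request the"
            " lowest m modes instead"
        )
    try:
        if want_all or N <= DENSE_LIMIT:
            evals, evecs = scipy.linalg.eigh(hessian.toarray())
            if not want_all:
                evals, evecs = evals[: int(m)], evecs[:, : int(m)]
            lam_max = float(evals[-1]) if want_all else float(
                scipy.linalg.eigh(hessian.toarray(), eigvals_only=True,
                                  subset_by_index=[3 * N - 1, 3 * N - 1])[0]
            )
        else:
            k = int(m)
            # H + εI is positive definite, so shift-invert about a small
            # negative sigma is stable even with the six-fold null space.
            evals, evecs = spla.eigsh(hessian.matrix.tocsc(), k=k, sigma=-1e-6,
                                      which="LM", mode="shift-invert")
            order = np.argsort(evals)
            evals, evecs = evals[order], evecs[:, order]
            # Gershgorin upper bound for the zero tolerance reference.
            absH = abs(hessian.matrix)
            lam_max = float((absH.sum(axis=1)).max())
    except (np.linalg.LinAlgError, spla.ArpackError) as exc:
        raise NumericalError(f"eigensolver failed: {exc}") from exc

    tol = _zero_tolerance(evals, lam_max)
    n_zero = int(np.count_nonzero(evals < tol))
    if n_zero > 6:
        warnings.warn(
            f"{n_zero} zero modes: network splits into "
            f"{hessian.n_components} connected components",
            DisconnectedNetworkWarning, stacklevel=2,
        )
    logger.info("modes: %d computed, %d zero (tol %.3g)", len(evals), n_zero, tol)
    return ModeSet(evals, evecs, n_zero, hessian.params)


def covariance(modes: ModeSet, params: ENMParameters | None = None,
               n_modes: int | str = "all") -> CovarianceMatrix:
    """Thermal covariance (k_B T/γ) Σ λ⁻¹ V Vᵀ over non-zero modes.

    ``n_modes`` limits the sum to the lowest non-zero modes (default all
    available). The stored eigenvalues belong to the assembled Hessian and
    carry one factor of γ; the k_B T/γ prefactor multiplies the inverse
    spectrum of the dimensionless contact-topology matrix λ/γ, so on the
    full spectrum C = k_B T · pinv(H) and fluctuations scale as 1/γ.
    """
    params = params or modes.params
    lo = modes.n_zero
    hi = modes.n_modes if n_modes == "all" else min(lo + int(n_modes), modes.n_modes)
    if hi <= lo:
        raise InsufficientModesError("no modes beyond the rigid-body null space")
    lam = modes.eigenvalues[lo:hi] / params.gamma
    V = modes.eigenvectors[:, lo:hi]
    C = params.scale * (V / lam) @ V.T
    return CovarianceMatrix(C, params.scale, (lo, hi))


def predicted_fluctuations(cov: CovarianceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-node ⟨Δr²⟩ (trace of the diagonal 3×3 block) and B = 8π²/3 ⟨Δr²⟩."""
    N = cov.N
    msf = np.einsum("iaia->i", cov.C.reshape(N, 3, N, 3))
    msf = np.maximum(msf, 0.0)  # clip eigensolver round-off
    return msf, (8.0 * np.pi**2 / 3.0) * msf


def mode_fluctuations(modes: ModeSet, params: ENMParameters | None = None,
                      n_modes: int | str = "all") -> tuple[np.ndarray, np.ndarray]:
    """Fluctuations straight from modes, avoiding the dense 3N×3N covariance."""
    params = params or modes.params
    lo = modes.n_zero
    hi = modes.n_modes if n_modes == "all" else min(lo + int(n_modes), modes.n_modes)
    if hi <= lo:
        raise InsufficientModesError("no modes beyond the rigid-body null space")
    V = modes.eigenvectors[:, lo:hi].reshape(modes.N, 3, hi - lo)
    msf = params.scale * np.einsum("nak,nak,k->n", V, V,
                                   params.gamma / modes.eigenvalues[lo:hi])
    return msf, (8.0 * np.pi**2 / 3.0) * msf


def cross_correlation(cov: CovarianceMatrix) -> np.ndarray:
    """Normalized node–node correlation map C_ij/√(C_ii C_jj) in [−1, 1]."""
    N = cov.N
    T = np.einsum("iaja->ij", cov.C.reshape(N, 3, N, 3))
    diag = np.diag(T)
    if np.any(diag <= 0):
        raise UndefinedCorrelationError(
            f"node(s) {np.nonzero(diag <= 0)[0].tolist()} have zero fluctuation"
        )
    M = T / np.sqrt(np.outer(diag, diag))
    return np.clip(M, -1.0, 1.0)


def write_nmd(path: str | Path, nodes: NodeSet, modes: ModeSet,
              n_modes: int = 20, name: str = "ribomech") -> None:
    """Export non-zero modes in NMD format for NMWiz-style viewers.

    Each mode line carries a 1/√λ scale so displayed amplitudes reflect the
    thermal weighting of the mode.
    """
    lo = modes.n_zero
    hi = min(lo + n_modes, modes.n_modes)
    chains, seqs, atoms = zip(*nodes.sources)
    lines = [
        f"nmwiz_load {Path(path).name}",
        f"name {name}",
        "atomnames " + " ".join(a.replace("'", "*") for a in atoms),
        "resids " + " ".join(str(s) for s in seqs),
        "chainids " + " ".join(chains),
        "coordinates " + " ".join(f"{x:.3f}" for x in nodes.positions.ravel()),
    ]
    for k in range(lo, hi):
        scale = 1.0 / np.sqrt(modes.eigenvalues[k])
        vec = " ".join(f"{x:.5f}" for x in modes.eigenvectors[:, k])
        lines.append(f"mode {k - lo + 1} {scale:.5f} {vec}")
    Path(path).write_text("\n".join(lines) + "\n")
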