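"""Independent oracles shared across tests.

The finite-difference Hessian differentiates the pairwise harmonic energy
E = γ/2 Σ_{i<j in contact} (R_ij − R⁰_ij)² numerically, never touching the
analytic assembly it is used to check. Contacts are frozen at the
equilibrium geometry (strictly inside the cutoff), matching the model's
fixed-topology assumption.
"""

from __future__ import annotations

import numpy as np


def contact_pairs(pos0: np.ndarray, cutoff: float) -> list[tuple[int, int, float]]:
    out = []
    n = len(pos0)
    for i in range(n):
        for j in range(i + 1, n):
            d0 = float(np.linalg.norm(pos0[i] - pos0[j]))
            if d0 < cutoff:
                out.append((i, j, d0))
    return out


def anm_energy(flat: np.ndarray, pairs: list[tuple[int, int, float]], gamma: float) -> float:
    pos = flat.reshape(-1, 3)
    e = 0.0
    for i, j, d0 in pairs:
        d = np.linalg.norm(pos[i] - pos[j])
        e += (d - d0) ** 2
    return 0.5 * gamma * e


def fd_hessian(pos0: np.ndarray, gamma: float, cutoff: float, h: float = 1e-5) -> np.ndarray:
    """Central second differences of the elastic energy, O(h²) accurate."""
    pairs = contact_pairs(pos0, cutoff)
    x0 = pos0.ravel().astype(float)
    n = len(x0)
    H = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            xpp = x0.copy(); xpp[a] += h; xpp[b] += h
            xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
            xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
            xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
            val = (
                anm_energy(xpp, pairs, gamma)
                - anm_energy(xpm, pairs, gamma)
                - anm_energy(xmp, pairs, gamma)
                + anm_energy(xmm, pairs, gamma)
            ) / (4 * h * h)
            H[a, b] = H[b, a] = val
    return H


def rigid_body_basis(pos0: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid translations + infinitesimal rotations."""
    n = len(pos0)
    centered = pos0 - pos0.mean(axis=0)
    vecs = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = 1.0
        vecs.append(t.ravel())
    for axis in np.eye(3):
        vecs.append(np.cross(np.broadcast_to(axis, (n, 3)), centered).ravel())
    Q, _ = np.linalg.qr(np.column_stack(vecs))
    return Q


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
    return Q * np.sign(np.diag(R))


def subspace_angle(A: np.ndarray, B: np.ndarray) -> float:
    """Largest principal angle (rad) between the column spaces of A and B."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(np.arccos(np.clip(s.min(), -1.0, 1.0)))
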