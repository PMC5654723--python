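"""Coarse-grained anisotropic elastic network model on C-alpha atoms.

Springs of uniform stiffness connect all C-alpha pairs within a cutoff
(default 10 A).  Eigenpairs of the 3N x 3N Hessian give the normal modes:
modes 1-6 are the zero-frequency rigid-body motions; internal motion starts
at mode 7 (the most facile hinge-type motion for an elongated multi-domain
protein).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = ["ElasticNetwork", "ModeSet", "build_enm", "compute_modes", "mode_overlap",
           "rigid_body_basis", "DisconnectedNetworkError"]

ZERO_MODE_RELATIVE_TOL = 1e-8
_DENSE_LIMIT = 200  # nodes; above this a sparse shift-invert eigensolver is used


class DisconnectedNetworkError(ValueError):
    """The spring network has more than one connected component."""


@dataclass
class ElasticNetwork:
    node_positions: np.ndarray          # (N, 3)
    springs: list[tuple[int, int]]
    cutoff: float
    stiffness: float = 1.0
    node_atom_indices: np.ndarray | None = None  # indices into the source structure

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    def is_connected(self) -> bool:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.springs)
        return nx.is_connected(g) if self.n_nodes else False


@dataclass
class ModeSet:
    eigenvalues: np.ndarray             # ascending
    eigenvectors: np.ndarray            # columns, unit norm, 3N rows
    n_zero: int

    def mode(self, index: int) -> np.ndarray:
        """1-based mode vector; internal modes start at index 7."""
        if index < 1 or index > len(self.eigenvalues):
            raise IndexError(f"mode index {index} out of range 1..{len(self.eigenvalues)}")
        return self.eigenvectors[:, index - 1]

    def internal_mode(self, index: int) -> np.ndarray:
        if index < 7:
            raise ValueError(f"internal modes start at mode 7, got {index}")
        return self.mode(index)


def build_enm(structure: Structure, cutoff: float = 10.0, stiffness: float = 1.0) -> ElasticNetwork:
    """Place a node on every C-alpha and spring all pairs within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if stiffness <= 0:
        raise ValueError("stiffness must be positive")
    ca = structure.ca_indices()
    coords = structure.coords
    if len(ca) < 2:
        raise ValueError("need at least 2 C-alpha atoms for an elastic network")
    pos = coords[ca]
    if len(ca) >= 3 and _collinear(pos):
        raise ValueError("degenerate geometry: all C-alpha atoms are collinear")
    tree = cKDTree(pos)
    springs = sorted(tree.query_pairs(cutoff))
    return ElasticNetwork(pos, springs, cutoff, stiffness, ca)


def _collinear(pos: np.ndarray, tol: float = 1e-8) -> bool:
    centered = pos - pos.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(1.0, s[0])


def _hessian(enm: ElasticNetwork) -> sp.csr_matrix:
    n = enm.n_nodes
    h = sp.lil_matrix((3 * n, 3 * n))
    for i, j in enm.springs:
        d = enm.node_positions[j] - enm.node_positions[i]
        r2 = float(d @ d)
        if r2 == 0:
            raise ValueError(f"coincident nodes {i}, {j}")
        block = enm.stiffness * np.outer(d, d) / r2
        si, sj = 3 * i, 3 * j
        h[si:si + 3, sj:sj + 3] -= block
        h[sj:sj + 3, si:si + 3] -= block
        h[si:si + 3, si:si + 3] += block
        h[sj:sj + 3, sj:sj + 3] += block
    return h.tocsr()


def compute_modes(enm: ElasticNetwork, n_internal: int = 5) -> ModeSet:
    """Lowest eigenpairs of the ENM Hessian, exposing modes 7..6+n_internal.

    Raises :class:`DisconnectedNetworkError` when the network is split
    (extra zero modes would make internal-mode indexing meaningless).
    """
    if n_internal < 1:
        raise ValueError("n_internal must be >= 1")
    if not enm.is_connected():
        raise DisconnectedNetworkError(
            "spring network is disconnected; internal-mode indexing is undefined")
    n = enm.n_nodes
    h = _hessian(enm)
    k = min(3 * n, 6 + n_internal + 4)  # small buffer past the requested modes
    if n <= _DENSE_LIMIT or k >= 3 * n - 1:
        dense = h.toarray()
        vals, vecs = np.linalg.eigh(dense)
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        # shift-invert at a small negative sigma: H + |sigma| I is positive
        # definite, so the factorization never hits the zero eigenvalues
        scale = float(np.mean(h.diagonal()))
        vals, vecs = spla.eigsh(h, k=k, sigma=-1e-3 * scale, which="LM",
                                v0=np.full(3 * n, 1.0 / np.sqrt(3 * n)))
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    vecs = _fix_signs(vecs)
    n_zero = int(np.sum(vals < ZERO_MODE_RELATIVE_TOL * max(vals.max(), 1e-300)))
    return ModeSet(vals, vecs, n_zero)


def _fix_signs(vecs: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    out = vecs.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if len(nz) and col[nz[0]] < 0:
            out[:, c] = -col
    return out


def rigid_body_basis(positions: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N x 6) of rigid translations and rotations."""
    n = len(positions)
    centered = positions - positions.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for ax in range(3):
        basis[ax::3, ax] = 1.0
    for ax, unit in enumerate(np.eye(3)):
        basis[:, 3 + ax] = np.cross(unit, centered).ravel()
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def mode_overlap(mode_vector: np.ndarray, displacement: np.ndarray,
                 positions: np.ndarray | None = None) -> float:
    """Cosine overlap between a mode and a displacement.

    The six rigid-body components of the displacement are projected out
    first (using ``positions`` when given, otherwise the displacement is
    used as-is).  A displacement that vanishes after projection is an error.
    """
    mode_vector = np.asarray(mode_vector, float).ravel()
    displacement = np.asarray(displacement, float).ravel()
    if mode_vector.shape != displacement.shape:
        raise ValueError("mode and displacement dimensions differ")
    disp = displacement.copy()
    if positions is not None:
        basis = rigid_body_basis(np.asarray(positions, float))
        disp -= basis @ (basis.T @ disp)
    norm = np.linalg.norm(disp)
    if norm < 1e-12 * max(1.0, np.linalg.norm(displacement)):
        raise ValueError("displacement is a pure rigid-body motion; overlap undefined")
    return float(np.dot(mode_vector, disp) / (np.linalg.norm(mode_vector) * norm))
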