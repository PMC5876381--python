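"""First-order FEM assembly and solution of the conduction equation.

Solves div(sigma grad u) = 0 with Neumann current injection at electrode
nodes and one grounded reference node, on triangle (2-D) or tetrahedral
(3-D) meshes.  Linear (P1) elements, sparse direct factorisation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


def stiffness_matrix(nodes: np.ndarray, elements: np.ndarray,
                     sigma: np.ndarray) -> sp.csc_matrix:
    """Assemble the P1 stiffness matrix for per-element conductivity."""
    dim = nodes.shape[1]
    pts = nodes[elements]                      # (m, dim+1, dim)
    edges = pts[:, 1:, :] - pts[:, :1, :]      # (m, dim, dim)
    det = np.linalg.det(edges)
    if np.any(np.abs(det) < 1e-14):
        raise ValueError("degenerate element(s) in mesh")
    inv = np.linalg.inv(edges)                 # rows: grads of barycentric 1..dim
    grads = np.empty((len(elements), dim + 1, dim))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    measure = np.abs(det) / (2.0 if dim == 2 else 6.0)
    ke = np.einsum("eid,ejd->eij", grads, grads) * (sigma * measure)[:, None, None]
    nloc = dim + 1
    rows = np.repeat(elements, nloc, axis=1).ravel()
    cols = np.tile(elements, (1, nloc)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(len(nodes), len(nodes))).tocsc()
    return K


def merge_dofs(n_nodes: int, groups: list) -> np.ndarray:
    """DOF map tying each electrode group to a single shunted unknown."""
    dof = np.arange(n_nodes)
    for g in groups:
        g = np.asarray(g)
        dof[g] = g[0]
    # compress to contiguous numbering
    uniq, inv = np.unique(dof, return_inverse=True)
    return inv


class ForwardSystem:
    """Factorised conduction system for one mesh + conductivity map."""

    def __init__(self, mesh, sigma_per_element: np.ndarray,
                 ground_node: int | None = None):
        K = stiffness_matrix(mesh.nodes, mesh.elements, sigma_per_element)
        groups = [np.asarray(g) for g in mesh.electrode_nodes]
        if any(len(g) > 1 for g in groups):
            dof = merge_dofs(len(mesh.nodes), groups)
            n = dof.max() + 1
            P = sp.coo_matrix((np.ones(len(dof)), (np.arange(len(dof)), dof)),
                              shape=(len(dof), n)).tocsc()
            K = (P.T @ K @ P).tocsc()
            self._dof = dof
        else:
            self._dof = np.arange(len(mesh.nodes))
        self.n = K.shape[0]
        self.electrode_dof = np.array([self._dof[g[0]] for g in groups])
        if ground_node is None:
            ground_node = self._pick_ground(mesh)
        self.ground = self._dof[ground_node]
        if self.ground in set(self.electrode_dof.tolist()):
            raise ValueError("ground node collides with an electrode")
        keep = np.ones(self.n, bool)
        keep[self.ground] = False
        self._keep = np.flatnonzero(keep)
        self._lu = splu(K[self._keep][:, self._keep].tocsc())

    @staticmethod
    def _pick_ground(mesh) -> int:
        """Interior node nearest the domain centroid (never an electrode)."""
        centroid = mesh.nodes.mean(axis=0)
        d = np.linalg.norm(mesh.nodes - centroid, axis=1)
        forbidden = set(int(i) for g in mesh.electrode_nodes for i in np.asarray(g))
        for i in np.argsort(d):
            if int(i) not in forbidden:
                return int(i)
        raise ValueError("no admissible ground node")

    def solve_injections(self, injections, current_amp: float) -> np.ndarray:
        """Nodal potentials for each injection pair; shape (n_inj, n_dof)."""
        rhs = np.zeros((self.n, len(injections)))
        for j, (a, b) in enumerate(injections):
            rhs[self.electrode_dof[a], j] += current_amp
            rhs[self.electrode_dof[b], j] -= current_amp
        sol = self._lu.solve(rhs[self._keep])
        u = np.zeros((self.n, len(injections)))
        u[self._keep] = sol
        return u.T

    def electrode_potentials(self, u: np.ndarray) -> np.ndarray:
        """(n_inj, n_electrodes) potentials at the electrode DOFs."""
        return u[:, self.electrode_dof]
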