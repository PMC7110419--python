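"""Linear tetrahedral FEM forward solver for TES and EEG.

Discretizes the quasistatic potential equation div(sigma grad psi) = source
with Neumann boundary conditions on a labelled tet mesh (P1 Galerkin).  The
pure-Neumann null space (constants) is removed by grounding one interior node;
all reported quantities are potential differences or fields, so the choice of
ground is immaterial.

Two source models are supported:

* pointwise electrode currents (TES): the load vector carries the injected
  current at each electrode's attachment node;
* current dipoles (EEG): a partial-integration load on the containing element,
  ``b_j = -m . grad(phi_j)(x0)``.  With this sign convention the EEG lead
  field is exactly the transpose of the TES transfer matrix (reciprocity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import BRAIN, ConductivityMap, ElectrodeSet, HeadMesh, MeshingError

__all__ = [
    "FEMSystem",
    "ForwardSolution",
    "TransferMatrix",
    "LeadField",
    "assemble_fem",
    "solve_forward",
    "build_transfer_matrix",
    "dipole_leadfield",
    "element_gradients",
]

#: relative residual bound enforced on every solve
RESIDUAL_TOL = 1e-8


def element_gradients(mesh: HeadMesh) -> np.ndarray:
    """Gradients of the four barycentric shape functions per element.

    Returns ``B`` of shape (N_H, 3, 4): ``B[e, :, j] = grad(phi_j)`` on
    element ``e`` (constant within the element for P1).
    """
    x = mesh.nodes[mesh.tets]                      # (N, 4, 3)
    d = np.swapaxes(x[:, 1:, :] - x[:, :1, :], 1, 2)  # (N, 3, 3) columns = edges
    dinv = np.linalg.inv(d)                        # lambda_{1..3} = dinv (x - x0)
    g = np.swapaxes(dinv, 1, 2)                    # (N, 3, 3): g[:, :, j] = grad lambda_{j+1}
    g0 = -g.sum(axis=2, keepdims=True)
    return np.concatenate([g0, g], axis=2)


@dataclass
class FEMSystem:
    """Assembled stiffness operator with a grounding strategy.

    ``K`` is the full symmetric P x P stiffness (row sums zero); the reduced
    system with the ground node removed is factorized lazily and reused for
    every right-hand side.
    """

    mesh: HeadMesh
    K: sp.csr_matrix
    ground_node: int
    gradients: np.ndarray = field(repr=False)
    _lu: object | None = field(default=None, repr=False, compare=False)
    _free: np.ndarray | None = field(default=None, repr=False, compare=False)

    def _factorize(self):
        if self._lu is None:
            free = np.ones(self.mesh.n_nodes, dtype=bool)
            free[self.ground_node] = False
            self._free = np.flatnonzero(free)
            K_red = self.K[self._free][:, self._free].tocsc()
            self._lu = splu(K_red)
        return self._lu, self._free

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve K psi = rhs with psi(ground) = 0; enforces the residual bound."""
        lu, free = self._factorize()
        psi = np.zeros(self.mesh.n_nodes)
        psi[free] = lu.solve(rhs[free])
        rnorm = float(np.linalg.norm(rhs))
        if rnorm > 0:
            res = float(np.linalg.norm(self.K @ psi - rhs)) / rnorm
            # the full-system residual includes the (consistent) ground row
            if res > RESIDUAL_TOL:
                raise RuntimeError(
                    f"forward solve residual {res:.2e} exceeds {RESIDUAL_TOL:.0e}; "
                    "the mesh may contain near-degenerate elements"
                )
        return psi


@dataclass
class ForwardSolution:
    """Node potentials (V) and per-element constant fields (V/m)."""

    psi: np.ndarray
    efield: np.ndarray            # (N_sub, 3)
    element_index: np.ndarray     # global tet ids the field rows refer to


@dataclass
class TransferMatrix:
    """Electric-field response per independent electrode injection.

    ``values`` is 3N x (L-1); column ``l`` holds the field over the element
    subset for a unit current (+1 A) at electrode ``l`` returned through the
    reference electrode L.  By superposition ``values @ i`` is the field of
    any independent pattern ``i``.
    """

    values: np.ndarray
    element_index: np.ndarray
    n_electrodes: int

    @property
    def n_elements(self) -> int:
        return self.element_index.size

    def field_of(self, i: np.ndarray) -> np.ndarray:
        """Field (N, 3) produced by independent pattern ``i`` in amperes."""
        return (self.values @ np.asarray(i, dtype=float)).reshape(-1, 3)

    def block(self, n: int) -> np.ndarray:
        """``T_n``: the 3 x (L-1) block of element ``n`` (local index)."""
        return self.values[3 * n: 3 * n + 3]


@dataclass
class LeadField:
    """EEG lead field: (L-1) x 3N potentials per unit dipole, vs. reference."""

    values: np.ndarray
    element_index: np.ndarray
    dipole_scale: float = 1.0  # A.m per unit entry


def assemble_fem(mesh: HeadMesh, cond: ConductivityMap, ground_node: int | None = None) -> FEMSystem:
    """Assemble the P1 Galerkin stiffness matrix ``K`` (symmetric, sparse).

    ``K_e = sigma_e V_e B_e^T B_e`` per element; row sums vanish before
    grounding (constants are the pure-Neumann null space).  ``ground_node``
    defaults to the node nearest the mesh centroid.
    """
    if cond.tensors is not None:
        raise NotImplementedError("this solver is isotropic; per-element tensors are not supported")
    mesh.orient_positively()
    vol = mesh.element_volumes()
    bad = np.flatnonzero(vol <= 0)
    if bad.size:
        raise MeshingError(f"inverted/degenerate elements: {bad[:10].tolist()}")
    sigma = cond.per_element(mesh)
    B = element_gradients(mesh)                       # (N, 3, 4)
    Ke = np.einsum("e,e,eki,ekj->eij", sigma, vol, B, B, optimize=True)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    if ground_node is None:
        center = mesh.nodes.mean(axis=0)
        ground_node = int(np.argmin(np.linalg.norm(mesh.nodes - center, axis=1)))
    return FEMSystem(mesh=mesh, K=K, ground_node=ground_node, gradients=B)


def _expanded_rhs(sys: FEMSystem, electrodes: ElectrodeSet, pattern: np.ndarray) -> np.ndarray:
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (electrodes.n_electrodes,):
        raise ValueError(
            f"expanded pattern must have length L={electrodes.n_electrodes}, got {pattern.shape}"
        )
    tot = float(abs(pattern.sum()))
    scale = float(np.abs(pattern).sum())
    if scale > 0 and tot > 1e-12 * scale:
        raise ValueError(f"net injected current {pattern.sum():.3e} A violates Kirchhoff's law")
    rhs = np.zeros(sys.mesh.n_nodes)
    np.add.at(rhs, electrodes.nodes, pattern)
    return rhs


def solve_forward(
    sys: FEMSystem,
    electrodes: ElectrodeSet,
    pattern: np.ndarray,
    element_subset: np.ndarray | None = None,
) -> ForwardSolution:
    """Solve the TES forward problem for an expanded pattern (amperes, sums to 0)."""
    rhs = _expanded_rhs(sys, electrodes, pattern)
    psi = sys.solve(rhs)
    if element_subset is None:
        element_subset = np.arange(sys.mesh.n_elements)
    element_subset = np.asarray(element_subset, dtype=np.int64)
    E = -np.einsum("ekj,ej->ek", sys.gradients[element_subset], psi[sys.mesh.tets[element_subset]])
    return ForwardSolution(psi=psi, efield=E, element_index=element_subset)


def build_transfer_matrix(
    sys: FEMSystem, electrodes: ElectrodeSet, element_subset: np.ndarray
) -> TransferMatrix:
    """Assemble T (3N x L-1) with L-1 forward solves, one per basis pattern."""
    element_subset = np.asarray(element_subset, dtype=np.int64)
    if element_subset.size == 0:
        raise ValueError("element subset is empty")
    if np.any(sys.mesh.labels[element_subset] != BRAIN):
        warnings.warn("transfer-matrix subset includes elements outside the brain compartment")
    L = electrodes.n_electrodes
    T = np.empty((3 * element_subset.size, L - 1))
    for l in range(L - 1):
        pattern = np.zeros(L)
        pattern[l], pattern[-1] = 1.0, -1.0
        sol = solve_forward(sys, electrodes, pattern, element_subset)
        T[:, l] = sol.efield.ravel()
    return TransferMatrix(values=T, element_index=element_subset, n_electrodes=L)


def dipole_leadfield(
    sys: FEMSystem, electrodes: ElectrodeSet, element_subset: np.ndarray
) -> LeadField:
    """EEG lead field by per-dipole forward solves (3 per element).

    For each subset element a unit dipole is placed at its centroid along each
    canonical axis; the partial-integration load over the element's nodes is
    ``b_j = -m . grad(phi_j)``, and electrode potentials are read relative to
    the reference electrode.  This is the independent route used to check
    reciprocity against :func:`build_transfer_matrix`.
    """
    element_subset = np.asarray(element_subset, dtype=np.int64)
    L = electrodes.n_electrodes
    lead = np.empty((L - 1, 3 * element_subset.size))
    elec_nodes, ref_node = electrodes.nodes[:-1], electrodes.nodes[-1]
    for col, e in enumerate(element_subset):
        tet_nodes = sys.mesh.tets[e]
        if sys.ground_node in tet_nodes:
            warnings.warn(f"dipole element {int(e)} touches the ground node")
        B = sys.gradients[e]                          # (3, 4)
        for k in range(3):
            rhs = np.zeros(sys.mesh.n_nodes)
            rhs[tet_nodes] = -B[k]                    # b_j = -e_k . grad(phi_j)
            psi = sys.solve(rhs)
            lead[:, 3 * col + k] = psi[elec_nodes] - psi[ref_node]
    return LeadField(values=lead, element_index=element_subset)
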