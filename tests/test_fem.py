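"""FEM assembly, forward solves, transfer matrix, lead field, reciprocity."""

import numpy as np
import pytest

from tesopt import (
    BRAIN,
    ConductivityMap,
    HeadMesh,
    assemble_fem,
    build_transfer_matrix,
    dipole_leadfield,
    solve_forward,
)
from tesopt.fem import element_gradients


def _single_tet_mesh():
    nodes = np.array(
        [[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0], [0, 0, 1e-3]], dtype=float
    )
    return HeadMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]]), labels=np.array([BRAIN]))


def test_stiffness_annihilates_constants():
    mesh = _single_tet_mesh()
    sigma = ConductivityMap(values={BRAIN: 1.0, 2: 1.79, 3: 0.006, 4: 0.3})
    system = assemble_fem(mesh, sigma)
    K = system.K.toarray()
    assert np.allclose(K, K.T)
    assert np.allclose(K @ np.ones(4), 0.0, atol=1e-18)


def test_stiffness_linear_in_sigma(head32):
    mesh, _, _, _ = head32
    base = ConductivityMap()
    doubled = ConductivityMap(values={k: 2 * v for k, v in base.values.items()})
    K1 = assemble_fem(mesh, base).K
    K2 = assemble_fem(mesh, doubled).K
    assert abs(K2 - 2 * K1).max() < 1e-12 * abs(K1).max()


def test_gradients_reproduce_linear_field():
    mesh = _single_tet_mesh()
    B = element_gradients(mesh)  # (1, 3, 4)
    coeffs = np.array([1.0, 2.0, -3.0])
    psi = mesh.nodes @ coeffs  # linear potential
    grad = B[0] @ psi[mesh.tets[0]]
    assert np.allclose(grad, coeffs, atol=1e-12)


def test_zero_pattern_zero_solution(head32):
    mesh, electrodes, system, _ = head32
    sol = solve_forward(system, electrodes, np.zeros(electrodes.n_electrodes))
    assert np.allclose(sol.psi, 0.0)
    assert np.allclose(sol.efield, 0.0)


def test_linearity_scaling(head32):
    mesh, electrodes, system, _ = head32
    L = electrodes.n_electrodes
    pattern = np.zeros(L)
    pattern[0], pattern[-1] = 1e-3, -1e-3
    s1 = solve_forward(system, electrodes, pattern)
    s2 = solve_forward(system, electrodes, 2 * pattern)
    assert np.allclose(s2.psi, 2 * s1.psi, rtol=0, atol=1e-12 * np.abs(s1.psi).max())


def test_nonzero_net_current_rejected(head32):
    _, electrodes, system, _ = head32
    bad = np.zeros(electrodes.n_electrodes)
    bad[0] = 1e-3
    with pytest.raises(ValueError):
        solve_forward(system, electrodes, bad)


def test_residual_bound(head32):
    mesh, electrodes, system, _ = head32
    L = electrodes.n_electrodes
    pattern = np.zeros(L)
    pattern[3], pattern[-1] = 2e-3, -2e-3
    sol = solve_forward(system, electrodes, pattern)
    # rebuild the load and check the residual directly
    u = np.zeros(mesh.n_nodes)
    u[electrodes.nodes] = pattern
    r = system.K @ sol.psi - u
    assert np.linalg.norm(r) <= 1e-8 * np.linalg.norm(u)


def test_transfer_superposition(head32):
    """Field of the (e_a - e_b) pair equals column_a - column_b."""
    mesh, electrodes, system, T = head32
    L = electrodes.n_electrodes
    a, b = 2, 5
    pattern = np.zeros(L)
    pattern[a], pattern[b] = 1.0, -1.0
    sol = solve_forward(system, electrodes, pattern, element_subset=T.element_index)
    expect = T.values[:, a] - T.values[:, b]
    got = sol.efield.reshape(-1)
    assert np.linalg.norm(got - expect) <= 1e-9 * np.linalg.norm(expect)


def test_transfer_linearity(head32):
    _, _, _, T = head32
    rng = np.random.default_rng(0)
    i = rng.normal(size=T.n_electrodes - 1) * 1e-3
    F = T.field_of(i)
    assert F.shape == (T.n_elements, 3)
    assert np.allclose(F.reshape(-1), T.values @ i)


def test_reciprocity_lead_field_equals_transfer_transpose(head32):
    """max|L - T'| / max|T| small on a random brain-element subset."""
    mesh, electrodes, system, T = head32
    rng = np.random.default_rng(1)
    subset = np.sort(rng.choice(T.element_index, size=24, replace=False))
    lead = dipole_leadfield(system, electrodes, subset)
    assert lead.values.shape == (T.n_electrodes - 1, 3 * subset.size)
    cols = np.searchsorted(T.element_index, subset)
    pick = np.concatenate([[3 * c, 3 * c + 1, 3 * c + 2] for c in cols])
    diff = np.abs(lead.values - T.values[pick, :].T).max()
    assert diff <= 1e-6 * np.abs(T.values).max()
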