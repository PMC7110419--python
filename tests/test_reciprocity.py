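"""Reciprocity closed forms: one-to-one and per-electrode-limited montages."""

import itertools

import numpy as np
import pytest

from tesopt import (
    ConstraintSet,
    expansion_matrix,
    reciprocity_limited,
    reciprocity_one_to_one,
    synthetic_potential,
)
from tesopt._solvers import solve_lp

I_MAX = 1e-3


@pytest.fixture(scope="module")
def phi32(head32, prob32):
    _, _, _, T = head32
    target, weights = prob32
    return synthetic_potential(T, weights, target.d)


def test_one_to_one_structure(phi32):
    rec = reciprocity_one_to_one(phi32, I_MAX)
    i_exp = rec.i_expanded
    nz = np.flatnonzero(np.abs(i_exp) > 0)
    assert nz.size == 2
    assert np.isclose(i_exp[nz].max(), I_MAX)
    assert np.isclose(i_exp[nz].min(), -I_MAX)
    phi_exp = phi32.phi_expanded
    assert np.isclose(rec.objective, I_MAX * (phi_exp.max() - phi_exp.min()))


def test_one_to_one_matches_brute_force_pairs(phi32):
    """Exhaustive enumeration of all source/sink pairs at +/- i_max."""
    phi_exp = phi32.phi_expanded
    L = phi_exp.size
    best, best_pair = -np.inf, None
    for a, b in itertools.permutations(range(L), 2):
        val = I_MAX * (phi_exp[a] - phi_exp[b])
        if val > best:
            best, best_pair = val, (a, b)
    rec = reciprocity_one_to_one(phi32, I_MAX)
    i_exp = rec.i_expanded
    assert np.isclose(rec.objective, best)
    assert i_exp[best_pair[0]] == I_MAX and i_exp[best_pair[1]] == -I_MAX


def test_limited_2_source_20_sink_structure(phi32):
    """i_max = 1 mA with +i_max/2 source and i_max/20 sink limits."""
    rec = reciprocity_limited(phi32, I_MAX, I_MAX / 2, I_MAX / 20)
    i_exp = rec.i_expanded
    sources = np.flatnonzero(i_exp > 1e-15)
    sinks = np.flatnonzero(i_exp < -1e-15)
    assert sources.size == 2 and sinks.size == 20
    assert np.allclose(i_exp[sources], I_MAX / 2)
    assert np.allclose(i_exp[sinks], -I_MAX / 20)
    assert np.isclose(np.abs(i_exp).sum(), 2 * I_MAX)
    # sources sit at the largest potentials, sinks at the smallest
    phi_exp = phi32.phi_expanded
    assert phi_exp[sources].min() >= np.sort(phi_exp)[-2] - 1e-15
    assert phi_exp[sinks].max() <= np.sort(phi_exp)[19] + 1e-15


def test_limited_matches_convex_solve(phi32):
    """The closed form attains the LP optimum of the boxed problem."""
    L = phi32.phi.size + 1
    for c_src, c_snk in ((I_MAX / 2, I_MAX / 20), (I_MAX / 3.7, I_MAX / 9.3)):
        rec = reciprocity_limited(phi32, I_MAX, c_src, c_snk)
        H = expansion_matrix(L)
        lo = np.full(L, -c_snk)
        hi = np.full(L, c_src)
        x = solve_lp(phi32.phi, H, 2 * I_MAX, lo, hi)
        lp_obj = float(phi32.phi @ x)
        assert rec.objective <= lp_obj * (1 + 1e-12)
        assert rec.objective >= lp_obj * (1 - 1e-12)


def test_limited_fractional_remainder(phi32):
    """Budget not divisible by the limit => one partially loaded electrode."""
    c = I_MAX / 2.5  # 2.5 sources worth of budget
    rec = reciprocity_limited(phi32, I_MAX, c, c)
    i_exp = rec.i_expanded
    sources = i_exp[i_exp > 1e-15]
    assert sources.size == 3
    assert np.isclose(np.sort(sources)[0], 0.5 * c)
    assert np.allclose(np.sort(sources)[1:], c)


def test_limited_infeasible_rejected(phi32):
    L = phi32.phi.size + 1
    # would need more electrodes than exist
    with pytest.raises(ValueError):
        reciprocity_limited(phi32, I_MAX, I_MAX / L, I_MAX / L)


def test_reciprocity_via_transfer_equals_leadfield_route(head32, prob32):
    """Phi from the transfer matrix (reciprocity) equals Phi from explicit
    dipole solves.  d vanishes off the ROI, so the lead field is only needed
    on the ROI columns."""
    from tesopt import dipole_leadfield

    mesh, electrodes, system, T = head32
    target, weights = prob32
    phi_T = synthetic_potential(T, weights, target.d)
    roi_elements = T.element_index[target.roi_local]
    lead = dipole_leadfield(system, electrodes, roi_elements)
    roi_rows = np.concatenate(
        [[3 * k, 3 * k + 1, 3 * k + 2] for k in target.roi_local]
    )
    gd = (weights.gamma * target.d)[roi_rows]
    phi_L = lead.values @ gd
    denom = np.abs(phi_T.phi).max()
    assert np.abs(phi_T.phi - phi_L).max() <= 1e-6 * denom
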