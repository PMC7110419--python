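"""Directional maximization: limit cases, equivalences, constraint activity."""

import numpy as np
import pytest

from tesopt import (
    ConstraintSet,
    constrained_wls,
    dirmax,
    reciprocity_one_to_one,
    synthetic_potential,
    wls_closed_form,
)
from tesopt.optimize import _energy_matrix, _objective_vector

I_MAX = 1e-3


@pytest.fixture(scope="module")
def ingredients32(head32, prob32):
    _, _, _, T = head32
    target, weights = prob32
    A = _energy_matrix(T, weights.gamma_nonroi)
    b = _objective_vector(T, weights, target.d)
    rec = reciprocity_one_to_one(synthetic_potential(T, weights, target.d), I_MAX)
    return T, target, weights, A, b, rec


def test_low_alpha_matches_wls_closed_form(ingredients32):
    """Budget slack => the energy bound alone shapes the optimum (closed form)."""
    T, target, weights, A, b, rec = ingredients32
    shape = wls_closed_form(T, weights, target, k=1.0)
    # alpha chosen so the closed form uses ~30% of the budget
    scale = 0.3 * 2 * I_MAX / shape.used_budget
    alpha = float(shape.i @ A @ shape.i) * scale**2
    cf = wls_closed_form(T, weights, target, alpha_I=alpha)
    dm = dirmax(T, weights, target, ConstraintSet(i_max=I_MAX, alpha_I=alpha))
    assert np.linalg.norm(dm.i - cf.i) <= 1e-3 * np.linalg.norm(cf.i)
    assert np.isclose(float(dm.i @ A @ dm.i), alpha, rtol=1e-4)
    assert dm.active_constraints["nonroi"] and not dm.active_constraints["budget"]


def test_high_alpha_matches_reciprocity(ingredients32):
    """Energy bound slack => LP vertex == two-electrode reciprocity montage."""
    T, target, weights, A, b, rec = ingredients32
    alpha = float(rec.i @ A @ rec.i) * 25.0
    dm = dirmax(T, weights, target, ConstraintSet(i_max=I_MAX, alpha_I=alpha))
    assert np.array_equal(np.flatnonzero(np.abs(dm.i_expanded) > 1e-12),
                          np.flatnonzero(np.abs(rec.i_expanded) > 1e-12))
    assert np.abs(dm.i_expanded - rec.i_expanded).max() <= 1e-6 * I_MAX
    assert not dm.active_constraints["nonroi"]


def test_mid_alpha_dominates_feasible_wls(ingredients32):
    T, target, weights, A, b, rec = ingredients32
    shape = wls_closed_form(T, weights, target, k=1.0)
    a_lo = float(shape.i @ A @ shape.i) * (0.3 * 2 * I_MAX / shape.used_budget) ** 2
    a_hi = float(rec.i @ A @ rec.i)
    alpha = float(np.sqrt(a_lo * a_hi))
    dm = dirmax(T, weights, target, ConstraintSet(i_max=I_MAX, alpha_I=alpha))
    cf = wls_closed_form(T, weights, target, alpha_I=alpha)
    cfi = cf.i * min(1.0, 2 * I_MAX / cf.used_budget)
    assert b @ dm.i >= b @ cfi * (1 - 1e-6)
    assert float(dm.i @ A @ dm.i) <= alpha * (1 + 1e-6)
    assert dm.used_budget <= 2 * I_MAX * (1 + 1e-6)


def test_monotone_objective_in_alpha(ingredients32):
    T, target, weights, A, b, rec = ingredients32
    a_hi = float(rec.i @ A @ rec.i)
    objectives = []
    for alpha in np.geomspace(a_hi / 300, a_hi * 3, 6):
        dm = dirmax(T, weights, target, ConstraintSet(i_max=I_MAX, alpha_I=alpha))
        objectives.append(dm.objective)
    diffs = np.diff(objectives)
    assert np.all(diffs >= -1e-6 * np.abs(objectives[0]))


def test_equivalence_constrained_wls_vs_dirmax(head64, prob64_approx):
    """Solving the constrained WLS, reading off its non-ROI exposure alpha',
    and re-solving the directional maximization at alpha' reproduces the same
    montage (the two formulations share KKT systems).  Needs the shared
    quadratic form, hence approximate weights."""
    _, _, _, T = head64
    target, weights = prob64_approx
    A = _energy_matrix(T, weights.gamma_nonroi)
    cs = ConstraintSet(i_max=2e-3)
    k = 50.0  # strong pull: budget active
    i_wls = constrained_wls(T, weights, target, k, cs).i
    alpha_prime = float(i_wls @ A @ i_wls)
    i_dm = dirmax(T, weights, target,
                  ConstraintSet(i_max=2e-3, alpha_I=alpha_prime)).i
    assert np.linalg.norm(i_dm - i_wls) <= 1e-3 * np.linalg.norm(i_wls)


def test_equivalence_with_box_limits(head64, prob64_approx):
    """Same equivalence with per-electrode box limits engaged."""
    _, _, _, T = head64
    target, weights = prob64_approx
    A = _energy_matrix(T, weights.gamma_nonroi)
    L = T.n_electrodes
    box = 0.4e-3
    cs = ConstraintSet(
        i_max=2e-3,
        i_min_vec=np.full(L, -box),
        i_max_vec=np.full(L, box),
    )
    k = 50.0
    sol = constrained_wls(T, weights, target, k, cs)
    assert np.abs(sol.i_expanded).max() <= box * (1 + 1e-6)
    alpha_prime = float(sol.i @ A @ sol.i)
    i_dm = dirmax(
        T,
        weights,
        target,
        ConstraintSet(
            i_max=2e-3,
            alpha_I=alpha_prime,
            i_min_vec=np.full(L, -box),
            i_max_vec=np.full(L, box),
        ),
    ).i
    assert np.linalg.norm(i_dm - sol.i) <= 1e-3 * np.linalg.norm(sol.i)


def test_elementwise_bound_tight_budget_slack(head32, prob32):
    _, _, _, T = head32
    target, weights = prob32
    rec = reciprocity_one_to_one(synthetic_potential(T, weights, target.d), I_MAX)
    peak_rec = float(
        np.linalg.norm(T.field_of(rec.i), axis=1)[weights.nonroi_mask_elements].max()
    )
    alpha_E = peak_rec / 30.0
    dm = dirmax(
        T, weights, target, ConstraintSet(i_max=I_MAX, alpha_E=alpha_E),
        nonroi_mode="elementwise",
    )
    norms = np.linalg.norm(T.field_of(dm.i), axis=1)[weights.nonroi_mask_elements]
    assert norms.max() <= alpha_E * (1 + 1e-4)
    assert norms.max() >= alpha_E * (1 - 1e-3)  # bound binds
    assert dm.used_budget < 2 * I_MAX * 0.995  # budget slack at low alpha


def test_elementwise_high_alpha_matches_reciprocity(head32, prob32):
    _, _, _, T = head32
    target, weights = prob32
    rec = reciprocity_one_to_one(synthetic_potential(T, weights, target.d), I_MAX)
    peak_rec = float(
        np.linalg.norm(T.field_of(rec.i), axis=1)[weights.nonroi_mask_elements].max()
    )
    dm = dirmax(
        T, weights, target, ConstraintSet(i_max=I_MAX, alpha_E=peak_rec * 10),
        nonroi_mode="elementwise",
    )
    assert np.abs(dm.i_expanded - rec.i_expanded).max() <= 1e-9 * I_MAX
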