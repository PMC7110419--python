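"""The unified family of TES montage optimizers.

All methods maximize (or serve) the directional intensity d' Gamma T i over
the ROI under safety constraints, and differ in which constraints are active:

* :func:`wls_closed_form` — the low-alpha limit: energy-constrained
  maximization, solved in closed form; identical to the weighted-least-
  squares solution with desired field k d.
* :func:`scaled_wls` — the closed-form direction rescaled to exhaust the
  current budget exactly (the solution at the first critical point of the
  intensity-focality trade-off).
* :func:`constrained_wls` — WLS with l1 budget and per-electrode box limits
  (a linearly constrained QP).
* :func:`dirmax` — the full constrained directional maximization (a QCLP):
  linear objective, non-ROI bound (energy integral or per-element), budget
  and box limits.
* :func:`reciprocity_one_to_one` / :func:`reciprocity_limited` — the
  high-alpha limit: closed forms reading off the extrema of the synthetic
  EEG potential of a dipole field at the target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._solvers import SolverError, solve_lcqp, solve_qclp
from .fem import LeadField, TransferMatrix
from .problem import ConstraintSet, TargetSpec, VolumeWeights, expand_pattern, expansion_matrix

__all__ = [
    "Optimum",
    "SyntheticPotential",
    "wls_closed_form",
    "scaled_wls",
    "constrained_wls",
    "dirmax",
    "synthetic_potential",
    "reciprocity_one_to_one",
    "reciprocity_limited",
]

logger = logging.getLogger(__name__)

#: constraints tighter than this fraction of their bound are flagged active
ACTIVE_TOL = 1e-4


@dataclass
class Optimum:
    """A solved montage: independent + expanded pattern and diagnostics."""

    i: np.ndarray                 # (L-1,) independent pattern, A
    objective: float              # d' Gamma T i, in V/m * m^3
    k_scale: float | None = None  # V/m, for closed-form WLS solutions
    active_constraints: dict = field(default_factory=dict)
    status: str = "optimal"

    @property
    def i_expanded(self) -> np.ndarray:
        return expand_pattern(self.i)

    @property
    def used_budget(self) -> float:
        """l1 norm of the expanded pattern in amperes."""
        return float(np.abs(self.i_expanded).sum())


@dataclass
class SyntheticPotential:
    """EEG potential at the electrodes of the dipole field s * Gamma d."""

    phi: np.ndarray           # (L-1,) relative to the reference electrode
    dipole_scale: float       # s, in A.m/m^3

    @property
    def phi_expanded(self) -> np.ndarray:
        """All-electrode potential with 0 at the reference."""
        return np.concatenate([self.phi, [0.0]])


# ---------------------------------------------------------------------------
# shared ingredients
# ---------------------------------------------------------------------------

def _objective_vector(T: TransferMatrix, weights: VolumeWeights, d: np.ndarray) -> np.ndarray:
    """c = T' Gamma d, so the maximized functional is c . i."""
    return T.values.T @ (weights.gamma * d)


def _energy_matrix(T: TransferMatrix, gamma_vec: np.ndarray) -> np.ndarray:
    """A = T' diag(gamma_vec) T (the non-ROI energy quadratic form)."""
    return T.values.T @ (gamma_vec[:, None] * T.values)


def _solve_spd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return scipy.linalg.solve(A, b, assume_a="pos")
    except scipy.linalg.LinAlgError:
        warnings.warn("normal-equation matrix is rank deficient; using a pseudo-inverse")
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _flags(i: np.ndarray, constraints: ConstraintSet, energy: float | None = None,
           alpha: float | None = None) -> dict:
    i_exp = expand_pattern(i)
    L = i_exp.size
    lo, hi = constraints.box(L)
    used = float(np.abs(i_exp).sum())
    flags = {
        "budget": used >= 2 * constraints.i_max * (1 - ACTIVE_TOL),
        "box": bool(np.any(i_exp >= hi - ACTIVE_TOL * constraints.i_max)
                    or np.any(i_exp <= lo + ACTIVE_TOL * constraints.i_max)),
    }
    if energy is not None and alpha is not None:
        flags["nonroi"] = energy >= alpha * (1 - 1e-4)
    return flags


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def wls_closed_form(
    T: TransferMatrix,
    weights: VolumeWeights,
    target: TargetSpec,
    alpha_I: float | None = None,
    k: float | None = None,
) -> Optimum:
    """Closed-form (W)LS solution, the low-alpha limit of directional maximization.

    ``i = (T' Gamma_nonROI T)^-1 T' Gamma d * k``; given ``alpha_I`` the scale
    is ``k = sqrt(alpha_I / (b' A^-1 b))`` with ``b = T' Gamma d``, which puts
    the solution exactly on the energy-constraint boundary.  Alternatively a
    desired-field scale ``k`` (V/m) may be given directly (default 1 V/m).
    Unweighted LS is obtained by passing identity weights.
    """
    if alpha_I is not None and k is not None:
        raise ValueError("give either alpha_I or k, not both")
    A = _energy_matrix(T, weights.gamma_nonroi)
    b = _objective_vector(T, weights, target.d)
    direction = _solve_spd(A, b)
    bAb = float(b @ direction)
    if bAb <= 0:
        raise ValueError("degenerate target: d' Gamma T (T' Gamma_nonROI T)^-1 T' Gamma d <= 0")
    if alpha_I is not None:
        k = float(np.sqrt(alpha_I / bAb))
    elif k is None:
        k = 1.0
    i = direction * k
    return Optimum(
        i=i,
        objective=float(b @ i),
        k_scale=k,
        active_constraints={"nonroi": True, "budget": False, "box": False},
        status="closed-form",
    )


def scaled_wls(
    T: TransferMatrix, weights: VolumeWeights, target: TargetSpec, i_max: float
) -> Optimum:
    """Closed-form WLS direction rescaled so the expanded l1 norm is 2 i_max."""
    base = wls_closed_form(T, weights, target, k=1.0)
    used = base.used_budget
    if used <= 0:
        raise ValueError("closed-form solution is zero; cannot scale to the budget")
    scale = 2.0 * i_max / used
    b = _objective_vector(T, weights, target.d)
    i = base.i * scale
    return Optimum(
        i=i,
        objective=float(b @ i),
        k_scale=base.k_scale * scale,
        active_constraints={"budget": True, "nonroi": False, "box": False},
        status="closed-form",
    )


# ---------------------------------------------------------------------------
# convex programs
# ---------------------------------------------------------------------------

def constrained_wls(
    T: TransferMatrix,
    weights: VolumeWeights,
    target: TargetSpec,
    k: float,
    constraints: ConstraintSet,
    tol: float = 1e-8,
) -> Optimum:
    """WLS with budget and box limits: min (kd - Ti)' Gamma (kd - Ti).

    The l1 budget is handled by the linear reformulation with auxiliary
    variables; the problem is a linearly constrained QP.
    """
    H = expansion_matrix(T.n_electrodes)
    Q = _energy_matrix(T, weights.gamma)
    b = _objective_vector(T, weights, target.d)
    lo, hi = constraints.box(T.n_electrodes)
    if np.any(lo > hi):
        raise ValueError("infeasible per-electrode box limits")
    i = solve_lcqp(Q, k * b, H, 2.0 * constraints.i_max, lo, hi, tol=tol)
    return Optimum(
        i=i,
        objective=float(b @ i),
        k_scale=k,
        active_constraints=_flags(i, constraints),
        status="optimal",
    )


def dirmax(
    T: TransferMatrix,
    weights: VolumeWeights,
    target: TargetSpec,
    constraints: ConstraintSet,
    nonroi_mode: str = "integral",
    tol: float = 1e-8,
) -> Optimum:
    """Constrained directional maximization (the unified QCLP).

    maximize d' Gamma T i subject to the selected non-ROI bound
    (``integral``: energy integral <= alpha_I; ``elementwise``: per-element
    second-order-cone bounds ||T_n i|| <= alpha_E), the total budget
    ||i~||_1 <= 2 i_max, and per-electrode box limits.
    """
    if nonroi_mode not in ("integral", "elementwise"):
        raise ValueError(f"nonroi_mode must be 'integral' or 'elementwise', got {nonroi_mode!r}")
    c = _objective_vector(T, weights, target.d)
    if not np.any(c):
        return Optimum(i=np.zeros(T.n_electrodes - 1), objective=0.0,
                       active_constraints={}, status="degenerate-target")
    H = expansion_matrix(T.n_electrodes)
    lo, hi = constraints.box(T.n_electrodes)
    budget = 2.0 * constraints.i_max

    if nonroi_mode == "integral":
        if constraints.alpha_I is None:
            raise ValueError("integral mode requires alpha_I")
        A = _energy_matrix(T, weights.gamma_nonroi)
        i, info = solve_qclp(c, H, budget, lo, hi, quad_A=A,
                             alpha_I=constraints.alpha_I, tol=tol)
        energy = float(i @ A @ i)
        flags = _flags(i, constraints, energy=energy, alpha=constraints.alpha_I)
    else:
        if constraints.alpha_E is None:
            raise ValueError("elementwise mode requires alpha_E")
        mask = weights.nonroi_mask_elements
        Tn = T.values.reshape(-1, 3, T.n_electrodes - 1)[mask]
        alpha_E = np.broadcast_to(np.asarray(constraints.alpha_E, dtype=float),
                                  (Tn.shape[0],)).copy()
        if not np.all(alpha_E > 0):
            raise ValueError("alpha_E must be positive")
        i, info = solve_qclp(c, H, budget, lo, hi, Tn=Tn, alpha_E=alpha_E, tol=tol)
        norms = np.linalg.norm(np.einsum("nkl,l->nk", Tn, i), axis=1)
        peak = float(norms.max()) if norms.size else 0.0
        flags = _flags(i, constraints, energy=peak, alpha=float(alpha_E.min()))
    flags["nonroi"] = info["nonroi_active"]
    return Optimum(i=i, objective=float(c @ i), active_constraints=flags,
                   status=info["method"])


# ---------------------------------------------------------------------------
# reciprocity closed forms
# ---------------------------------------------------------------------------

def synthetic_potential(
    operator: TransferMatrix | LeadField,
    weights: VolumeWeights,
    d: np.ndarray,
    s: float = 1.0,
) -> SyntheticPotential:
    """Phi_Gamma = L Gamma d s, the EEG projection of the target dipole field.

    Accepts either a lead field or, via reciprocity (L = T'), a transfer
    matrix — in which case no dipole solves are needed at all.
    """
    if not s > 0:
        raise ValueError("dipole source density s must be positive")
    gd = weights.gamma * np.asarray(d, dtype=float)
    if isinstance(operator, TransferMatrix):
        phi = operator.values.T @ gd * s
    else:
        phi = operator.values @ gd * s
    return SyntheticPotential(phi=phi, dipole_scale=s)


def _stable_extremes(phi: np.ndarray):
    lmax = int(np.argmax(phi))   # argmax/argmin take the lowest index on ties
    lmin = int(np.argmin(phi))
    if np.count_nonzero(phi == phi[lmax]) > 1 or np.count_nonzero(phi == phi[lmin]) > 1:
        logger.info("synthetic potential has tied extrema; lowest electrode index chosen")
    return lmax, lmin


def reciprocity_one_to_one(phi: SyntheticPotential | np.ndarray, i_max: float) -> Optimum:
    """Two-electrode reciprocity montage: +i_max at the potential maximum,
    -i_max at the minimum.

    This is the exact solution of the budget-only directional maximization
    (the feasible l1 ball is a polytope whose vertices are two-electrode
    patterns; the best vertex pairs the extreme potentials).
    """
    phi_exp = phi.phi_expanded if isinstance(phi, SyntheticPotential) else np.asarray(phi, float)
    lmax, lmin = _stable_extremes(phi_exp)
    if lmax == lmin:
        raise ValueError("synthetic potential is constant; no montage is defined")
    i_exp = np.zeros(phi_exp.size)
    i_exp[lmax] = i_max
    i_exp[lmin] = -i_max
    return Optimum(
        i=i_exp[:-1].copy(),
        objective=float(phi_exp @ i_exp),
        active_constraints={"budget": True, "nonroi": False, "box": False},
        status="closed-form",
    )


def reciprocity_limited(
    phi: SyntheticPotential | np.ndarray,
    i_max: float,
    c_source: float,
    c_sink: float,
) -> Optimum:
    """Reciprocity montage under uniform per-electrode limits +c_source/-c_sink.

    ceil(i_max / c_source) best electrodes (by synthetic potential) source
    current at +c_source each, ceil(i_max / c_sink) worst sink at -c_sink;
    with non-integer ratios the last source/sink carries the remainder.
    Reproduces the "opposite", "one source - all sinks" and patch-like
    montages.  ``c_source = c_sink = i_max`` reduces to the one-to-one form.
    """
    if not (c_source > 0 and c_sink > 0):
        raise ValueError("per-electrode limits must be positive")
    phi_exp = phi.phi_expanded if isinstance(phi, SyntheticPotential) else np.asarray(phi, float)
    L = phi_exp.size
    n_src = int(np.ceil(i_max / c_source - 1e-12))
    n_snk = int(np.ceil(i_max / c_sink - 1e-12))
    if n_src + n_snk > L:
        raise ValueError(
            f"infeasible limits: need {n_src} sources + {n_snk} sinks but only {L} electrodes"
        )
    order_desc = np.argsort(-phi_exp, kind="stable")
    order_asc = np.argsort(phi_exp, kind="stable")
    i_exp = np.zeros(L)
    remaining = i_max
    for e in order_desc[:n_src]:
        amount = min(c_source, remaining)
        i_exp[e] = amount
        remaining -= amount
    remaining = i_max
    for e in order_asc[:n_snk]:
        amount = min(c_sink, remaining)
        i_exp[e] = -amount
        remaining -= amount
    return Optimum(
        i=i_exp[:-1].copy(),  # the reference entry is recovered by Kirchhoff closure
        objective=float(phi_exp @ i_exp),
        active_constraints={"budget": True, "nonroi": False, "box": True},
        status="closed-form",
    )
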