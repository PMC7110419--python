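"""Convex solver backends for the montage optimizers.

The l1 budget constraint ||H i||_1 <= 2 i_max is reformulated with auxiliary
variables t >= |H i| (a set of linear constraints), so every problem here is
smooth:

* linear objective + linear constraints -> HiGHS ``linprog`` (exact vertex
  solutions, which is what the polytope-corner regime of directional
  maximization requires);
* linear or quadratic objective + convex quadratic constraints ->
  ``trust-constr``, after whitening the dominant quadratic form by its
  Cholesky factor so the feasible ellipsoid becomes the unit ball (without
  this the interior-point iterations stall on the physical scales: currents
  ~1e-3 A, energies ~1e-5 V^2/m^2 m^3).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import LinAlgError, cholesky, solve_triangular
from scipy.optimize import LinearConstraint, NonlinearConstraint, linprog, minimize

__all__ = ["solve_lp", "solve_qclp", "solve_lcqp", "SolverError"]

DEFAULT_TOL = 1e-8


class SolverError(RuntimeError):
    """Raised when a convex solve does not converge."""


def solve_lp(c: np.ndarray, H: np.ndarray, budget: float, lo: np.ndarray, hi: np.ndarray):
    """maximize c.i  s.t.  ||H i||_1 <= budget, lo <= H i <= hi."""
    L, m = H.shape
    A_ub = np.block(
        [
            [H, -np.eye(L)],
            [-H, -np.eye(L)],
            [np.zeros((1, m)), np.ones((1, L))],
            [H, np.zeros((L, L))],
            [-H, np.zeros((L, L))],
        ]
    )
    b_ub = np.concatenate([np.zeros(2 * L), [budget], hi, -lo])
    cost = np.concatenate([-c, np.zeros(L)])
    bounds = [(None, None)] * m + [(0.0, None)] * L
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"LP solve failed: {res.message}")
    return res.x[:m]


def _chol(A: np.ndarray) -> np.ndarray:
    """Upper Cholesky factor, with a tiny ridge retry for rank-deficient forms."""
    try:
        return cholesky(A, lower=False)
    except LinAlgError:
        ridge = 1e-12 * np.trace(A) / A.shape[0]
        return cholesky(A + ridge * np.eye(A.shape[0]), lower=False)


def _linear_constraints(HM: np.ndarray, budget: float, lo: np.ndarray, hi: np.ndarray):
    """Budget/box constraints on z = [y, t] where i = (map) y and t >= |H i|."""
    L, m = HM.shape
    return [
        LinearConstraint(np.hstack([HM, -np.eye(L)]), -np.inf, 0.0),
        LinearConstraint(np.hstack([-HM, -np.eye(L)]), -np.inf, 0.0),
        LinearConstraint(np.concatenate([np.zeros(m), np.ones(L)])[None, :], -np.inf, budget),
        LinearConstraint(np.hstack([HM, np.zeros((L, L))]), lo, hi),
    ]


def _run_trust_constr(fun, jac, hess, z0, constraints, tol, coarse=False):
    if coarse:
        options = {"gtol": 1e-4, "xtol": 1e-10, "barrier_tol": 1e-4, "maxiter": 500}
    else:
        options = {"gtol": tol, "xtol": 1e-12, "barrier_tol": 1e-12, "maxiter": 3000}
    res = minimize(
        fun,
        z0,
        jac=jac,
        hess=hess,
        method="trust-constr",
        constraints=constraints,
        options=options,
    )
    if not coarse and res.status not in (1, 2):  # gtol / xtol satisfied
        raise SolverError(f"trust-constr did not converge: status={res.status}, {res.message}")
    return res


def _polish_qclp_integral(c, quad_A, alpha_I, H, budget, lo, hi, x):
    """Active-set Newton polish for the energy-bounded maximization.

    On this code path the energy bound is known to be active (the LP vertex
    violated it).  Freeze the remaining active set read off from ``x`` and
    run Newton on the equality-KKT system

        2 mu A x + E' lam = c,   x' A x = alpha_I,   E x = f.

    The polished point is kept only if it is feasible and does not lower
    the objective.
    """
    w = H @ x
    scale = float(np.abs(w).max())
    if scale == 0.0:
        return x
    eps = 1e-3
    atol = 1e-9 * max(budget, scale)
    best, best_obj = x, float(c @ x)
    pinned: set[int] = set()
    for _ in range(10):
        w = H @ best
        rows, rhs = [], []
        if float(np.abs(w).sum()) >= budget * (1 - eps):
            signs = np.sign(w)
            signs[np.abs(w) < eps * scale] = 0.0
            for j in pinned:
                signs[j] = 0.0
            rows.append(signs @ H)
            rhs.append(budget)
            for j in np.flatnonzero(signs == 0.0):
                rows.append(H[j])
                rhs.append(0.0)
        else:
            signs = None
        for j in range(H.shape[0]):
            if w[j] >= hi[j] - eps * scale and np.isfinite(hi[j]):
                rows.append(H[j])
                rhs.append(hi[j])
            elif w[j] <= lo[j] + eps * scale and np.isfinite(lo[j]):
                rows.append(H[j])
                rhs.append(lo[j])
        if rows:
            E = np.unique(np.column_stack([np.array(rows), np.array(rhs)]), axis=0)
            E, f = E[:, :-1], E[:, -1]
        else:
            E = np.zeros((0, x.size))
            f = np.zeros(0)
        m, p = x.size, E.shape[0]
        # initial multipliers from least squares of the stationarity residual
        Ax = quad_A @ best
        basis = np.column_stack([2.0 * Ax, E.T]) if p else (2.0 * Ax)[:, None]
        mul, *_ = np.linalg.lstsq(basis, c, rcond=None)
        mu, lam = float(mul[0]), mul[1:]
        z = best.copy()
        ok = False
        for _ in range(30):
            Az = quad_A @ z
            r = np.concatenate(
                [
                    2.0 * mu * Az + (E.T @ lam if p else 0.0) - c,
                    [float(z @ Az) - alpha_I],
                    E @ z - f,
                ]
            )
            if np.linalg.norm(r) <= 1e-12 * max(1.0, np.linalg.norm(c)):
                ok = True
                break
            J = np.zeros((m + 1 + p, m + 1 + p))
            J[:m, :m] = 2.0 * mu * quad_A
            J[:m, m] = 2.0 * Az
            if p:
                J[:m, m + 1:] = E.T
                J[m + 1:, :m] = E
            J[m, :m] = 2.0 * Az
            try:
                step = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError:
                break
            z += step[:m]
            mu += step[m]
            lam = lam + step[m + 1:]
        if not ok:
            return best
        w_new = H @ z
        feasible = (
            float(np.abs(w_new).sum()) <= budget + atol
            and np.all(w_new <= hi + atol)
            and np.all(w_new >= lo - atol)
            and float(z @ quad_A @ z) <= alpha_I * (1 + 1e-9)
        )
        if feasible:
            if float(c @ z) > best_obj:
                best, best_obj = z, float(c @ z)
            else:
                return best
        elif signs is not None:
            flipped = np.flatnonzero((np.sign(w_new) != signs) & (signs != 0.0))
            if flipped.size == 0:
                return best
            pinned |= set(flipped.tolist())
        else:
            return best
    return best


def solve_qclp(
    c: np.ndarray,
    H: np.ndarray,
    budget: float,
    lo: np.ndarray,
    hi: np.ndarray,
    quad_A: np.ndarray | None = None,
    alpha_I: float | None = None,
    Tn: np.ndarray | None = None,
    alpha_E: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
):
    """maximize c.i under the l1/box constraints plus a non-ROI field bound.

    Exactly one of the two bound families must be given: an energy integral
    ``i' A i <= alpha_I`` (quad_A = T' Gamma_nonROI T) or per-element bounds
    ``||T_n i|| <= alpha_E[n]`` (Tn of shape (M, 3, m), squared internally to
    keep the constraints smooth).

    Strategy: first solve the LP obtained by dropping the field bound; if the
    bound already holds there it was inactive and the LP vertex is optimal.
    Otherwise solve the QCLP with trust-constr in whitened coordinates
    (``i = map @ y`` with the energy ellipsoid mapped to the unit ball),
    warm-started from the LP solution shrunk radially into the feasible set
    (which is star-shaped around 0, so shrinking is always feasible).
    """
    L, m = H.shape
    x_lp = solve_lp(c, H, budget, lo, hi)
    if quad_A is not None:
        q = float(x_lp @ quad_A @ x_lp)
        if q <= alpha_I * (1 + 1e-9):
            return x_lp, {"nonroi_active": False, "method": "lp"}
        R = _chol(quad_A)
        mapping = np.sqrt(alpha_I) * solve_triangular(R, np.eye(m))
        y_lp = (R @ x_lp) / np.sqrt(alpha_I)

        def qfun(z):
            y = z[:m]
            return float(y @ y)

        def qjac(z):
            g = np.zeros_like(z)
            g[:m] = 2.0 * z[:m]
            return g

        def qhess(z, v):
            Hm = np.zeros((m + L, m + L))
            Hm[:m, :m] = 2.0 * v[0] * np.eye(m)
            return Hm

        nl = NonlinearConstraint(qfun, -np.inf, 1.0, jac=qjac, hess=qhess)
        y0 = y_lp / np.linalg.norm(y_lp) * 0.95
    else:
        return _solve_qclp_elementwise(c, H, budget, lo, hi, Tn, alpha_E, x_lp, tol)

    s = budget / 2.0  # current scale for the linear constraints
    HM = H @ mapping / s
    c_y = mapping.T @ c
    c_y = c_y / np.linalg.norm(c_y)
    cz = np.concatenate([-c_y, np.zeros(L)])

    def fun(z):
        return float(cz @ z)

    def jac(z):
        return cz

    def hess(z):
        return np.zeros((m + L, m + L))

    constraints = _linear_constraints(HM, 2.0, lo / s, hi / s)
    constraints.append(nl)
    z0 = np.concatenate([y0, np.abs(HM @ y0) + 1e-9])
    res = _run_trust_constr(fun, jac, hess, z0, constraints, tol)
    x_opt = _polish_qclp_integral(
        c, quad_A, alpha_I, H, budget, lo, hi, mapping @ res.x[:m]
    )
    return x_opt, {"nonroi_active": True, "method": "trust-constr"}


def _cone_constraint(Tn_scaled, idx, mapping, m):
    """NonlinearConstraint for the working-set cones in whitened coordinates.

    ``extra`` trailing variables (the budget auxiliaries, if any) are ignored
    by padding the Jacobian/Hessian to the full variable count.
    """
    Tny = np.einsum("nkl,lj->nkj", Tn_scaled[idx], mapping)
    Mw = Tny.shape[0]

    def qfun(z):
        F = np.einsum("nkl,l->nk", Tny, z[:m])
        return np.einsum("nk,nk->n", F, F)

    def qjac(z):
        F = np.einsum("nkl,l->nk", Tny, z[:m])
        J = np.zeros((Mw, z.size))
        J[:, :m] = 2.0 * np.einsum("nk,nkl->nl", F, Tny)
        return J

    def qhess(z, v):
        Hm = np.zeros((z.size, z.size))
        Hm[:m, :m] = 2.0 * np.einsum("n,nkl,nkj->lj", v, Tny, Tny)
        return Hm

    return NonlinearConstraint(qfun, -np.inf, np.ones(Mw), jac=qjac, hess=qhess)


def _solve_cone_only(c, Tn_scaled, mapping, R, x0, norms0, scaled_norms, tol):
    """maximize c.x s.t. ||T_n x|| <= alpha_n only (budget/box dropped).

    In the low-alpha regime the budget and box constraints are slack, and
    carrying their auxiliary variables (whose t = |H i| rows are always
    active) makes the interior-point iterations degenerate and slow.  This
    reduced problem has just the m whitened variables.  The aggregate bound
    ||y||^2 <= M (the sum of all element bounds, hence a valid relaxation)
    keeps every working-set subproblem bounded.
    """
    m = mapping.shape[1]
    M = Tn_scaled.shape[0]
    c_y = mapping.T @ c
    c_y = c_y / np.linalg.norm(c_y)

    def fun(y):
        return -float(c_y @ y)

    def jac(y):
        return -c_y

    def hess(y):
        return np.zeros((m, m))

    ball = NonlinearConstraint(
        lambda y: float(y @ y),
        -np.inf,
        float(M),
        jac=lambda y: 2.0 * y,
        hess=lambda y, v: 2.0 * v[0] * np.eye(m),
    )
    working = set(np.argsort(norms0)[-max(8, m):].tolist())
    x = x0
    for _ in range(60):
        idx = np.fromiter(sorted(working), dtype=np.int64)
        nl = _cone_constraint(Tn_scaled, idx, mapping, m)
        res = _run_trust_constr(fun, jac, hess, R @ x, [ball, nl], tol, coarse=True)
        x = mapping @ res.x
        norms = scaled_norms(x)
        violated = np.flatnonzero(norms > 1 + 1e-6)
        if not set(violated.tolist()) - working:
            res = _run_trust_constr(fun, jac, hess, R @ x, [ball, nl], tol)
            x = mapping @ res.x
            norms = scaled_norms(x)
            violated = np.flatnonzero(norms > 1 + 1e-6)
            if not set(violated.tolist()) - working:
                return x
        # grow slowly (only a few cones end up active) and prune clearly
        # slack members: the trust-constr cost scales with the working set
        worst = violated[np.argsort(norms[violated])[::-1]][:32]
        working |= set(worst.tolist())
        if len(working) > 4 * m:
            keep = {n for n in working if norms[n] > 0.5}
            working = keep | set(worst.tolist())
        x = x / float(norms.max()) * 0.999
    raise SolverError("cone-only constraint generation did not settle within 60 rounds")


def _solve_qclp_elementwise(c, H, budget, lo, hi, Tn, alpha_E, x_lp, tol):
    """Per-element cone-bounded maximization by constraint generation.

    Only a handful of the thousands of element bounds are active at the
    optimum, so the QCLP is solved on a growing working set: violated
    elements are added and the reduced problem re-solved until the full
    constraint set is satisfied.  Whitening uses the aggregate form
    G = sum_n (T_n/alpha_n)' (T_n/alpha_n), which is well conditioned even
    when the working set alone is rank deficient.
    """
    L, m = H.shape
    alpha_E = np.asarray(alpha_E, dtype=float)
    Tn_scaled = Tn / alpha_E[:, None, None]

    def scaled_norms(x):
        return np.linalg.norm(np.einsum("nkl,l->nk", Tn_scaled, x), axis=1)

    norms = scaled_norms(x_lp)
    peak = float(norms.max()) if norms.size else 0.0
    if peak <= 1 + 1e-9:
        return x_lp, {"nonroi_active": False, "method": "lp"}

    G = np.einsum("nkl,nkj->lj", Tn_scaled, Tn_scaled)
    R = _chol(G)
    mapping = solve_triangular(R, np.eye(m))

    # fast path: solve without the budget/box machinery and keep the result
    # if those constraints turn out slack at the cone-bounded optimum
    x_cone = _solve_cone_only(
        c, Tn_scaled, mapping, R, x_lp / peak * 0.95, norms, scaled_norms, tol
    )
    hx = H @ x_cone
    atol = 1e-9 * budget
    if (
        float(np.abs(hx).sum()) <= budget + atol
        and np.all(hx <= hi + atol)
        and np.all(hx >= lo - atol)
    ):
        return x_cone, {"nonroi_active": True, "method": "trust-constr"}

    s = budget / 2.0
    HM = H @ mapping / s
    c_y = mapping.T @ c
    c_y = c_y / np.linalg.norm(c_y)
    cz = np.concatenate([-c_y, np.zeros(L)])
    lin = _linear_constraints(HM, 2.0, lo / s, hi / s)

    def fun(z):
        return float(cz @ z)

    def jac(z):
        return cz

    def hess(z):
        return np.zeros((m + L, m + L))

    working = set(np.argsort(scaled_norms(x_cone))[-max(8, m):].tolist())
    x = x_cone / float(scaled_norms(x_cone).max()) * 0.95
    for _ in range(60):  # shrink toward 0 (always feasible) until budget/box hold
        hx = H @ x
        if float(np.abs(hx).sum()) <= budget and np.all(hx <= hi) and np.all(hx >= lo):
            break
        x *= 0.5
    for _ in range(30):
        idx = np.fromiter(sorted(working), dtype=np.int64)
        nl = _cone_constraint(Tn_scaled, idx, mapping, m)
        y0 = R @ x
        z0 = np.concatenate([y0, np.abs(HM @ y0) + 1e-9])
        # coarse solves while the working set is still growing, one tight
        # solve once all element bounds hold
        res = _run_trust_constr(fun, jac, hess, z0, lin + [nl], tol, coarse=True)
        x = mapping @ res.x[:m]
        norms = scaled_norms(x)
        violated = np.flatnonzero(norms > 1 + 1e-6)
        new = set(violated.tolist()) - working
        if not new:
            res = _run_trust_constr(fun, jac, hess, np.concatenate(
                [R @ x, np.abs(HM @ (R @ x)) + 1e-9]), lin + [nl], tol)
            x = mapping @ res.x[:m]
            norms = scaled_norms(x)
            violated = np.flatnonzero(norms > 1 + 1e-6)
            if not set(violated.tolist()) - working:
                return x, {"nonroi_active": True, "method": "trust-constr"}
        worst = violated[np.argsort(norms[violated])[::-1]][:32]
        working |= set(worst.tolist())
        if len(working) > 4 * m:
            keep = {n for n in working if norms[n] > 0.5}
            working = keep | set(worst.tolist())
        x = x / float(norms.max()) * 0.999
    raise SolverError("constraint generation did not settle within 30 rounds")


def _polish_lcqp(Q, b, H, budget, lo, hi, x):
    """Active-set Newton polish for the linearly constrained QP.

    The interior-point iterations leave a small (~1e-4 relative) gap to the
    active constraints.  Freeze the active set read off from ``x`` — the
    l1 budget with its sign pattern, pinned-to-zero electrodes, active box
    rows — solve the equality-constrained KKT system exactly, and keep the
    result only if it is feasible and lowers the objective.
    """
    scale0 = float(np.abs(H @ x).max())
    if scale0 == 0.0:
        return x
    eps = 1e-3
    atol = 1e-9 * max(budget, scale0)

    def obj(v):
        return float(v @ Q @ v - 2 * b @ v)

    best, best_obj = x, obj(x)
    cand, pinned = x, set()
    for _ in range(10):
        w = H @ cand
        rows, rhs = [], []
        if float(np.abs(w).sum()) >= budget * (1 - eps):
            signs = np.sign(w)
            signs[np.abs(w) < eps * scale0] = 0.0
            for j in pinned:
                signs[j] = 0.0
            rows.append(signs @ H)
            rhs.append(budget)
            for j in np.flatnonzero(signs == 0.0):
                rows.append(H[j])
                rhs.append(0.0)
        else:
            signs = None
        for j in range(H.shape[0]):
            if w[j] >= hi[j] - eps * scale0 and np.isfinite(hi[j]):
                rows.append(H[j])
                rhs.append(hi[j])
            elif w[j] <= lo[j] + eps * scale0 and np.isfinite(lo[j]):
                rows.append(H[j])
                rhs.append(lo[j])
        if not rows:
            return best
        E = np.unique(np.column_stack([np.array(rows), np.array(rhs)]), axis=0)
        E, f = E[:, :-1], E[:, -1]
        m, p = Q.shape[0], E.shape[0]
        kkt = np.block([[2.0 * Q, E.T], [E, np.zeros((p, p))]])
        try:
            sol = np.linalg.solve(kkt, np.concatenate([2.0 * b, f]))
        except np.linalg.LinAlgError:
            return best
        x_new = sol[:m]
        w_new = H @ x_new
        feasible = (
            float(np.abs(w_new).sum()) <= budget + atol
            and np.all(w_new <= hi + atol)
            and np.all(w_new >= lo - atol)
        )
        if feasible:
            if obj(x_new) < best_obj:
                best, best_obj = x_new, obj(x_new)
            else:
                return best
        elif signs is not None:
            # a small electrode flipped sign against the frozen l1 pattern:
            # pin the offenders to zero and re-solve
            flipped = np.flatnonzero((np.sign(w_new) != signs) & (signs != 0.0))
            if flipped.size == 0:
                return best
            pinned |= set(flipped.tolist())
        else:
            return best
        cand = x_new
    return best


def solve_lcqp(
    Q: np.ndarray,
    b: np.ndarray,
    H: np.ndarray,
    budget: float,
    lo: np.ndarray,
    hi: np.ndarray,
    tol: float = DEFAULT_TOL,
):
    """minimize x' Q x - 2 b.x  s.t.  ||H x||_1 <= budget, lo <= H x <= hi.

    Whitened with the Cholesky factor of Q and scaled by the unconstrained
    minimizer's magnitude, so the objective is the unit paraboloid
    ||u - u*||^2 regardless of the physical scales.
    """
    L, m = H.shape
    R = _chol(Q)
    b_w = solve_triangular(R, b, trans="T")       # unconstrained optimum in y = R x
    scale = float(np.linalg.norm(b_w))
    if scale == 0:
        return np.zeros(m)
    mapping = solve_triangular(R, np.eye(m)) * scale   # x = mapping @ u, u = y/scale
    b_hat = b_w / scale
    HM = H @ mapping / (budget / 2.0)

    def fun(z):
        u = z[:m]
        return float(u @ u - 2.0 * b_hat @ u)

    def jac(z):
        g = np.zeros_like(z)
        g[:m] = 2.0 * (z[:m] - b_hat)
        return g

    def hess(z):
        Hm = np.zeros((m + L, m + L))
        Hm[:m, :m] = 2.0 * np.eye(m)
        return Hm

    s = budget / 2.0
    constraints = _linear_constraints(HM, 2.0, lo / s, hi / s)
    u0 = b_hat * 0.5
    nrm1 = float(np.abs(HM @ u0).sum())
    if nrm1 > 2.0:
        u0 *= 2.0 / nrm1 * 0.95
    z0 = np.concatenate([u0, np.abs(HM @ u0) + 1e-9])
    res = _run_trust_constr(fun, jac, hess, z0, constraints, tol)
    return _polish_lcqp(Q, b, H, budget, lo, hi, mapping @ res.x[:m])
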