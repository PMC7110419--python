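"""Alpha sweeps: the intensity-focality trade-off and its critical points.

Sweeping the non-ROI bound (alpha_I for the energy integral, alpha_E for the
per-element bound) over a log grid traces the whole family of optimal
montages between two closed-form extremes:

* below critical point "a" the budget is not exhausted and the solution is a
  rescaled copy of one fixed shape (the WLS closed form, for the integral
  constraint);
* above critical point "b" the solution has collapsed onto the reciprocity
  montage and no longer changes;
* in between ("white zone") both constraints are active and the
  intensity-focality trade-off unfolds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solvers import SolverError
from .fem import TransferMatrix
from .metrics import elementwise_focality, integral_focality, mean_roi_intensity
from .optimize import (
    Optimum,
    dirmax,
    reciprocity_limited,
    reciprocity_one_to_one,
    scaled_wls,
    synthetic_potential,
)
from .problem import ConstraintSet, TargetSpec, VolumeWeights, expand_pattern

__all__ = ["SweepResult", "alpha_sweep", "detect_critical_points", "cross_focality_curves"]

logger = logging.getLogger(__name__)

#: budget fraction above which the budget constraint counts as saturated
BUDGET_SATURATION = 0.995
#: relative l2 tolerance for declaring two patterns equivalent
PATTERN_MATCH_TOL = 1e-3


def patterns_match(i_a: np.ndarray, i_b: np.ndarray, tol: float = PATTERN_MATCH_TOL) -> bool:
    a, b = expand_pattern(i_a), expand_pattern(i_b)
    nb = np.linalg.norm(b)
    return bool(np.linalg.norm(a - b) <= tol * nb) if nb > 0 else bool(np.linalg.norm(a) == 0)


@dataclass
class SweepResult:
    """Ordered sweep points with metrics, patterns, and critical points."""

    table: pd.DataFrame
    patterns: list[np.ndarray]
    nonroi_mode: str
    i_max: float
    reciprocity_pattern: np.ndarray
    critical_a: float | None = None
    critical_b: float | None = None
    critical_c: float | None = None
    failures: list[tuple[float, str]] = field(default_factory=list)

    @property
    def alphas(self) -> np.ndarray:
        return self.table["alpha"].to_numpy()


def _reference_reciprocity(T, weights, target, constraints: ConstraintSet) -> Optimum:
    """The closed-form montage the sweep collapses onto at large alpha."""
    phi = synthetic_potential(T, weights, target.d)
    L = T.n_electrodes
    lo, hi = constraints.box(L)
    if np.allclose(hi, constraints.i_max) and np.allclose(lo, -constraints.i_max):
        return reciprocity_one_to_one(phi, constraints.i_max)
    if np.ptp(hi) < 1e-15 and np.ptp(lo) < 1e-15:
        return reciprocity_limited(phi, constraints.i_max, float(hi[0]), float(-lo[0]))
    # non-uniform boxes have no published closed form; fall back to one-to-one
    return reciprocity_one_to_one(phi, constraints.i_max)


def _default_grid(T, weights, target, constraints, nonroi_mode, n_points) -> np.ndarray:
    """Log grid bracketing both saturation regimes.

    The bracket is derived from the model itself: the non-ROI exposure of the
    budget-exhausting WLS montage (near point "a") and of the reciprocity
    montage (at/above point "b"), padded by two decades below and one above.
    """
    i_wls = scaled_wls(T, weights, target, constraints.i_max).i
    i_rec = _reference_reciprocity(T, weights, target, constraints).i
    if nonroi_mode == "integral":
        A = T.values.T @ (weights.gamma_nonroi[:, None] * T.values)
        lo_val = float(i_wls @ A @ i_wls)
        hi_val = float(i_rec @ A @ i_rec)
    else:
        mask = weights.nonroi_mask_elements

        def peak(i):
            return float(np.linalg.norm(T.field_of(i), axis=1)[mask].max())

        lo_val, hi_val = peak(i_wls), peak(i_rec)
    return np.geomspace(lo_val / 100.0, hi_val * 10.0, n_points)


def alpha_sweep(
    T: TransferMatrix,
    weights: VolumeWeights,
    target: TargetSpec,
    constraints: ConstraintSet,
    nonroi_mode: str = "integral",
    alpha_grid: np.ndarray | None = None,
    n_points: int = 40,
    tol: float = 1e-8,
) -> SweepResult:
    """One dirmax solve per alpha; intensity, budget and both focality metrics
    recorded at every point.

    The grid is extended automatically (up to 4 decades each side) until the
    leftmost point leaves the budget unsaturated and the rightmost pattern
    matches the reciprocity closed form.
    """
    if alpha_grid is None:
        grid = _default_grid(T, weights, target, constraints, nonroi_mode, n_points)
    else:
        grid = np.sort(np.asarray(alpha_grid, dtype=float))
    i_rec = _reference_reciprocity(T, weights, target, constraints).i

    def solve_at(alpha) -> Optimum:
        cs = ConstraintSet(
            i_max=constraints.i_max,
            alpha_I=alpha if nonroi_mode == "integral" else None,
            alpha_E=alpha if nonroi_mode == "elementwise" else None,
            i_min_vec=constraints.i_min_vec,
            i_max_vec=constraints.i_max_vec,
        )
        return dirmax(T, weights, target, cs, nonroi_mode=nonroi_mode, tol=tol)

    # extend the bracket where needed before the full sweep
    for _ in range(4):
        opt = solve_at(grid[0])
        if opt.used_budget < BUDGET_SATURATION * 2 * constraints.i_max:
            break
        grid = np.concatenate([[grid[0] / 10.0], grid])
    for _ in range(4):
        opt = solve_at(grid[-1])
        if patterns_match(opt.i, i_rec):
            break
        grid = np.concatenate([grid, [grid[-1] * 10.0]])

    rows, patterns, failures = [], [], []
    for alpha in grid:
        try:
            opt = solve_at(alpha)
        except SolverError as exc:
            logger.warning("sweep point alpha=%.3e failed: %s", alpha, exc)
            failures.append((float(alpha), str(exc)))
            continue
        used = opt.used_budget
        rows.append(
            {
                "alpha": float(alpha),
                "mean_roi_intensity": mean_roi_intensity(opt.i, T, weights, target),
                "used_budget_A": used,
                "budget_pct": 100.0 * used / (2 * constraints.i_max),
                "focality_integral": integral_focality(opt.i, T, weights, target),
                "focality_elementwise": elementwise_focality(opt.i, T, weights, target),
                "nonroi_active": opt.active_constraints.get("nonroi", False),
                "budget_active": opt.active_constraints.get("budget", False),
            }
        )
        patterns.append(opt.i)
    result = SweepResult(
        table=pd.DataFrame(rows),
        patterns=patterns,
        nonroi_mode=nonroi_mode,
        i_max=constraints.i_max,
        reciprocity_pattern=i_rec,
        failures=failures,
    )
    detect_critical_points(result)
    return result


def detect_critical_points(sweep: SweepResult):
    """Locate critical points "a" (budget saturates) and "b" (reciprocity
    reached) and label the zones; returns (a, b).

    "a" is the smallest alpha with used budget >= 99.5% of 2 i_max; "b" the
    smallest alpha whose pattern matches the reciprocity closed form within
    1e-3 relative l2.  Point "c" (steepest focality decrease, informational)
    is recorded for elementwise sweeps.
    """
    tbl = sweep.table
    pct = tbl["budget_pct"].to_numpy()
    alphas = tbl["alpha"].to_numpy()
    sat = np.flatnonzero(pct >= 100.0 * BUDGET_SATURATION)
    sweep.critical_a = float(alphas[sat[0]]) if sat.size else None
    match = np.flatnonzero(
        [patterns_match(p, sweep.reciprocity_pattern) for p in sweep.patterns]
    )
    sweep.critical_b = float(alphas[match[0]]) if match.size else None
    if sweep.critical_a is None or sweep.critical_b is None:
        logger.warning("sweep did not span both regimes; critical points open-ended")

    zones = []
    for a in alphas:
        if sweep.critical_a is not None and a < sweep.critical_a:
            zones.append("pink")
        elif sweep.critical_b is not None and a >= sweep.critical_b:
            zones.append("blue")
        else:
            zones.append("white")
    tbl["zone"] = zones

    if sweep.nonroi_mode == "elementwise" and len(alphas) > 2:
        foc = tbl["focality_elementwise"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.diff(np.log(foc)) / np.diff(np.log(alphas))
        slope = np.where(np.isfinite(slope), slope, 0.0)
        sweep.critical_c = float(alphas[int(np.argmin(slope))]) if slope.size else None
    return sweep.critical_a, sweep.critical_b


def cross_focality_curves(sweep_integral: SweepResult, sweep_elementwise: SweepResult) -> pd.DataFrame:
    """Tidy table of both focality metrics for both solution families.

    Indexed by the mean ROI intensity so the two families are directly
    comparable (their alpha axes have different units).
    """
    frames = []
    for family, sweep in (("integral", sweep_integral), ("elementwise", sweep_elementwise)):
        t = sweep.table.copy()
        t.insert(0, "family", family)
        frames.append(
            t[
                [
                    "family",
                    "alpha",
                    "mean_roi_intensity",
                    "budget_pct",
                    "focality_integral",
                    "focality_elementwise",
                    "zone",
                ]
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["family", "mean_roi_intensity"]).reset_index(drop=True)
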