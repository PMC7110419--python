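# Methods

Notation: the head mesh has `n` nodes and `N_brain` brain tetrahedra; `L`
electrodes inject currents `ĩ ∈ R^L` with `Σ ĩ = 0`. The reduced pattern
`i ∈ R^(L−1)` drops the last (return) electrode; the expansion matrix
`H ∈ R^(L×(L−1))` (identity over a final row of −1) restores it, so Kirchhoff's
law holds by construction: `ĩ = H i`.

## Synthetic head models

`generate_sphere_head` builds a four-shell concentric sphere
(brain/CSF/skull/scalp, default outer radii 80/81/86/92 mm, conductivities
0.33/1.79/0.006/0.3 S/m). Nodes are placed quasi-uniformly on concentric
spherical shells with a Fibonacci lattice, independently rotated and jittered
per shell from a seeded RNG (so meshes are reproducible by seed but
distinct across seeds), and tetrahedralized with `scipy.spatial.Delaunay` —
the domain is a ball, hence convex, so the Delaunay tetrahedralization covers
it exactly. Elements are labelled by centroid radius; positive orientation is
enforced by vertex swaps. The generator verifies the total mesh volume
against the analytic sphere volume (2% gate) and rejects non-increasing
radii. Electrode positions are a seeded subsample of well-separated outer
nodes. Gmsh MSH 2.2 ASCII import (`read_gmsh`) and plain-text mesh I/O are
provided for externally supplied heads.

## FEM forward problem

Piecewise-linear (P1) Galerkin discretization of `∇·(σ∇φ) = 0` with Neumann
boundary injection gives the symmetric stiffness system `K φ = u`, with per-
element stiffness `V_e σ_e B_eᵀB_e` (`B_e` the constant gradient operator of
the tet, `V_e` its volume). `K` annihilates constants (pure-Neumann null
space); one interior node is grounded by row/column deletion, and the system
is factorized once with sparse LU (`scipy splu`) — deterministic, and reused
for every right-hand side. Each solve asserts the relative residual
`‖Kφ − u‖ / ‖u‖ ≤ 1e−8`. Point electrodes enter as entries `±I` in `u`.

The transfer matrix `T ∈ R^(3N_brain × (L−1))` collects the brain electric
field `E = −∇φ` of the `L−1` basis patterns (electrode `j` vs the return
electrode); an arbitrary montage's field is `T i` by superposition.

## Lead field and reciprocity

The dipole lead field row for a unit dipole `m` at element `e` is obtained by
solving `K w = b` with the adjoint load `b_j = −m·∇φ_j(x_e)` (the P1 gradient
of basis function `j` on element `e`) and reading the solution at the
electrode nodes. With this sign convention the reciprocity relation is
exactly `L = Tᵀ` — verified element-by-element to ~1e−15 relative — so in
practice lead-field rows are read off the transfer matrix without extra
solves. (The opposite load sign gives `L = −Tᵀ`.) If a dipole element touches
the ground node the grounded load entry is dropped with a warning; only the
potential's arbitrary constant is affected.

## Target, weights, constraints

The ROI is a set of brain elements (a ball around a centroid in the provided
builders); the desired direction field `d ∈ R^(3N)` is zero outside the ROI
and, by default, the unit surface-normal of the nearest brain-surface facet
inside it (degenerate mean normals are an error). The diagonal volume
matrices `Γ` (all elements) and `Γ_nonROI` are stored as 3N vectors of element
volumes; `exact` mode zeroes the ROI entries of `Γ_nonROI`, `approximate`
mode keeps `Γ_nonROI = Γ` (the ROI volume fraction is tiny; this mode makes
the closed-form equivalences below hold with one shared quadratic form).

A `ConstraintSet` carries the safety budget `‖H i‖₁ ≤ 2·i_max`, optional
per-electrode box limits `lo ≤ H i ≤ hi` (must straddle zero), and exactly
one non-ROI field bound for the directional maximization: the energy integral
`iᵀ A i ≤ α_I` with `A = Tᵀ Γ_nonROI T`, or elementwise bounds
`‖T_e i‖₂ ≤ α_E` per non-ROI element.

## Optimizers

All optimizers return an `Optimum` with the reduced pattern, objective,
active-constraint flags and used budget. Writing `b = Tᵀ Γ d`:

* **`wls_closed_form`** — the weighted-least-squares direction
  `î = k · A⁻¹ b`. The scale is either a given `k` or chosen from an energy
  level `α_I` via `k(α_I) = sqrt(α_I / bᵀA⁻¹b)`, which places the solution
  exactly on the energy boundary.
* **`scaled_wls`** — the same direction rescaled to exhaust the `ℓ₁` budget.
* **`constrained_wls`** — `min iᵀ Q i − 2k bᵀ i` with `Q = Tᵀ Γ T`, subject
  to budget and box constraints (a linearly constrained QP).
* **`dirmax`** — `max bᵀ i` subject to budget, box, and the non-ROI bound
  (`α_I`: a quadratically constrained LP; `α_E`: second-order-cone
  constraints). This is the unifying problem: small `α` reproduces the WLS
  closed form, large `α` the reciprocity montage. Those limit cases are used
  only as test oracles — the solver is a direct convex solve.
* **`synthetic_potential`** — the electrode potential `Φ = L (Γ d) s` a
  dipole distribution along `d` would produce, computed through `Tᵀ`.
* **`reciprocity_one_to_one`** — closed form: inject `+i_max` and `−i_max` at
  the electrodes with the extreme synthetic potentials.
* **`reciprocity_limited`** — closed form with per-electrode source/sink
  limits `c_src`, `c_snk`: fill electrodes greedily by descending (ascending)
  synthetic potential until `i_max` is reached on each side, with fractional
  remainders. Equals the large-`α` convex solve with the corresponding box.

## Convex backends (`_solvers.py`)

The `ℓ₁` budget is reformulated with auxiliary variables `t ≥ |H i|`, making
every program smooth.

* Linear programs (the budget/box-only regime) go to HiGHS `linprog`, whose
  vertex solutions are exact — required in the large-`α` regime where the
  optimum is a polytope corner.
* Quadratically/cone-constrained programs go to `trust-constr` with analytic
  Jacobians and Hessians, after *whitening*: the dominant quadratic form is
  Cholesky-factorized and the variables mapped so the feasible ellipsoid is
  the unit ball. Without this the interior-point iterations stall on the
  physical scales (currents ~1e−3 A, energies ~1e−5).
* Interior-point solutions stop ~1e−4 (relative) short of their active
  constraints, so both QP and QCLP solutions are *polished*: the active set
  is read off the solution (`ℓ₁` sign pattern with pinned-to-zero electrodes,
  active box rows, active energy bound) and the equality-KKT system is solved
  exactly — a linear solve for the QP, a few Newton steps on the bilinear KKT
  for the QCLP. The polished point is kept only if feasible and improving;
  electrodes that flip sign against the frozen pattern are pinned and the
  polish re-run. This brings the limit-case equivalences from ~2e−3 to
  ~1e−13 relative in the box-limited case.
* The elementwise bound involves thousands of cones of which only a handful
  are active, so it is solved by constraint generation: solve on a working
  set, add up to 32 of the worst violated cones per round, prune clearly
  slack members. When budget and box are slack at the cone-bounded optimum
  (the usual low-`α` case) a fast path drops the budget auxiliaries entirely
  — their `t = |H i|` rows are always active and degenerate, and removing
  them speeds the solve ~10×. A ball relaxation `‖y‖² ≤ M` (the sum of all
  cone bounds, hence valid) keeps every working-set subproblem bounded.

Active-constraint flags are reported at a relative tolerance of 1e−4,
separating polished/closed-form solutions (machine precision at the
boundary) from interior-point gaps.

## Focality metrics and α sweeps

For a montage with field `F = T i`:

* `mean_roi_intensity` — volume-weighted mean over ROI elements of the field
  component along `d`.
* `integral_focality` — that intensity divided by the volume-RMS field
  magnitude over the whole compartment.
* `elementwise_focality` — intensity divided by the peak non-ROI field
  magnitude.

`alpha_sweep` solves `dirmax` on a log-spaced `α` grid bracketing both limit
regimes and classifies each point into three zones: **pink** (budget
< 99.5% used — the field bound alone limits the montage), **white** (budget
saturated, pattern still changing), **blue** (pattern matches the
reciprocity montage within 1e−3 relative). Critical point `a` is the first
grid `α` with saturated budget, `b` the first whose pattern matches
reciprocity, and (elementwise sweeps) `c` the steepest drop of
log-focality vs log-α. `cross_focality_curves` tabulates both sweep families
(integral- and elementwise-bounded) under both metrics; at matched mean ROI
intensity each family dominates the other under its own metric.

## Verification against an analytic oracle

For a homogeneous sphere, the surface potential of two point electrodes has
a Legendre series closed form; the implementation sums it with Lanczos sigma
factors (`sinc(k/(K+1))`) to suppress Gibbs oscillations of the truncated
series. The FEM solution on a uniform-conductivity four-shell mesh is
compared to this oracle over the outer surface, excluding 25° caps around
the injection points (the point-source potential is singular there; no
mesh-based method converges pointwise at the singularity). Relative RMS
errors decrease monotonically under refinement: 3.5% (18 mm edges), 1.6%
(16 mm), 1.1% (11 mm), 0.5% (8 mm).
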