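# Methods

## The problem

Score-based diffusion models generate molecular conformations by
integrating a reverse-time stochastic differential equation (SDE) whose
drift is the learned score `∇ log p_t(x)`.  Nothing in that dynamics
guarantees that generated structures respect known geometric facts —
covalent bond lengths, target interatomic distances, torsional
preferences.  `shakediff` enforces such facts as *holonomic constraints*
`σ_a(x) = 0`, `a = 1..A`, by projecting every stochastic update onto the
constraint manifold, the stochastic analogue of the SHAKE algorithm from
constrained molecular dynamics.

## Constraint model

A constraint is a scalar internal coordinate minus a target:

    σ(x) = value(x) − target,

where `value` is an interatomic distance (Å), a bond angle or a torsion
(degrees, IUPAC sign, residuals wrapped to the shortest arc (−180, 180]).
The linear form is used rather than the squared form `(value − target)²`
because its gradient does not vanish at feasibility, which keeps the Gram
matrix of the multiplier solve well conditioned near the solution; the
squared form is available as `SquaredConstraint` for comparison.
Analytic gradients are implemented for all three kinds (standard
internal-coordinate derivative formulas); angular gradients are expressed
in degrees per Å so that residuals and gradients share one unit system and
finite-difference checks apply uniformly.  Interatomic separations below
1e-8 Å and collinear angle/dihedral frames raise a degenerate-geometry
error rather than returning an arbitrary direction.

Bounded constraints `lower ≤ value(x) ≤ upper` are handled by active-set
resolution: a constraint whose value lies strictly inside its bounds is
*inactive* (the permitted slack absorbs the deviation and the constraint
drops out of the Jacobian); a violated bound becomes an active equality at
that bound; coincident bounds are always active — the holonomic
(strict-equality) limit.

## Projection (matrix SHAKE)

After an unconstrained trial step `x̃`, the projection iterates

    solve  (G + εI) λ = −σ,   G_ab = ∇σ_a · ∇σ_b
    update x ← x + Σ_a λ_a ∇σ_a

until `max_a w_a |σ_a| ≤ tol`, with `w_a = 1` for distances and
`w_a = 0.01 Å/degree` for angular constraints (so 1° of angular violation
counts like 0.01 Å).  The A×A Gram system is solved directly by Cholesky
factorization — all constraint gradients are incorporated simultaneously —
with a Tikhonov fallback `ε = 1e-10·tr(G)/A` if factorization fails, and a
rank-deficiency error (carrying an SVD-based rank report) when even the
regularized system is singular.  The Jacobian is re-evaluated at every
iterate (full Newton iteration on `σ(x) = 0`); a `refresh_jacobian=False`
flag freezes it at the trial point, reproducing the classic SHAKE
linearization.  No mass weighting is applied (unit masses).  The default
violation acceptance is `tol = 0.003` in Å-equivalent units.

Sign convention: solving `Gλ = −σ` makes `+Jᵀλ` the descent (Newton)
correction; the update with the opposite sign moves away from the manifold
and diverges, which is easy to verify on a single two-atom distance
constraint.

Noise is optionally restricted to the constraint tangent space before the
trial step with the projector

    P = I − Jᵀ(J Jᵀ)⁻¹ J,

the multi-constraint generalization of removing the component along a
single constraint gradient.  `P` is idempotent, annihilates every
constraint-normal direction, and requires full row rank of `J` (an SVD
check raises otherwise).  Because projected noise is only tangent to first
order, the position projection after the step remains necessary; its
correction is second order in the step size.

## Time-dependent bounds

Bounds interpolate from loose initial values to strict final values under
a logistic schedule `s(t) = 1/(1 + e^{−β(t−t₀)})` of the normalized
sampler progress `t ∈ [0, 1]` (reverse diffusion runs physical time
`T → 0`; schedules are parameterized by increasing progress).  Defaults
`β = 10`, `t₀ = 0.5`.  Two numerical choices matter:

- **Endpoint normalization.**  The interpolation uses
  `ŝ(t) = (s(t) − s(0)) / (s(1) − s(0))` so the bounds reach the final
  strict values *exactly* at `t = 1`.  A raw logistic with β = 10 attains
  only s(1) ≈ 0.993, which would leave a residual ±0.07 slack window open
  at the last step and break the holonomic limit that coincident bounds
  are meant to produce.
- **Unbounded initial bounds.**  An unbounded (`None`) endpoint is not a
  large float (which would overflow the linear interpolation); while
  `ŝ ≤ 1e-6` the bound is reported as ±∞, after which it recedes as
  `final ∓ unbound_scale·(1 − ŝ)/ŝ` (default scale 10 Å) — finite,
  monotone, and converging to the final bound.

The deterministic bound trajectory has a closed form, so the per-step
bound update evaluates it exactly; the result is independent of how the
interval is partitioned into steps (no integrator error in the
deterministic component of the coupled stochastic–algebraic system).

## Sampler

The constrained formulation assumes a feasible initial condition (the
existence results for the coupled stochastic–algebraic system start from a
point on the manifold), so with the projection method the prior draw is
first projected onto the initially-active constraint manifold — scheduled
constraints are typically still unbounded at the start and contribute
nothing to this initialization.  Then, per step: (1) advance the
schedules, (2) optionally project the noise increment onto the tangent
space of the currently active constraints (default on for the projection
method, off for guidance), (3) take an Euler–Maruyama trial step,
(4) apply position projection, guidance, or nothing.  The trajectory log
records per-step corrections only; initialization is not a step.
Identical seeds give bit-identical trajectories.  Per-step
diagnostics (max/mean bound violation, correction norms, iteration counts)
are logged to a trajectory record exportable as CSV.

Two stepping modes are keyed by the score model:

- **Reverse SDE** (`dx = [f − g²∇log p_t] dt + g dW̃`), used with the
  built-in Gaussian-mixture score, which is the *exact* noised score of an
  isotropic mixture under the chosen noise schedule
  (variance-exploding, σ: 0.01 → 5 geometric, default; or
  variance-preserving, linear β: 0.1 → 20).  The prior at t = 1 is sampled
  exactly from the noised mixture, so the only error is time
  discretization.
- **Annealed Langevin** (`x ← x + D s dt + √(2D dt) η`), used with the
  Boltzmann surrogate score `s = −∇U/k_B T(τ)` (k_B = 1, reduced units;
  default geometric anneal T: 5 → 1).  For a frozen score the stationary
  law of this dynamics is `exp(−U/k_B T)` — a harmonic well `½k(x−x₀)²`
  equilibrates to variance `k_B T/k`, which the test suite verifies by
  Monte Carlo.  The reverse-SDE `g²` drift factor is *not* used here: it
  is only correct for true time-dependent scores and would square the
  density of a frozen one.  The Boltzmann score is an annealing surrogate,
  not an exact noised score, and is documented as such.

The score is treated as exact on the constraint manifold; no
Fixman/co-area density correction is applied (known limitation — the
sampled law on the manifold carries the ambient-to-surface Jacobian
factor uncorrected).

## Guidance baseline

Soft constraint handling adds the gradient of a quadratic penalty
`U = Σ (k_a/2) σ_a²` with step size γ, each constraint treated
independently (no coupling solve).  Defaults `k = 10` (energy/Å²),
`γ = 1e-3`, one inner iteration per sampler step — stable but visibly
under-correcting, which is the regime in which a soft baseline is
informative.  Guidance provides no tolerance guarantee: a two-constraint
tug-of-war (shared atom pulled both ways) leaves residuals above the
acceptance in a single pass where the coupled solve converges.

A structural note established during benchmarking: once guidance
equilibrates against an opposing score drift, its per-step force equals
the normal component of that drift — which the projection must also
cancel, on top of second-order noise-curvature corrections — so the two
methods' per-step correction magnitudes are close at these defaults.  The
mean guidance correction does exceed the projection method's over a long
butane run (the projection's corrections die off with the annealed noise
while guidance keeps pushing), but only once initialization is excluded
from the comparison: counting the one-off projection of the broad prior
draw as a "step correction" would swamp the mean, which is one more
reason the sampler treats feasible initialization as separate from
stepping.  The robust discriminator between the methods remains the
constraint error, which is orders of magnitude larger for guidance.

## Constraint mining

Conformer ensembles are featurized as flattened upper-triangular pairwise
distance vectors (`m = n(n−1)/2` per conformer), partitioned with k-means
(k-means++ init, 10 restarts, fixed seed), and each cluster's pairs are
ranked by the significance `Δ_k(i,j) = |x̄_k(i,j) − x̄(i,j)|` — the
deviation of the cluster-mean distance from the global mean.  The top-T
pairs with cluster-mean targets form that cluster's constraint set; ties
break lexicographically by pair.  Because targets are means of distances
that co-occur in real cluster members, the sets are simultaneously
satisfiable: projecting a cluster member onto its own top-T set converges
in a few iterations.  An optional bounded mode emits
`slack_max = within-cluster standard deviation` per pair.  A PCA variant
ranks pairs by |loading| per principal component of the centered features
and reports the extreme-scoring conformer as that component's
representative.  The number of clusters corresponds to the number of
conformational minima and is supplied by the caller; a silhouette-score
helper exists purely as a convenience heuristic.

## Synthetic data

All inputs are generated programmatically:

- **Chain builder** — bond lengths/angles/torsions to Cartesian placement
  (extension-frame construction); measured internals round-trip to 1e-8.
- **Butane fixture** — 4-carbon skeleton with standard alkane geometry
  (C–C 1.53 Å, C–C–C 112.5°; fixture constants, with an optional
  explicit-hydrogen decorator).  The anti skeleton's C1–C4 distance is
  3.91 Å; the constraint sets pair an end-to-end target (3.9 Å staggered /
  3.15 Å eclipsed) with the three C–C bonds at equilibrium, so the
  end-to-end target cannot be met by stretching bonds.
- **Toy energy** — harmonic bonds (k = 300 kcal/mol/Å²) and angles
  (k = 60 kcal/mol/rad²) plus Lennard-Jones on 1-4 and more distant pairs
  (ε = 0.25, σ_LJ = 3.4 Å), chosen so the staggered butane geometry has
  lower energy than the eclipsed one.  The energy path is smooth-tolerant:
  collinear angle frames use a clamped (bounded, continuous) gradient and
  LJ terms evaluate at `max(r, 0.8 Å)` (soft core), so the hot,
  near-random start of annealed sampling cannot produce divergent forces;
  constraint evaluation keeps strict degenerate-geometry errors.
- **Two-mode ensembles** — conformers drawn from jittered
  internal-coordinate modes (defaults: 5° torsion, 1° angle, 0.005 Å bond
  jitter — tight vibrational noise around well-separated torsional
  minima), with ground-truth mode labels recorded.

What the generator does *not* emulate: real force-field energetics,
solvent, hydrogens' steric detail, or the breadth of conformer diversity
a learned model produces.  Passing tests therefore demonstrate the
correctness of the constraint/projection/sampling machinery and the
qualitative method comparisons, not chemical accuracy on real molecules.

## Study configurations and problem sizes

The shipped experiments (shared by the CLI, the test suite and
`scripts/acceptance.py`) use: a 6-atom chain with 5 bond constraints,
1000 steps × batch 16, for the per-step violation-acceptance check;
2000 steps × batch 64 for the eclipsed-butane steering run (sigmoid
schedule β = 10, t₀ = 0.5, Langevin dt = 0.002); 240 conformers for the
torsion/distance correspondence; and a 10-atom chain with 10 mined
constraints, 500 steps × batch 32 × 5 seeds, for the guidance-vs-
projection error benchmark.  In that benchmark the constraints come from
the *folded* cluster of a two-mode ensemble while the score's energy
minimum is the extended chain, so the score persistently opposes the
constraints — the regime in which independent harmonic updates
under-correct (mean per-constraint error ~0.3 Å) while the multiplier
solve holds residuals at the 1e-4 Å scale.

## Known limitations

- No Fixman/co-area correction: densities on the manifold are biased by
  the constraint Jacobian factor.
- Guidance hyperparameters are global, not per-constraint-adaptive.
- Active-set resolution is instantaneous per step; no anti-chattering
  hysteresis (not needed at the step sizes used here).
- The explicit-hydrogen butane builder is geometric only; no H-involving
  energy terms are parameterized.
- 2D systems are supported for toy densities; dihedrals require 3D.
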