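# shakediff

Exact geometric constraints in score-based diffusion sampling via
SHAKE-style manifold projection.

Diffusion models sample molecular conformations by integrating a
reverse-time SDE driven by a score function, but nothing guarantees the
results respect known geometry — bond lengths, target interatomic
distances, torsional preferences.  `shakediff` enforces such requirements
*exactly*: every stochastic step is projected onto the manifold defined by
a set of holonomic constraints `σ_a(x) = 0` by solving the
Lagrange-multiplier (Gram) system

    Σ_b λ_b (∇σ_a · ∇σ_b) = −σ_a ,      x ← x + Σ_a λ_a ∇σ_a ,

iterated until every residual is below a violation acceptance (0.003 Å by
default).  Around this core the package provides:

- **Constraint primitives** — distance / angle / dihedral constraints with
  analytic gradients, stacked Jacobians and SVD rank diagnostics;
- **Tangent-space noise projection** — `P = I − Jᵀ(JJᵀ)⁻¹J` applied to the
  noise increment so the stochastic step stays (to first order) on the
  manifold;
- **Sigmoid bound schedules** — time-dependent lower/upper bounds that
  tighten from unbounded to strict over the course of generation, with
  active-set resolution of bounded constraints via slack variables;
- **A reverse-SDE sampler** with pluggable scores (exact Gaussian-mixture
  scores under VE/VP noise schedules; an annealed Boltzmann surrogate
  `−∇U/k_BT(τ)` for energy-driven toys) and per-step trajectory logging;
- **A harmonic-guidance baseline** (independent penalty-gradient updates,
  no coupling solve) for method comparison;
- **Constraint mining** — k-means clustering of flattened pairwise-distance
  vectors over a conformer ensemble, ranking atom pairs by the deviation of
  cluster means from the global mean (plus a PCA-loading variant), to
  derive constraint sets that real conformers actually co-satisfy;
- **Geometry fixtures** — an internal-coordinate chain builder, a toy
  chain force field, two-mode conformer ensembles and a butane test system;
  everything is generated programmatically, no downloads.

Intended users: method developers in molecular machine learning and
structural bioinformatics who need a reference implementation of
constrained diffusion sampling, and anyone who wants to steer a toy
generative process with hard geometric conditions.

## Worked example: steering butane between conformers

Butane's torsional conformers map almost uniquely onto the C1–C4
distance: ≈3.9 Å for the staggered (anti, 180° torsion) form and 3.15 Å
for the eclipsed form.  Constraining that single distance (plus the three
C–C bonds at equilibrium, so the target cannot be met by stretching
bonds) steers generation to either conformer:

```python
from shakediff.experiments import butane_generation

res = butane_generation(target="eclipsed", method="shake",
                        n_steps=1000, batch=16, seed=0)
print(f"mean C1-C4: {res['d14'].mean():.3f} A  (sd {res['d14'].std():.4f})")
print(f"final max residual: {res['result'].trajectory.max_residual[-1]:.2e}")
```

prints

```
mean C1-C4: 3.150 A  (sd 0.0000)
final max residual: 3.91e-04
```

— the batch mean lands on the 3.15 Å eclipsed target and the final
constraint violation is below the 0.003 Å acceptance.  The
`examples/` directory holds one short script per capability
(projection, constrained sampling, conformer steering, mining,
guidance comparison, scheduled 2D bounds); each prints the numbers it
computes and a line on what they mean.

A thin CLI wraps the same machinery:

```bash
shakediff demo butane --method shake --target staggered --steps 1000 \
    --batch 16 --out butane.xyz --trajectory traj.csv
shakediff mine --ensemble conformers.xyz --clusters 2 --top 5 --seed 0 \
    --out constraints.yaml
shakediff analyze --trajectory traj.csv
```

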