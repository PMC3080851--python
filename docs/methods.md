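# Methods

## Model

A cuboidal block of lung parenchyma is idealized as a space-filling tiling of
polyhedral cells, each cell one alveolus.  Two tilings are implemented: simple
cubic cells and tetrakaidecahedra (truncated octahedra, 6 squares + 8 regular
hexagons) on a body-centred lattice.  Every polygonal wall carries springs
from its centroid to each of its vertices ("face springs"); every geometric
edge of the tiling carries a single shared "edge spring" representing the
septal junction line.  The 8-per-side cubic block has 512 cells, 1728 faces
and 8856 springs (4·1728 face springs + 1944 edge springs).

Springs are tension-only: force develops only at positive engineering strain
ε = (L − L0)/L0, either linearly, f = k·ε, or by a monotone power law
f = A·ε + B·ε^p.  Because such a network cannot support compression it is
stabilized by a uniform pre-strain: all node positions are scaled about the
box centre by a factor λ0 (default 1.2, i.e. 20% linear strain) with rest
lengths unchanged, and the outer surface (boundary vertices and boundary face
centres) is held fixed.

The 14-hedral tiling is clipped to the cuboid: cells whose centres fall
outside are discarded, cells straddling the surface are cut by the box planes
and capped, so the block is watertight and the cells exactly fill the box.
Clipped boundary cells are smaller than the bulk cells; volume statistics are
therefore normalized by the mean initial cell volume (box volume / cell
count), which reduces to the single-cell volume on cubic lattices.

## Energies, boundary conditions and equilibration

The total energy is the sum of spring energies ∫ f dε per spring (the
default "extension" form makes a linear spring's energy (k/2)(L−L0)²; a
"strain" form (k/2)L0·ε² is available — normalized outputs are insensitive
to this global prefactor), plus boundary work terms:

* fixed — boundary nodes immobile;
* force — constant external nodal forces, energy −Σ F·x, all nodes free;
* pressure — energy +P·V with V the volume enclosed by the exterior surface;
  P acts on the fan-triangulated boundary faces as nodal forces −P·S/3 per
  triangle node (for a closed surface this equal split is the exact gradient
  of P·V).  An outer loop refreshes the facet forces as the geometry changes
  until the free energy is stationary.

The energy surface is convex (verified by annealing cross-checks), so
equilibria are found by gradient methods with analytic gradients.  The
default solver is L-BFGS; a plain gradient descent with Armijo backtracking
is provided and reaches the same minimum (tested to 1e-6 relative), as does
a seeded Metropolis simulated-annealing minimizer used purely as an
independent cross-check on small fixtures (agreement to 1e-4 relative).
Convergence requires both the maximum and the mean resultant-force magnitude
over free nodes to fall below thresholds (defaults 1e-6 and 1e-7 in units of
k·cell_size).  Two numerical details matter near these tight tolerances: the
external-work term is measured relative to the iteration's starting
positions (a constant shift that keeps the objective small compared with the
float64 resolution of the line search), and a damped fixed-step gradient
polish runs after L-BFGS stalls.  Nodes whose incident springs are all
broken (centres of removed walls) are frozen and excluded from the force
criteria.

## Destruction

Walls are removed Nf at a time (default 4) from the internal faces only —
the boundary must stay closed.  Three policies: random (uniform without
replacement); force-based (the Nf highest-load eligible walls, where a
wall's load is the sum of its face-spring tensions; ties broken by the
seeded RNG; the first step is always random — the spatially random initial
seed of destruction); and mixed (round(r·Nf) by force, the rest at random).
With r = 0.1 the mixed scenario uses Nf = 10 so that exactly one wall per
step is load-selected; with the default Nf = 4, round(0.1·4) = 0 would
degenerate to pure random.  Removing a wall breaks its face springs; an edge
spring breaks once every wall adjoining its edge is gone.

A run loops select → remove → re-equilibrate (fixed boundary) → measure,
stopping at K/K0 ≤ 0.3, on wall exhaustion, or when the whole block has
merged into one airspace (after which there is no volume distribution left
to track; random destruction reaches this state while still fairly stiff at
the scales used here).  Runs are bit-reproducible from the policy seed.

## Measurements

Airspaces are clusters of cells connected by removed walls
(union–find/connected components).  Volumes come from the divergence
theorem: every face is fanned into triangles about its centre node and the
signed tetrahedron volumes (apex at the origin) are summed with build-time
outward orientations; a shared intact wall cancels between its two cells, so
summing per-cell signed contributions over a cluster yields exactly its
boundary-surface volume, valid for non-convex shapes.  Under the fixed
boundary the cluster volumes sum to the box volume to 1e-6 relative at every
damage state (a standing invariant).  Per step the mean μ and the central
moments m2–m4 of the normalized cluster volumes are recorded.

The bulk modulus is probed as in an excised-tissue experiment: the resultant
spring force on each boundary node is balanced by an equal-and-opposite
constant external force, the boundary is released (the state remains an
equilibrium), a small distending pressure ΔP (default 1% of the recoil
scale k·ε0/cell) is superposed on the exterior surface, the network
re-equilibrates, and K = ΔP/(ΔV/V0).  The probe restores the network state
and is linear (halving ΔP moves K by <0.5%) and repeatable (<0.1%).

Because the probe freezes the pre-existing boundary reactions as constant
forces before adding ΔP, the analytic comparator for the intact lattice is
the affine-restricted stiffness K = C/(9·V_built·λ0), where C = d²U/dλ² of
the affine energy; per unit cubic cell C/V = 9k, giving the infinite-lattice
value k/λ0 (0.8333 at λ0 = 1.2).  (The pressure-path formula
C(2−λ)/(9Vλ²) describes a geometry-following pre-pressure and is *not* what
this probe measures.)  Finite blocks deviate by O(1/n) surface terms —
boundary-spring excess stiffens, face-centre bulging under facet pressure
softens — which largely cancel: measured 0.811 (4³), 0.828 (6³), 0.835 (8³)
against 0.8333.  Two exact oracles close the loop in the tests: a
closed-form two-parameter symmetric-family energy for the single cube (the
released cube's equilibrium lies in that subspace by octahedral symmetry)
and a finite-difference-Hessian linear-response solve on a 2³ block.

## Structure–function analysis

Stacking the per-step moments of one or more runs into a matrix M (rows =
steps, columns = μ, m2, m3, m4), the KL (PCA) basis is the eigensystem of
the column covariance matrix (columns centred, not rescaled; eigenvector
signs fixed so the largest-magnitude entry is positive).  Projections P1, P2
onto the two leading eigenvectors — computed with the basis means, which is
essential when projecting new runs onto a fixed basis — feed the
least-squares plane K̂/K0 = a·P1 + b·P2 + c.  `crossfit_evaluation` fixes
basis and plane on chosen source runs and scores every run by the relative
error 100·|K̂−K|/K (max/median/quartiles per run).  The same machinery is
wrapped statsmodels-style as `StiffnessPlaneModel(...).fit()` returning a
results object with `params`, `resid`, `rsquared`, `predict` and
`summary()`.

## Study conditions (defaults of the scenario suite)

* Base ensemble: 6-per-side cubic block (216 cells, 540 internal walls),
  pre-strain 1.2, linear springs with k = 1, Nf = 4, three random + three
  force-based seeded replicates, run to K/K0 ≈ 0.3.
* Held-out variants: force-based at 1.5× pre-strain (ε0 0.2 → 0.3, factor
  1.3), force-based on a 14-hedral block (n = 3, 91 cells), force-based on a
  128-cell block (4×4×8), force-based with power-law springs (p = 3, A = k,
  B set so the tangent stiffness doubles at ε = 0.3 — any monotone choice
  leaves the cutting order unchanged), mixed with r = 0.1, and random at
  1.5× pre-strain.
* Pattern-contrast ensemble: 3 force + 3 random runs continued past full
  merging to K/K0 ≤ 0.35, from which the removed-wall counts at K/K0 = 0.4
  and the mean/variance orderings at a matched wall count (20% of internal
  walls, within the growth phase) are computed.

These sizes keep the full suite around 5 minutes on one CPU.  All
randomness flows from one master seed through per-scenario crc32-derived
sub-seeds.

## What the synthetic scenarios do and do not show

The generator emulates the geometry and quasi-static mechanics of
pre-stressed parenchyma with tension-only walls; it omits surface tension,
alveolar ducts and the axial fibre system, inertial/viscoelastic dynamics,
and any coupling to the chest wall, and its blocks are orders of magnitude
smaller than real tissue samples.  Passing tests therefore validate the
implementation of this model, not the physiology of real lungs.

A known limitation of the reduced scale is that the stiffness-vs-structure
estimator is much weaker than the idealized expectation: within a single
run, K/K0 is nearly linear in the four moments (R² ≈ 0.9–0.98), but the
moment→stiffness mapping differs strongly between random and force-based
patterns (at equal volume variance a force-damaged block is considerably
softer), and the moments are strongly convex in the removed-wall count, so
the pooled two-component plane fit carries large errors.  This persists at
the 512-cell scale and across many alternative moment definitions, and
plausibly depends on the number of walls removed per step (which sets how
many cavities seed the correlated pattern); the per-step removal count is
kept at its stated default rather than adjusted.  The acceptance suite
reports the measured errors as they are.

## Numerical choices and degenerate inputs

Tolerances: spring-count/volume invariants at 1e-9 to 1e-6 relative;
equilibrium force thresholds as above; probe ΔP in the linear-response
regime.  Tie-breaks in force selection are RNG-seeded; eigenvector signs are
fixed deterministically.  Degenerate inputs are rejected with `ValueError`
(non-positive sizes or strains ≤ 0 pre-strain factors, removed or boundary
walls in selection/removal, collinear plane fits, open surfaces in the
volume engine); network exhaustion raises a dedicated signal that the run
loop converts into a clean stop.
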