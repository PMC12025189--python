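# Methods

This note documents the models behind `stemlattice`, the assumptions they
make, the defaults and why, and what the tests do and do not establish.

## Problem

A femoral-stem implant that is much stiffer than the bone around it carries
load past that bone. Bone adapts to mechanical stimulus, so chronically
understressed bone resorbs — the *stress/strain shielding* pathway to
implant loosening. One mitigation is a porous stem whose local density (and
hence stiffness) is graded to keep the surrounding bone loaded. The package
designs such density fields, learns to predict them directly from implant
geometry with a neural network, evaluates the resulting implants for strain
shielding and strength against solid and uniformly porous controls, and
renders the field as a printable density-graded gyroid lattice.

## Homogenized gyroid material

The porous material is a *sheet gyroid*: the minimal surface thickened by a
wall thickness `t`. At the continuum scale its behavior is captured by two
cubic scaling laws in the local solid volume fraction `vf`:

    E*/Es     = 0.1018 vf^3 + 0.4388 vf^2 + 0.2405 vf
    σ*/σs     = 0.5545 vf^3 + 0.1250 vf^2 + 0.4666 vf

with Ti-6Al-4V as the solid (Es = 110 GPa, σs = 850 MPa, ν = 0.3). Both
laws vanish at `vf = 0` and are strictly increasing. Note that the yield law
evaluates to 1.1461 at full density — slightly above the solid yield. This
is an artifact of the published fit; we apply the law as printed, since the
strength comparisons are relative between variants using the same law.

The density update map of the optimizer is the *numerical inverse* of the
yield law (safeguarded Newton, residual ≤ 1e-12, clamped to [0, 1]); the
forward law is cheap and monotone, so no closed-form inverse is needed.

## Implant geometry

Nine parameters describe one design (ranges and full-factorial level counts
in `geometry.DESIGN_RANGES`/`DESIGN_LEVELS`; the level grid has 480,000
combinations). The outline is a stack of four straight-edged quadrilateral
patches: solid distal block (φ2 × hdist), porous remodeling band (height
hrem), solid neck parallelogram (width φ1, length Ltap at θ above the
horizontal), and solid taper block (height htap). Conventions chosen here:

- θ is measured from the horizontal +x axis. This makes the printed offset
  formula exact by construction — the taper's top medial corner sits at
  `offset = L1 − φ2/2 + Ltap·cosθ + (φ1/2)·sinθ` — and a 40–50° angle
  matches the anatomical neck-shaft angle (~130° from the shaft).
- α inclines the band's *lateral* edge by (α − 90°) from vertical, while the
  medial edge runs straight from the distal block's medial corner to the
  neck base, so the neck always lands on the band. A strongly inclined
  lateral edge over a long band can cross the neck base; such parameter
  combinations are flagged infeasible (returned as `None`), mirroring the
  fact that only a subset of a random design draw is geometrically valid.
- Meshing is ruled interpolation between each patch's bottom/top edges with
  shared boundary nodes, 4-node quads, 2×2 Gauss points. Feasibility
  additionally requires a simple outline polygon and positive Jacobians.

The *extended* design space widens the remodeling band into a convex
trapezoid bounding the conventional band (default 10 mm beyond it at the
top on both sides), leaving the solid parts unchanged. It exists to test
whether the optimizer, unconstrained by anatomy, recovers the anatomical
solution (it does not, which is why the shielding studies use the
conventional model).

## Finite element solver

Linear elasto-static plane strain, per-integration-point Young's modulus,
uniform ν, plane-strain thickness 35 mm. The default element is the
bilinear quad augmented with Wilson/Taylor incompatible bending modes
(statically condensed; bubble gradients mapped with the element-center
Jacobian and volume-mean subtracted so the distorted patch test passes to
machine precision). Plain Q4 shear-locks — on the 20:1 cantilever at a
20×2 mesh it reaches only ~71% of the beam-theory deflection, versus ~99.5%
for the incompatible-modes element — which would poison every
stiffness-sensitive result downstream; `element="bilinear"` remains
available for comparison. Equivalent measures: von Mises stress with σzz =
ν(σxx+σyy), and the deviatoric von Mises strain with the 2/3 prefactor
(reduces to the axial strain in the incompressible uniaxial state). The
strain-shielding measure is a ratio of like measures, so the prefactor
convention cancels.

## Remodeling optimizer

Starting fully solid, each iteration solves the FEM problem, ranks the
band's integration points by von Mises stress, raises the density of the
top `α` fraction and lowers the bottom `β` fraction through the inverse
yield law (`raise` uses max(current, law), `lower` uses min(current, law)),
clamped to [vf_min, 1]. Iteration stops at a control average band density,
on stagnation, or at an iteration cap. Two numerical refinements:

- Points clamped at a bound are not selection candidates. Without this the
  same already-minimal points are re-selected forever and the loop stalls
  far above the control density.
- The last reduction step is truncated (bisection on the number of lowered
  points) so the area-weighted mean lands at the control density instead of
  overshooting by up to β·(1 − vf_min).

Defaults: α = β = 0.05 (small steps approximating continuous adaptation),
control density 0.6, vf_min = 0.1 (keeps the stiffness matrix well
conditioned and the lattice printable), cap 100 iterations, stagnation
tolerance 1e-4. The loop contains no randomness; identical inputs give
identical fields. Loading for the stand-alone implant: distal base pinned,
2300 N axially downward at the taper.

## Surrogate

A multilayer perceptron maps eleven inputs — the nine design variables plus
the evaluation point's (x, y) — to the local optimal volume fraction, all
inputs min–max scaled to [0, 1] with bounds fitted on training rows only
(the target is a volume fraction and needs no scaling). The corpus holds
one row per remodeling-band integration point of each remodeled instance;
the 85/15 train/validation split is at the *instance* level so whole
implants are held out (point-level splits would leak geometry). When a
small corpus leaves a design variable constant on the training rows, its
published range substitutes for the degenerate fitted bound — a-priori
domain knowledge, not leakage.

Training: Adam on MSE, learning rate 1e-3, batch size per the searched
spec, up to 100 epochs with patience-5 early stopping on the validation
loss and best-epoch weight restoration. Hyperparameters (1–5 hidden layers,
32–256 neurons, tanh/ReLU/sigmoid, batch 32–256) are searched sequentially:
random warm-up, then a Matérn-kernel Gaussian process proposing the
expected-improvement maximizer; candidates train 10 epochs and are ranked
by validation MAE. A pure random strategy is available. Field prediction
clamps the output to [vf_min, 1] and forces solid regions to 1.

## Femur models and strain shielding

No patient imaging is used; the proximal femur is a **synthetic proxy**:
the implant outline dilated by a 14 mm bone margin (6 mm cortical shell
tagged by distance to the outer surface, trabecular interior) plus a 30 mm
distal shaft extension. Bone moduli: cortical 17.5 GPa, trabecular 5 GPa.
The model is meshed as one structured grid in which elements are tagged
implant/cortical/trabecular by centroid; bone and implant therefore share
every interface node (perfect bonding), at the price of a staircase
interface. The intact and implanted variants use the *identical* grid, so
the shielding measure

    φ̄ = (φ_intact − φ_implanted) / φ_intact

is evaluated at exactly matched integration points, with φ the equivalent
von Mises strain under the same 2300 N axial load applied at the same node
(femoral head / taper top). Points with intact strain below 1e-9 are masked
and counted, not classified. Classification against the reference stimulus
s = 0.6: φ̄ > s resorption, φ̄ < −s formation, the closed band [−s, s] is
the lazy zone. Area fractions are weighted by integration-point area over
the bone region and partition to 1.

Three implant variants are compared per design: solid (vf ≡ 1), uniform
(the graded field's area-weighted mean band density everywhere), and graded
(remodeled or network-predicted). Strength: a 10 mm vertical displacement
is imposed at the load point; with elastic–perfectly-plastic material and
apparent yield `g1(vf)·σs`, the pre-yield response is linear, so the
first-yield load is the elastic reaction scaled by the worst implant
point's yield margin (capped at the full-displacement reaction). A 100-step
incremental ramp oracle validates this within 1%. The strength delta is
F̄ = (F_uniform − F_graded)/F_uniform; negative values mean the graded
implant is stronger.

Because the femur proxy is synthetic, cohort-level percentages (shares of
designs with less resorption or more formation than the solid control)
are *qualitative* outputs of this geometry, not reproductions of any
published cohort numbers; the tests assert structural properties
(partitioning, nonempty distributions, exact-zero controls), not shares.

## Gyroid rendering and the density-thickness law

The implicit gyroid `sin(πx/L')cos(πy/L') + sin(πy/L')cos(πz/L') +
sin(πz/L')cos(πx/L')` repeats every `2L'`. Throughout the measurement and
rendering API, `L`/`cell_size` denote the **periodic** unit-cell size, and
the implicit function is evaluated at `L' = L/2`; with that convention the
normal-offset sheet's apparent density follows `ρ ≈ 2.868·t/L`.

`measure_density` integrates the sheet volume on a cell-centered grid using
the Euclidean distance to the surface: clamped Newton projection along the
local normal where it converges (near the surface; residual ≤ 1e-6·L), and
distance to a dense triangulation of the surface beyond 0.25 L, where the
projection path curls. `density_thickness_slope` fits `vf = slope·(t/L)`
through the origin over densities 0.1–0.9; thickness values are chosen a
priori from the linear law ("law" rule, default), or by spanning the
measured distribution ("quantile" rule). At 128³ the two rules agree within
0.5% (2.82 / 2.79 for L = 1); the measured slope sits ~2% below 2.868
because the normal-offset sheet saturates faster than the linear law at
high density.

`render` extrudes a 2D density field by `extrusion_depth`, assigns each 3D
sample the volume fraction of its nearest (2D) integration point, converts
it to a wall thickness, and extracts the zero level set of
min(domain signed distance, sheet membership) with marching cubes — a
closed, watertight triangulation by construction. Solid implant regions and
band points above `vf_ceiling` (default 0.99) are emitted fully solid;
points below `vf_floor` (default 0.1) are clamped; walls thinner than two
grid spacings trigger a warning with the affected column count. Export is
ASCII STL or legacy VTK.

## What the synthetic world does and does not establish

The generator emulates: the published design-variable grid, feasibility
attrition of random draws, stress-adaptive density grading, and the
relative mechanics of solid/uniform/graded variants on a consistent femur
proxy. It does not emulate: real femoral contours or cortical thickness
variation, bone anisotropy/heterogeneity, implant–bone friction or
micromotion, 3D load paths (plane strain with 35 mm thickness throughout),
or manufacturing deviations. A green test therefore establishes internal
correctness and the claimed scaled-down learning behavior — not clinical
performance.

## Known limitations

- The bone–implant interface is a voxel staircase at the femur grid
  resolution (default 3 mm); shielding fractions shift slightly with grid
  resolution, which is acceptable because all variants share the grid.
- The yield-load estimate addresses first yield only; no post-yield
  redistribution or hardening.
- The remodeling rule is a heuristic rank-and-update scheme, not a
  compliance-gradient optimizer; it is implemented as specified rather than
  replaced by SIMP-style methods.
- `vf_from_stress_ratio` clamps stress ratios above the yield law's value
  at full density; extremely stressed points simply become solid.
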