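# Methods

## The discrete OMT model

The brain domain M is a simplicial 3-complex with a single genus-zero
boundary. A per-vertex density ρ > 0 induces piecewise-linear simplex
densities by averaging — ρ(α) over a boundary triangle's 3 vertices, ρ(τ)
over a tetrahedron's 4 — and local masses

    a_ρ(v̂) = ⅓ ρ(v̂) Σ_{v̂⊂α} |α|,      m_ρ(v) = ¼ ρ(v) Σ_{v⊂τ} |τ|.

These satisfy Σ_v m_ρ(v) = Σ_τ ρ(τ)|τ| and the boundary analogue as exact
algebraic identities, which the test suite asserts to 1e-12 relative. The
complex is centralized and rescaled so the ρ-weighted center of mass is at
the origin and the total mass is one; the affine is retained so results map
back to scanner coordinates.

A map g : ∂M → ∂C³ (C³ = [-½, ½]³) is area-measure-preserving when
ρ(α)|α| = |g(α)| for every boundary face; f : M → C³ is
volume-measure-preserving when ρ(τ)|τ| = |f(τ)|. Among such maps we seek
minimizers of the quadratic transport costs d_ρ(g) = Σ ‖v̂ − g(v̂)‖² a_ρ(v̂)
and c_ρ(f) = Σ ‖v − f(v)‖² m_ρ(v).

## Boundary map (A-OMT)

The cubic boundary map is a composition g*_ρ = (h*₁)⁻¹ ∘ h*_ρ of two
spherical maps: h*_ρ of the brain boundary with density ρ and h*₁ of a
reference triangulation of the cube surface with uniform density. Each is
computed by projected descent on the area-weighted stretch energy
E_S(g) = ½ Σ_t (gᵗ)ᵀ L_S(g) gᵗ, whose Laplacian weights divide image corner
cotangents by the face stretch factor σ_{g⁻¹}(α) = ρ(α)|α|/|g(α)|. Two
properties make this energy the right objective: E_S(g) equals
Σ_α |g(α)|²/(ρ(α)|α|) identically, so its constrained minimizers equalize
the per-face mass ratios (Cauchy–Schwarz), and its gradient is exactly
2 L_S(g) g — both verified in the tests by finite differences.

Numerical choices:

- **Iteration.** Jacobi-preconditioned gradient steps with heavy-ball
  momentum (β = 0.9), projection onto the unit sphere after every step, and
  monotone acceptance: a step that increases the energy first drops the
  momentum term, then halves the step size. Plain projected gradient needed
  several thousand iterations on ~10k-vertex boundaries; the preconditioned
  momentum variant reaches a 5–95% stretch spread of a few percent within
  the default 400 iterations.
- **Initialization.** Radial projection of the centered boundary. If more
  than 5% of spherical triangles start folded, uniform-weight smoothing on
  the sphere is applied first. Phantom and voxel-cube boundaries start with
  essentially no folds.
- **Gauge.** The spherical minimizer is unique only up to rotation. The
  gauge is fixed by rotating the sphere image so the principal axes of the
  ρ-area-weighted boundary align with the cube axes (eigenvector signs fixed
  by their largest component, proper rotation enforced). When the spectrum
  is near-degenerate (relative spread < 2%) the rotation is skipped, so
  symmetric domains — notably the cube self-map — keep the identity gauge
  instead of an arbitrary axis permutation.
- **Boundary mass normalization.** The total ρ-weighted boundary area is
  rescaled to the cube's surface area (6), making the per-face ratios
  ρ(α)|α|/|g(α)| directly comparable to 1. The volume normalization fixes
  the enclosed mass, not the boundary area, so this extra scaling is needed
  for a well-posed area constraint.
- **Reference surface and inversion.** The cube surface is triangulated
  with an n×n vertex grid per face (default 33). Queries are located in the
  spherical image of this mesh by nearest-centroid candidates plus
  triple-product sign tests (ties broken by lowest face index, with a
  widened tolerance pass for points grazing an edge), pulled back with
  gnomonic barycentric weights, and snapped exactly onto the cube face
  plane. Finer grids sharpen the inverse at linear cost.

## Interior map (V-OMT)

With the boundary pinned, the interior solves a mass-weighted Laplacian
system. For each tetrahedron edge (v_i, v_j) with opposite edge (v_l, v_m)
the weight couples the two image faces not containing the endpoints,

    w_ij = −(1/9) |f([v_i,v_l,v_m])| |f([v_j,v_m,v_l])| cos θ / (ρ(τ)|τ|),

θ the dihedral angle between those faces along their shared image edge.
With outward image face normals N (|N| = 2·area) this collapses to
w_ij = (N_oppi · N_oppj)/(36 ρ(τ)|τ|): the linear-element stiffness matrix
of the image mesh with each tetrahedron's volume replaced by its source
mass. The diagonal is the negative row sum (the off-diagonal formula alone
does not determine it; the constant-kernel convention makes the Dirichlet
problem well posed).

The homotopy g_ζ(v̂) = (1−ζ) v̂ + ζ g*_ρ(v̂) is followed on a uniform
partition of [0, 1] with p steps (default p = 11, the partition at which the
total mass distortion bottoms out; the acceptance script reproduces the
p = 1 vs p = 11 comparison). At each step the operator is assembled at the
previous iterate and the interior block is solved directly (sparse LU) up to
60k interior vertices, and by Jacobi-preconditioned conjugate gradients
warm-started from the previous iterate above that, with the relative
residual checked against 1e-8 in both paths.

Quality is reported, never repaired: the transport cost, the total mass
distortion d_M(f) = Σ_τ |ρ(τ)|τ| − |f(τ)|| (the per-vertex 1-ring sum with
the ¼ weight counts every tetrahedron exactly once), the per-vertex local
mass ratio — reported as the 1-ring **mean** of ρ(τ)|τ|/|f(τ)|, which is 1
under exact preservation, with the raw 1-ring sum also recorded — and the
count of folded (non-positively oriented) image tetrahedra.

## Meshing

Each retained voxel is split into 6 tetrahedra (Kuhn subdivision along a
fixed global diagonal), so adjacent voxels share conforming faces and every
tetrahedron is positively orientable. Before meshing, the mask keeps its
largest 26-connected component and fills interior cavities; additionally,
the two critical voxel configurations (edge-diagonal 2×2 squares and
corner-diagonal 2×2×2 blocks) are repaired by adding voxels until the set is
well-composed — without this, rasterized curved boundaries routinely
produce non-manifold boundary edges that violate the genus-zero contract.
The boundary's closedness, Euler characteristic 2, and the agreement of the
divergence-theorem volume with the tetrahedron volume sum are enforced, not
assumed.

Refinement marks every tetrahedron whose centroid lies in the target region
and applies three levels of tagged (Maubach) bisection — on the Kuhn base
tetrahedra this is an exact 1:8 split into equal-volume children — then
restores conformity by recursively bisecting any tetrahedron that still
contains a split edge. This bisection closure is provably terminating and
conforming on Kuhn-type meshes, conserves volume exactly, and never moves
existing vertices. Dilation of the tumor region uses a Euclidean ball
(distance transform ≤ m voxels), default m = 5, matched to the 5×5×5 blur
kernel.

## Densities

Modalities are normalized by CEHE: Z-score over brain voxels, clipped at
±3 SD, then histogram equalization of the brain voxels onto [0, 1]
(background exactly 0; a constant image maps to 0.5). This is a monotone
transform of intensity ranks, so densities depend only on the intensity
ordering, not scanner units. Phase I sets ρ_γ(v) = exp(γ Ī₁) at the vertex's
owning voxel (min-corner convention, clamped at the grid border), γ ∈ [1, 2]
(values outside warn but compute). Phase II builds a step field — exp(γ Ī₁)
inside the dilated WT region, 1 outside — and convolves it with the m³ mean
kernel over the full cuboid (replicate padding at the cuboid border only),
then samples at mesh vertices. With the region covering the whole grid and
m = 1 this reduces exactly to the Phase I density.

## Tensorization and pullback

Cube tensors sample the brain through the inverse map: each of the n³ cube
voxel centers is located in an image tetrahedron (uniform spatial hash over
image-tet bounding boxes; barycentric containment with ε = 1e-9; a point in
several tets takes a positively oriented one, then the lowest index) and
pulled back barycentrically; the source volume is sampled at the containing
brain voxel with no interpolation, so label tensors stay in {0, 1, 2, 4}.
Cube voxels not covered by any image tetrahedron (folding artifacts) are
zero-filled and flagged; more than 5% uncovered raises an error. Phase I
emits one binary WT label cube; Phase II emits three, coding {2,1,4},
{1,4} and {4}.

The pullback averages, per brain voxel j, the probabilities of the n(j)
cube centers whose preimages lie in j; a brain voxel with n(j) = 0 takes the
probability of the cube center whose preimage is nearest to its center.
Labels follow the hierarchical rule: p¹ < ½ → 0; else p² < ½ → 2; else
p³ < ½ → 1; else 4; everything outside the brain stays 0. Because
rasterization and pullback traverse the same map, a perfect predictor
reproduces the source labels wherever n(j) ≥ 1 — the round-trip tests rest
on this exact consistency.

## Ensemble and metrics

Test-time augmentation uses five orientations of the cube tensor: identity,
90° counterclockwise rotation in the plane of the first two axes, mirror of
the first axis, mirror of the second, and mirror-then-rotation (the axis
convention is configuration-level, not hard-coded into the mathematics).
Predictions are inverse-transformed to the reference frame, binarized at ½,
and compared to the reference prediction (orientation 0, model 1) by Dice;
grids at Dice ≥ 0.8 enter an unweighted mean. The reference always
qualifies, so the vote is defined.

Dice, sensitivity, specificity and precision come from exact boolean
counts; empty/empty Dice is 1 and rates with empty denominators are
reported as missing rather than 0. HD95 is the symmetric
(max-of-directed) 95th percentile of surface-to-surface distances in
physical units, surfaces being voxels with at least one 6-neighbor outside
the set. The training loss is Dice loss plus cross-entropy with the
prediction clipped to [1e-7, 1] before the logarithm.

## Synthetic subjects and the oracle

The phantom emulates the BraTS layout: an ellipsoidal brain with a smooth
random radial perturbation occupying ~17% of the cuboid (semi-axes 0.40,
0.35, 0.29 of the grid dimensions put the brain fraction inside the 12–20%
band for any grid), nested tumor blobs labeled 4 ⊂ {1,4} ⊂ {2,1,4}, FLAIR
hyperintense on WT and T1CE on ET with tissue contrasts several noise SDs
apart (noise SD 0.02 against contrast steps ≥ 0.3), and per-seed
determinism. What it does not emulate: bias fields, partial-volume
blurring, multi-focal or infiltrative tumor geometry, inter-subject
anatomy. Passing round-trip and magnification tests therefore demonstrates
the geometry pipeline's correctness, not segmentation accuracy on clinical
data — the latter additionally depends on the trained networks, which are
out of scope behind the predictor contract.

The oracle predictor emits the rasterized label cube plus optional clipped
Gaussian noise. At noise 0 it is exact; at SD 0.1 the probability of a
threshold crossing is Φ(−5) ≈ 3e-7, so cube-level Dice stays ≈ 1.

## Problem sizes and defaults

Default study settings: cube 128³, p = 11, m = 5, γ ∈ {1.0, 1.5, 1.75,
2.0}, reference surface 33×33 per face. The test suite and acceptance
script run the same pipeline on 64×64×44 phantoms with a 64³ cube and a
17×17 reference surface (~180k tetrahedra unrefined, ~600k after Phase II
refinement), sizes at which every statistic of interest — conservation
identities, distortion quartiles, round-trip Dice, magnification — is
already stable while a full run completes in minutes on one CPU. Recorded
network hyperparameters (encoder depth 3, initial learning rate 1e-4, drop
factor 0.95, drop period 10, L2 1e-4, batch 8) are configuration defaults
only; nothing in this package consumes them.

## Known limitations

- Bijectivity of the maps is diagnosed (folding counts), not guaranteed;
  folded image tetrahedra are counted and the affected cube voxels resolved
  by the positive-orientation tie-break, never untangled.
- The CEHE construction is one concrete reading of contrast-enhanced
  histogram equalization; statistics that depend on the exact grayscale
  transform are reproducible within this package but not bit-comparable to
  other implementations.
- The spherical solver is first-order; extremely elongated or high-genus
  inputs (rejected by the topology check) are out of scope.
- `run_validate` derives the Phase II region from the plugged-in predictor's
  WT output (or ground truth as the documented fallback); with a weak
  predictor the magnification prior degrades gracefully toward the Phase I
  density but is not re-estimated iteratively.
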