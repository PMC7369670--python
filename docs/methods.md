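# Methods

`spinereg` registers a pair of 3D volumes of the same lumbar spine acquired
with different modalities (a CT-like fixed image `I_F` and an MR-like moving
image `I_M`) by estimating a spatial transform `T` that maps fixed-image
physical coordinates (mm) to moving-image physical coordinates, so that
`I_M(T(x))` matches `I_F(x)`.  This note records the model, the numerical
choices and their rationale, what the synthetic benchmark does and does not
show, and known limitations.

## Transform model

**Stage 1 — affine.** `T(x) = R(x − c) + t + c` with 12 free parameters (the
nine entries of `R`, which mix rotation, scale and shear, plus the
translation `t`; the rotation centre `c` is fixed at the fixed-image centre).
Optimisation starts from a centre-of-mass alignment of the two intensity
distributions, which bootstraps the differing fields of view of CT and MR
acquisitions.

**Stage 2 — B-spline free-form deformation (FFD).** A displacement field
parameterised by vectors `Φ_ijk` on a regular control-point lattice,
interpolated by the tensor product of uniform cubic B-splines

    B0(u) = (1−u)³/6,  B1(u) = (3u³−6u²+4)/6,
    B2(u) = (−3u³+3u²+3u+1)/6,  B3(u) = u³/6,   0 ≤ u < 1.

The basis is a partition of unity (constant coefficient fields reproduce
constant displacements exactly), C²-smooth, and locally supported: a control
point influences only its 4×4×4-cell neighbourhood, which keeps evaluation
and the cost gradient sparse.  The composite transform is
`T(x) = affine(x) + FFD displacement(x)` — the displacement is parameterised
over the *fixed-image* frame and added to the frozen affine result.  This
additive composition (rather than functional composition) keeps the bending
penalty a pure function of the FFD coefficients and cleanly separates the two
stages.  The lattice always covers the fixed-image bounding box with a spare
control-point layer on every face, so evaluation inside the image domain
never runs off the lattice.

The lattice spacing follows a coarse-to-fine schedule (default 28 → 20 mm;
see "Parameters" below).  A finer level is initialised by evaluating
the coarser level's displacement at the new control points (quasi-
interpolation — the slight smoothing this introduces is refined away by the
subsequent optimisation).

## Similarity: Parzen-window NMI

Both stages maximise normalized mutual information

    NMI(I_F; I_M) = (H(I_F) + H(I_M)) / H(I_F, I_M),

estimated from a joint intensity histogram over stochastic samples of the
fixed domain.  Two estimators are provided:

* **Parzen** (optimisation): each sample spreads kernel mass over bins — a
  first-order (linear) kernel along the fixed axis, a cubic B-spline kernel
  along the moving axis.  The cubic kernel makes the joint density C² in the
  moving intensities, which is what permits an analytic gradient.  Guard bins
  outside the nominal range keep the kernels untruncated, so total mass is
  exactly 1 by partition of unity.
* **Discrete** (reporting/evaluation): nearest-bin assignment.  The textbook
  identities `MI(X,X) = H(X)` and `NMI(X,X) = 2` hold exactly only for this
  estimator — the Parzen kernel inflates the conditional spread of the joint
  histogram even at perfect alignment (NMI(I,I) ≈ 1.5 with 32 bins on
  continuous intensities), which is a property of the estimator, not an
  error.  `dense_nmi` therefore reports the discrete estimate on a regular
  subgrid.

Intensity ranges are fixed per pyramid level from the 0.5–99.5 percentiles of
each image (robust to bias-field tails); 32 bins per axis in the deformable
stage and 64 in the affine stage (the coarser binning measurably displaces
the rotation optimum on noisy data); entropies in nats.
Samples whose transformed position falls outside the moving image are
discarded rather than filled, so differing fields of view cannot bias the
estimate.  The similarity term is `S = −NMI`, making the problem a
minimisation.

### Analytic gradient

`dC/dμ` chains: histogram-bin derivatives of the entropies → cubic-kernel
derivative with respect to the moving intensity → the *exact* spatial
gradient of the trilinear interpolant of `I_M` → the transform Jacobian
`∂T/∂μ` (closed form for both transform types).  The bending term is a
quadratic form in `Φ` and is differentiated exactly.  Because trilinear
interpolation is only piecewise smooth and `p log p` has unbounded curvature
where a bin's mass crosses zero, the cost is piecewise-smooth in `μ`;
finite-difference checks therefore use sample sets placed away from
interpolation cell faces and histograms with no empty bins inside the
occupied region (the analytic gradient is the ε→0 limit everywhere).

## Bending-energy penalty

    P = (1/N) Σ_x Σ_d [ T_xx² + T_yy² + T_zz² + 2T_xy² + 2T_yz² + 2T_zx² ](x)

with analytic second derivatives of the FFD in physical units (1/mm), summed
over the three displacement components and averaged over the same stochastic
samples as the similarity (a dense full-grid evaluation is available for
reporting).  `P` vanishes exactly on affine fields — rigid structures pay no
penalty — and is quadratic in `Φ`.  The combined cost is
`C = γ1·S + γ2·P` with `γ1 = γ2 = 1` by default.  Derivatives in mm mean `P`
carries mm⁻² scale; with γ2 = 1 the penalty is deliberately gentle (the same
convention as widely used registration toolboxes), acting against high-
curvature deformation rather than against displacement as such.

## Optimisation: adaptive stochastic gradient descent

Each iteration draws a fresh uniform random subset of fixed-image positions
(default 2048; positions are voxel centres jittered within the cell, keeping
samples off interpolation kinks) and steps

    μ ← μ − γ(t_k) · g_k / s,   γ(t) = a / (t + A)^α,   A = 20, α = 1.

The internal time `t` advances when successive stochastic gradients disagree
(oscillation ⇒ shrink the step) and recedes toward 0 when they agree — so
steady descent keeps large steps while noise near the optimum anneals them.
Per-parameter scales `s` equalise units: affine matrix entries are scaled by
the mean squared image extent so a unit step in any parameter moves points by
comparable millimetres.

Three safeguards around the textbook scheme (all verified necessary on the
synthetic suite):

* **Automatic step scale with a curvature probe.**  `a` is set so the first
  update's largest parameter change equals `init_step` (0.5 mm by default),
  estimated from a few gradient probes at `μ0` *and* at a trial point one
  `init_step` away.  The second probe matters when the start is already near
  an optimum (self-registration; a dominant penalty term): there the gradient
  at `μ0` is noise-level and calibrating on it alone overestimates `a`
  catastrophically.
* **Trust region.** Updates are capped at `2·init_step` per iteration; a
  capped update also shrinks `a` (a cap event is evidence of overestimation).
* **Tail averaging.** The returned `μ` is the average of the final half of
  the iterates, which suppresses the stochastic noise floor around the
  optimum (with it, self-registration recovers the identity to ~0.01 mm in
  translation).

A fixed iteration budget per level is used (no early stopping): the noisy
stochastic cost is a poor stopping signal.  The whole procedure is
deterministic given the seed — samples are drawn from
`SeedSequence([seed, stage, level])` and the iteration number.

## Pyramids

* Affine stage: 3 levels, downsampling by 4/2/1 with Gaussian smoothing of
  2/1/0 voxels (in mm via the fixed image's spacing, applied identically to
  both images).  No smoothing at the finest level: residual blur measurably
  displaces the rotation optimum of the NMI.
* Deformable stage: Gaussian smoothing only (1/0.5 voxels), no
  downsampling; lattice spacing tightens per level.  Smoothing both images
  with the *same physical* sigma (rather than per-grid voxel sigmas) removes
  a systematic asymmetry between the differently sampled modalities.

## MIND baseline

The modality-independent neighbourhood descriptor is computed per voxel from
Gaussian-weighted (σ = 0.5 voxel, 3×3×3 patch) squared differences to the six
face neighbours, normalised by the mean of those six distances (floored at
1e-6 of its volume mean to protect flat regions) and max-normalised so the
largest of the six components is 1.  Images are compared by the mean sum of
absolute differences of interpolated descriptor components.  Because the
patch distances and their local mean scale together, the descriptor is
invariant to affine intensity changes.  `MINDRegistration` reuses the exact
B-spline/ASGD machinery, swapping only the similarity (no bending penalty),
so the comparison isolates the metric — descriptors are recomputed per level
on the smoothed images.  Boundary convention: shifted images and patch
neighbourhoods are edge-clamped.

## Evaluation

Jaccard `J = |O_F∩O_A| / |O_F∪O_A|` and Dice `D = 2|O_F∩O_A| / (|O_F|+|O_A|)`
by voxel count on a common grid (`D = 2J/(1+J)` identically).  Target
registration error is the Euclidean distance between paired landmarks; since
`T` maps fixed→moving, the default measurement compares `T(l_fixed)` with
`l_moving` in moving space — the same distances as the fixed-space variant,
which is also available through iterative transform inversion.  Spreads are
sample standard deviations (n−1).  Landmark files are whitespace-separated
text (`label x y z` in mm).  Binary masks supplied by a user are warped by
nearest-neighbour resampling (exactly binary-preserving).

## Synthetic benchmark

The phantom emulates a lumbar CT/MR pair: five box-like vertebral bodies with
posterior spinous processes, ellipsoidal discs, a cylindrical blood vessel
anterior to the column, and a surrounding muscle ellipse, all defined as an
*analytic* label function over physical coordinates.  The CT-like rendering
maps bone brightest (monotone); the MR-like rendering is non-monotone (bone
dark, disc/vessel bright) and is multiplied by a random second-order
polynomial bias field (±30%); both get 2% additive Gaussian noise and a
0.6-voxel partial-volume blur on their own grids.  The MR grid is coarser
(1.25×1.25×2.5 mm versus 1×1×2 mm over a 64×64×128 mm field of view),
exercising all physical-coordinate machinery.  Geometry dimensions are chosen
anisotropic (trunk ellipse 56×42 mm, bodies 22×14 mm) the way a lumbar
cross-section is — which is also what makes rotation identifiable — and
deliberately off voxel-centre planes (axis-aligned faces that land exactly on
grid planes create knife-edge rasterisation artifacts).

The ground-truth transform is the same family the method estimates: an affine
(default 4/−3/2 mm translation, 5° axial rotation, mild scale/shear in the
harder cases) plus a smooth random B-spline warp (12 mm lattice, peak 8 mm)
whose coefficients are windowed to zero within ~3 mm of bone so vertebrae
move near-rigidly (residual ≈ 0.2 mm mean inside the bone mask) while discs,
vessel and muscle deform.  Because the anatomy is analytic, the fixed image
is *rasterised through* the ground-truth transform (never resampled), mask
and landmark correspondences are exact by construction, and the benchmark's
overlap evaluation rasterises the tissue outline of the aligned image
`I_M∘T` on the fixed grid — the protocol of annotating the aligned image
directly.  Its Dice is exactly 1 at the true transform, so the score measures
transform error alone; warping the coarse moving-grid mask by nearest
neighbour instead would cap Dice near 0.9 for the *exact* transform at this
scale (annotation quantisation, not registration error).

On this benchmark the MIND baseline scores within about 0.01 Dice of the
proposed method: the phantom's clean, self-similar structure is favourable
to a self-similarity descriptor, so the large gap reported on clinical data
should not be expected here — the comparison verifies machinery and ordering,
not the clinical margin.

What passing the benchmark does **not** show: robustness to real MR/CT
artefacts beyond a polynomial bias field (susceptibility, metal, motion),
pathology, true soft-tissue mechanics (the warp is a random smooth field, not
a biomechanical model), or behaviour at clinical resolution (the phantom is a
scaled-down 64³ study; the generator family is also the transform family the
method fits, so representation error on real deformations is not probed).

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| histogram bins | 64 (affine), 32 (deformable) | — | see text |
| samples/iteration | 2048 | — | gradient noise vs cost balance |
| ASGD A, α | 20, 1 | — | step ≈ a/(t+20) |
| init_step | 0.5 (affine), 0.5 (deformable) | mm | first-update size |
| iterations/level | 300–400 | — | fixed budget, no early stop |
| affine pyramid | 4/2/1, σ = 2/1/0 voxels | — | see "Pyramids" |
| deformable smoothing | σ = 2/1/0.5 voxels | — | no downsampling |
| lattice schedule | 28 → 20 | mm | see below |
| γ1, γ2 | 1, 1 | — | stated weighting of the cost |
| Parzen kernels | linear (fixed) × cubic (moving) | — | differentiability at least cost |
| intensity range | 0.5–99.5 percentile | — | bias-tail robust |
| MIND patch | 3×3×3, σ = 0.5 voxel, |R| = 6 | — | reference configuration |

The lattice schedule default (two levels, 28 then 20 mm) is both coarser
and shallower than the finest the code supports.  On the synthetic benchmark
a 16 mm final lattice has enough local freedom to chase noise-displaced local
optima of the NMI around bone boundaries (~0.5 mm spurious displacement even
from a perfect initialisation, with or without bias field), and a heavily
smoothed extra coarse level (32-40 mm lattice at sigma = 2 voxels) injects a
bone drift that finer levels do not undo — both degrade bone overlap below
what the affine stage already achieves.  Two moderately smoothed levels
ending at 20 mm recover the smooth soft-tissue warp while keeping bone
near-rigid.  Users registering data with finer genuine deformation should
tighten and deepen the schedule and consider raising γ2 in tandem.

## Numerical notes and edge cases

* Trilinear interpolation everywhere for scalar volumes (order 0 for binary
  masks); out-of-domain sampling returns a configurable fill value and is
  excluded from metric estimation.
* Degenerate histograms (zero joint entropy) raise rather than return NaN.
* The FFD raises on evaluation outside its lattice; the pipeline guarantees
  coverage by construction.
* Transform serialisation is plain JSON (type tag, fixed parameters, μ);
  displacement fields export as per-component NIfTI volumes.
* All randomness flows from integer seeds through `numpy` `SeedSequence`;
  two runs with the same config and seed are bitwise identical.

## Known limitations

* No diffeomorphism guarantee or folding correction; `BSplineFFD.jacobian`
  exposes the spatial Jacobian so users can check `det J > 0` themselves.
  The benchmark's 8 mm warps on 20 mm lattices stay invertible in practice.
* The global histogram makes NMI blind to spatially varying intensity
  relationships beyond what 32 bins capture; strong bias fields degrade it
  gracefully rather than being modelled.
* TRE inversion (`space="fixed"`) uses fixed-point iteration, which assumes
  the displacement is a contraction; extreme warps may need more iterations.
* The affine stage optimises the full 12-parameter model; on data with no
  scale/shear the extra freedom slightly inflates rotation/translation
  variance (polar decomposition is used when a rotation angle is reported).
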