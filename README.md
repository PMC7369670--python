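# spinereg

Coarse-to-fine multimodal registration of 3D lumbar-spine volumes.

Aligning CT and MR scans of the same spine is hard: the two modalities map
tissue to intensity in unrelated (non-monotone) ways, MR images carry smooth
bias-field artifacts, the fields of view differ, and the anatomy mixes rigid
vertebrae with deformable soft tissue (discs, vessels, muscle).  `spinereg`
implements a two-stage framework for this problem:

1. **Global positioning** — a 12-parameter affine transform
   `T(x) = R(x − c) + t + c` is optimised over a 3-level downsampling pyramid
   by maximising normalized mutual information,
   `NMI = (H(I_F) + H(I_M)) / H(I_F, I_M)`, estimated with Parzen windows
   from stochastic voxel samples.
2. **Hierarchical deformation** — a cubic B-spline free-form deformation
   (displacement vectors on a control-point lattice, tensor-product cubic
   B-spline interpolation) refines the frozen affine result by minimising the
   bending-energy-penalised cost

   `C(μ) = γ1·(−NMI) + γ2·P`,  
   `P = (1/N) Σ_x [Txx² + Tyy² + Tzz² + 2Txy² + 2Tyz² + 2Tzx²]`,

   with `γ1 = γ2 = 1`.  The penalty vanishes on affine fields, so rigid
   vertebrae are preserved while soft tissue deforms.

Both stages use adaptive stochastic gradient descent (fresh random voxel
subset per iteration, adaptive step decay) with fully analytic cost
gradients.  The package also implements the MIND self-similarity descriptor
(6-connected, 3×3×3 Gaussian-weighted patch distances) with a
sum-of-absolute-differences similarity as a comparison method, an evaluation
suite (Jaccard/Dice overlap, landmark target registration error), and a
synthetic-phantom generator that produces CT-like/MR-like lumbar spine pairs
with known ground-truth transforms, masks and landmarks — so the whole
framework is testable end to end without clinical data.

The registration estimators follow scikit-learn conventions
(`fit`, `get_params`/`set_params`, fitted attributes with trailing
underscores) and compose with scikit-learn tooling.

## Quick start (library)

```python
from spinereg import (CoarseToFineRegistration, AffineRegistration,
                      BSplineRegistration, make_case, PhantomSpec,
                      GroundTruthSpec, dice, target_registration_error)

# a synthetic CT-like/MR-like pair with a known affine + warp + bias field
fixed, moving, gt = make_case(PhantomSpec(seed=0), GroundTruthSpec(seed=0))

est = CoarseToFineRegistration(
    affine=AffineRegistration(iterations=400),
    deformable=BSplineRegistration(),
    seed=0,
).fit(fixed, moving)

result = est.result_                     # transforms, warped image, traces
tre, per_point, sd = target_registration_error(
    gt.landmarks_fixed, gt.landmarks_moving, result.composite)
d = dice(gt.masks_fixed["vertebrae"],
         gt.aligned_mask("vertebrae", result.composite, fixed))
print(f"vertebra Dice {d:.3f}, mean TRE {tre:.2f} mm (initial was 5.5 mm)")
```

On the default benchmark case this prints approximately

```
vertebra Dice 0.951, mean TRE 0.60 mm (initial was 5.5 mm)
```

i.e. the recovered transform overlaps the vertebra outline at ~95% Dice and
reduces the mean landmark error from ~5.5 mm (the initial misalignment) to
about half a fixed-image voxel.

## Quick start (command line)

```bash
# generate a synthetic pair with ground truth
spinereg phantom --seed 0 --out case/

# register (bep_nmi is the default method; mind is the baseline)
spinereg register --fixed case/fixed.nii.gz --moving case/moving.nii.gz \
    --out reg/ --seed 0

# overlap + landmark-error report, before and after
spinereg evaluate --transform reg/transform.json --fixed case/fixed.nii.gz \
    --fixed-mask case/fixed_mask_vertebrae.nii.gz \
    --moving-mask case/moving_mask_vertebrae.nii.gz \
    --landmarks-fixed case/landmarks_fixed.txt \
    --landmarks-moving case/landmarks_moving.txt \
    --out reg/report
```

`register` writes the warped volume, transform JSON files, per-axis
displacement-field NIfTIs, and a per-iteration trace CSV (cost, step size).
Volumes are read/written as NIfTI (`.nii`, `.nii.gz`) or MetaImage
(`.mhd`/`.mha`); landmarks are plain text (`label x y z` in mm).

## Testing

```bash
python -m pytest tests/
```

The suite covers unit behaviour per module (interpolation and I/O round
trips, B-spline basis identities, histogram normalisation, analytic-gradient
versus finite-difference checks, optimizer convergence), property-based
invariants, and end-to-end ground-truth recovery on the synthetic benchmark.
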