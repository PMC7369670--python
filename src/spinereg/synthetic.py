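"""Multimodal lumbar-spine phantoms with known ground-truth transforms.

The generator emulates the features of paired CT/MR lumbar scans that make
their registration hard, so the whole pipeline is testable without clinical
data:

* a stack of box-like "vertebrae" with posterior spinous processes,
  ellipsoidal intervertebral "discs", a cylindrical "blood vessel" and
  surrounding "muscle";
* a CT-like rendering (monotone tissue map, bone brightest) and an MR-like
  rendering (non-monotone map — bone dark, disc/vessel bright) so that the
  joint intensity relationship requires an information-theoretic metric;
* a smooth multiplicative second-order polynomial bias field on the MR-like
  image (the classic MR inhomogeneity artifact) plus additive Gaussian noise;
* different grids for the two modalities (the MR grid is coarser), so all
  physical-coordinate machinery is exercised;
* a ground-truth fixed-to-moving transform (affine + smooth B-spline warp,
  the warp attenuated to zero inside the vertebrae so bones move rigidly
  while soft tissue deforms), with masks and the four landmark classes (VBC,
  NE, DC, BVE) consistent with it.

The anatomy is *analytic* (a label function over physical coordinates), so
the warped fixed image, its masks and the landmark correspondences are
rasterised exactly through the ground-truth transform — never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .evaluation import LabelMask, LandmarkSet
from .transforms import AffineTransform, BSplineFFD, CompositeTransform
from .volumes import Volume

__all__ = [
    "PhantomSpec",
    "GroundTruthSpec",
    "GroundTruth",
    "generate_label_phantom",
    "render_modalities",
    "make_case",
    "benchmark_suite",
    "BACKGROUND", "MUSCLE", "VERTEBRA", "DISC", "PROCESS", "VESSEL",
]

BACKGROUND, MUSCLE, VERTEBRA, DISC, PROCESS, VESSEL = 0, 1, 2, 3, 4, 5

# tissue intensity maps (arbitrary units in [0, 1]); CT-like is monotone with
# bone brightest, MR-like is non-monotone (bone dark, disc/vessel bright)
CT_INTENSITY = {BACKGROUND: 0.02, MUSCLE: 0.30, DISC: 0.25, VESSEL: 0.35,
                VERTEBRA: 1.00, PROCESS: 1.00}
MR_INTENSITY = {BACKGROUND: 0.05, MUSCLE: 0.45, DISC: 0.85, VESSEL: 1.00,
                VERTEBRA: 0.15, PROCESS: 0.15}


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of the synthetic pair.

    The CT-like (fixed) grid defaults to 64^3 voxels at 1 x 1 x 2 mm; the
    MR-like (moving) grid is coarser, mimicking thicker MR slices.  Noise is
    2% of the dynamic range; the bias field is a second-order polynomial with
    +-30% amplitude.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    mr_spacing: tuple[float, float, float] = (1.25, 1.25, 2.5)
    n_vertebrae: int = 5
    vessel_radius: float = 3.0
    noise_sigma: float = 0.02
    bias_field_amplitude: float = 0.3
    pv_smooth_voxels: float = 0.6
    seed: int = 0

    def extent(self) -> np.ndarray:
        return np.array(self.shape, float) * np.array(self.spacing, float)

    def mr_shape(self) -> tuple[int, int, int]:
        return tuple(int(np.ceil(e / s))
                     for e, s in zip(self.extent(), self.mr_spacing))


class _Anatomy:
    """Analytic label function over canonical physical coordinates (mm)."""

    def __init__(self, spec: PhantomSpec):
        ext = spec.extent()
        self.center = ext / 2.0
        self.spec = spec
        cz = self.center[2]
        pitch = 21.7
        n = spec.n_vertebrae
        self.vert_z = cz + (np.arange(n) - (n - 1) / 2.0) * pitch
        if self.vert_z.min() < 12 or self.vert_z.max() > ext[2] - 12:
            raise ValueError(
                f"infeasible geometry: {n} vertebrae at 21.7 mm pitch do not fit "
                f"a {ext[2]:.0f} mm axial extent"
            )
        self.body_half = np.array([11.0, 7.0, 7.7])
        self.body_center_xy = self.center[:2] + np.array([0.0, 4.0])
        self.disc_z = (self.vert_z[:-1] + self.vert_z[1:]) / 2.0
        self.disc_semi = np.array([10.5, 6.5, 3.3])
        self.vessel_center_xy = self.center[:2] + np.array([0.0, -16.0])
        self.muscle_semi = np.array([28.0, 21.0])

    def labels(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        cx, cy = self.center[0], self.center[1]
        ext = self.spec.extent()
        out = np.zeros(pts.shape[0], dtype=int)

        muscle = (
            (((x - cx) / self.muscle_semi[0]) ** 2
             + ((y - cy) / self.muscle_semi[1]) ** 2 <= 1.0)
            & (z >= 4.1) & (z <= ext[2] - 4.1)
        )
        out[muscle] = MUSCLE

        bx, by = self.body_center_xy
        for zc in self.disc_z:
            disc = (
                ((x - bx) / self.disc_semi[0]) ** 2
                + ((y - by) / self.disc_semi[1]) ** 2
                + ((z - zc) / self.disc_semi[2]) ** 2
            ) <= 1.0
            out[disc] = DISC
        for zc in self.vert_z:
            body = (
                (np.abs(x - bx) <= self.body_half[0])
                & (np.abs(y - by) <= self.body_half[1])
                & (np.abs(z - zc) <= self.body_half[2])
            )
            out[body] = VERTEBRA
            process = (
                (np.abs(x - cx) <= 3.4)
                & (y >= by + self.body_half[1] - 2.1)
                & (y <= by + self.body_half[1] + 9.7)
                & (np.abs(z - zc) <= 4.3)
            )
            out[process] = PROCESS
        vx, vy = self.vessel_center_xy
        vessel = (
            ((x - vx) ** 2 + (y - vy) ** 2 <= self.spec.vessel_radius ** 2)
            & (z >= 6.2) & (z <= ext[2] - 6.2)
        )
        out[vessel] = VESSEL
        return out

    def bone_distance(self, points: np.ndarray) -> np.ndarray:
        """Approximate distance (mm) to the nearest vertebra (body or
        process); 0 inside bone.  Used to window the ground-truth warp."""
        pts = np.atleast_2d(np.asarray(points, float))
        bx, by = self.body_center_xy
        cx = self.center[0]
        d = np.full(pts.shape[0], np.inf)
        for zc in self.vert_z:
            q = np.abs(pts - np.array([bx, by, zc]))
            outside = np.maximum(q - self.body_half, 0.0)
            d = np.minimum(d, np.linalg.norm(outside, axis=1))
            qp = np.abs(pts - np.array([cx, by + self.body_half[1] + 3.8, zc]))
            outside_p = np.maximum(qp - np.array([3.4, 5.9, 4.3]), 0.0)
            d = np.minimum(d, np.linalg.norm(outside_p, axis=1))
        return d

    def landmarks(self) -> tuple[list[str], np.ndarray]:
        """Canonical-space anatomical landmarks of the four classes."""
        bx, by = self.body_center_xy
        cx = self.center[0]
        vx, vy = self.vessel_center_xy
        labels, pos = [], []
        for i, zc in enumerate(self.vert_z):
            labels.append(f"VBC_{i}")
            pos.append([bx, by, zc])
            labels.append(f"NE_{i}")
            pos.append([cx, by + self.body_half[1] + 2.0, zc])
        for i, zc in enumerate(self.disc_z):
            labels.append(f"DC_{i}")
            pos.append([bx, by, zc])
        for i, zc in enumerate(self.vert_z):
            labels.append(f"BVE_{i}")
            pos.append([vx + self.spec.vessel_radius, vy, zc])
        return labels, np.array(pos)


def _grid(spec: PhantomSpec, moving: bool = False) -> Volume:
    if moving:
        shape, spacing = spec.mr_shape(), spec.mr_spacing
    else:
        shape, spacing = spec.shape, spec.spacing
    return Volume(data=np.zeros(shape), spacing=spacing)


def generate_label_phantom(spec: PhantomSpec, moving: bool = False) -> Volume:
    """Integer tissue-label volume on the CT (default) or MR grid."""
    vol = _grid(spec, moving=moving)
    labels = _Anatomy(spec).labels(vol.grid_points())
    vol.data = labels.reshape(vol.shape).astype(float)
    return vol


def _render(labels: np.ndarray, intensity_map: dict[int, float]) -> np.ndarray:
    lut = np.zeros(max(intensity_map) + 1)
    for k, v in intensity_map.items():
        lut[k] = v
    return lut[labels.astype(int)]


def _bias_field(vol: Volume, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * q(p), q a random
    second-order polynomial normalised to max |q| = 1."""
    pts = vol.grid_points()
    lo, hi = vol.bounding_box()
    p = 2.0 * (pts - lo) / np.maximum(hi - lo, 1e-9) - 1.0
    terms = [np.ones(len(p))]
    for a in range(3):
        terms.append(p[:, a])
    for a in range(3):
        for b in range(a, 3):
            terms.append(p[:, a] * p[:, b])
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    coeffs[0] = 0.0
    q = np.stack(terms, axis=1) @ coeffs
    q /= max(np.abs(q).max(), 1e-12)
    return (1.0 + amplitude * q).reshape(vol.shape)


def render_modalities(spec: PhantomSpec, transform=None):
    """(ct_like fixed, mr_like moving) pair.

    The anatomy lives in the moving (MR) frame; the fixed CT image is
    rasterised through ``transform`` (fixed-to-moving, None = identity), so
    the given transform is exactly the mapping a registration should recover.
    """
    anatomy = _Anatomy(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))

    ct = _grid(spec, moving=False)
    pts = ct.grid_points()
    if transform is not None:
        pts = transform.apply(pts)
    ct.data = _render(anatomy.labels(pts).reshape(ct.shape), CT_INTENSITY)

    mr = _grid(spec, moving=True)
    mr.data = _render(anatomy.labels(mr.grid_points()).reshape(mr.shape),
                      MR_INTENSITY)
    if spec.bias_field_amplitude > 0:
        mr.data = mr.data * _bias_field(mr, spec.bias_field_amplitude, rng)

    for vol in (ct, mr):
        if spec.pv_smooth_voxels > 0:
            vol.data = ndimage.gaussian_filter(
                vol.data, sigma=spec.pv_smooth_voxels, mode="nearest"
            )
        if spec.noise_sigma > 0:
            vol.data = vol.data + rng.normal(
                0.0, spec.noise_sigma * np.ptp(vol.data), size=vol.shape
            )
    return ct, mr


@dataclass
class GroundTruthSpec:
    """Parameters of the ground-truth fixed-to-moving transform."""

    translation: tuple[float, float, float] = (4.0, -3.0, 2.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 5.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear: float = 0.0
    warp_amplitude: float = 8.0  # max control-point displacement, mm
    warp_grid_spacing: float = 12.0
    seed: int = 0

    def rotation_matrix(self) -> np.ndarray:
        ax, ay, az = np.deg2rad(self.rotation_deg)
        rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                       [0, np.sin(ax), np.cos(ax)]])
        ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                       [-np.sin(ay), 0, np.cos(ay)]])
        rz = np.array([[np.cos(az), -np.sin(az), 0],
                       [np.sin(az), np.cos(az), 0], [0, 0, 1]])
        return rz @ ry @ rx

    def affine(self, center: np.ndarray) -> AffineTransform:
        m = self.rotation_matrix() @ np.diag(self.scale)
        m = m + self.shear * (np.triu(np.ones((3, 3))) - np.eye(3))
        return AffineTransform(R=m, c=center, t=np.array(self.translation))


_TISSUE_LABELS = {"vertebrae": (VERTEBRA, PROCESS), "blood_vessel": (VESSEL,)}


@dataclass
class GroundTruth:
    """Ground-truth transform plus consistent masks and landmark pairs."""

    affine: AffineTransform
    warp: BSplineFFD
    composite: CompositeTransform
    masks_fixed: dict[str, LabelMask]
    masks_moving: dict[str, LabelMask]
    landmarks_fixed: LandmarkSet
    landmarks_moving: LandmarkSet
    anatomy: "_Anatomy" = None

    def aligned_mask(self, tissue: str, transform, reference: Volume) -> LabelMask:
        """Tissue outline of the *aligned* image I_M(T(x)), rasterised on the
        reference (fixed) grid.

        This mirrors annotating the warped image directly at fixed-grid
        resolution: the outline is exact because the anatomy is analytic, so
        the overlap with the fixed-space outline measures transform error
        alone (it is 1.0 when ``transform`` is the ground-truth composite).
        """
        which = _TISSUE_LABELS[tissue]
        pts = transform.apply(reference.grid_points())
        labels = self.anatomy.labels(pts)
        return LabelMask(_mask_volume(reference, labels, which), tissue)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return 3 * s**2 - 2 * s**3


def _ground_truth_warp(
    spec: PhantomSpec, gt_spec: GroundTruthSpec, anatomy: _Anatomy,
    affine: AffineTransform,
) -> BSplineFFD:
    """Random smooth coefficient field, rescaled to the requested amplitude
    and windowed to zero near the (affine-mapped) vertebrae so bone moves
    rigidly."""
    fixed = _grid(spec, moving=False)
    lo, hi = fixed.bounding_box()
    ffd = BSplineFFD.from_domain(lo, hi, gt_spec.warp_grid_spacing)
    if gt_spec.warp_amplitude <= 0:
        return ffd
    rng = np.random.default_rng(np.random.SeedSequence([gt_spec.seed, 11]))
    coef = rng.uniform(-1.0, 1.0, size=ffd.coefficients.shape)
    # correlate over ~2 control points so the field is smooth at the
    # soft-tissue scale, then rescale to the requested peak amplitude
    coef = ndimage.gaussian_filter(coef, sigma=(2.0, 2.0, 2.0, 0.0),
                                   mode="nearest")
    coef *= gt_spec.warp_amplitude / max(np.abs(coef).max(), 1e-12)
    # window the warp off inside/near bone (evaluated in the canonical frame);
    # the margin exceeds half the cubic support so leakage into bone is tiny
    cp = ffd.control_point_positions()
    d = anatomy.bone_distance(affine.apply(cp))
    w = _smoothstep((d - 3.0) / 8.0)
    ffd.coefficients = coef * w.reshape(ffd.grid_shape)[..., None]
    return ffd


def _mask_volume(fixed: Volume, labels: np.ndarray, which: tuple[int, ...]) -> Volume:
    data = np.isin(labels.reshape(fixed.shape), which).astype(float)
    return fixed.copy(data=data)


def make_case(
    spec: PhantomSpec | None = None,
    gt_spec: GroundTruthSpec | None = None,
):
    """Build one benchmark case: (fixed CT-like, moving MR-like, GroundTruth)."""
    spec = spec or PhantomSpec()
    gt_spec = gt_spec or GroundTruthSpec(seed=spec.seed)
    anatomy = _Anatomy(spec)
    fixed_grid = _grid(spec, moving=False)
    center = fixed_grid.physical_center()
    affine = gt_spec.affine(center)
    warp = _ground_truth_warp(spec, gt_spec, anatomy, affine)
    composite = CompositeTransform(affine, warp)

    fixed, moving = render_modalities(spec, transform=composite)

    # masks: analytic labels through the exact transform (never resampled)
    mapped = composite.apply(fixed.grid_points())
    fixed_labels = anatomy.labels(mapped)
    moving_grid = _grid(spec, moving=True)
    moving_labels = anatomy.labels(moving_grid.grid_points())
    masks_fixed = {
        "vertebrae": LabelMask(
            _mask_volume(fixed_grid, fixed_labels, (VERTEBRA, PROCESS)),
            "vertebrae"),
        "blood_vessel": LabelMask(
            _mask_volume(fixed_grid, fixed_labels, (VESSEL,)), "blood_vessel"),
    }
    masks_moving = {
        "vertebrae": LabelMask(
            _mask_volume(moving_grid, moving_labels, (VERTEBRA, PROCESS)),
            "vertebrae"),
        "blood_vessel": LabelMask(
            _mask_volume(moving_grid, moving_labels, (VESSEL,)), "blood_vessel"),
    }

    # landmark pairs exact under the composite: place them in the canonical
    # frame, pull back to fixed space by iterative inversion, then push the
    # fixed points forward so the stored pair satisfies l' = T(l) exactly
    from .evaluation import invert_transform_points

    labels, canonical = anatomy.landmarks()
    lfix = invert_transform_points(composite, canonical, iterations=200,
                                   tol=1e-12)
    lmov = composite.apply(lfix)
    landmarks_fixed = LandmarkSet(labels=labels, positions=lfix, space="fixed")
    landmarks_moving = LandmarkSet(labels=list(labels), positions=lmov,
                                   space="moving")
    gt = GroundTruth(
        affine=affine, warp=warp, composite=composite,
        masks_fixed=masks_fixed, masks_moving=masks_moving,
        landmarks_fixed=landmarks_fixed, landmarks_moving=landmarks_moving,
        anatomy=anatomy,
    )
    return fixed, moving, gt


CASE_SPECS = {
    "translation": dict(rotation_deg=(0, 0, 0), warp_amplitude=0.0, bias=0.0),
    "rigid": dict(rotation_deg=(0, 0, 5.0), warp_amplitude=0.0, bias=0.0),
    "affine": dict(rotation_deg=(0, 0, 5.0), scale=(1.03, 0.97, 1.0),
                   shear=0.02, warp_amplitude=0.0, bias=0.0),
    "affine_warp": dict(rotation_deg=(0, 0, 5.0), scale=(1.03, 0.97, 1.0),
                        warp_amplitude=8.0, bias=0.0),
    "affine_warp_bias": dict(rotation_deg=(0, 0, 5.0), scale=(1.03, 0.97, 1.0),
                             warp_amplitude=8.0, bias=0.3),
}


def benchmark_suite(seed: int = 0, names=None) -> dict:
    """Catalogue of phantom cases of increasing difficulty, deterministic
    given the seed: translation-only, rigid, affine, affine+warp and
    affine+warp+bias-field."""
    out = {}
    for name, params in CASE_SPECS.items():
        if names is not None and name not in names:
            continue
        params = dict(params)
        bias = params.pop("bias")
        spec = PhantomSpec(seed=seed, bias_field_amplitude=bias)
        gt_spec = GroundTruthSpec(seed=seed, **params)
        out[name] = make_case(spec, gt_spec)
    return out


def write_case(fixed: Volume, moving: Volume, gt: GroundTruth, outdir) -> None:
    """Persist one case in standard formats (NIfTI volumes and masks,
    landmark text files, ground-truth transform JSON)."""
    import os

    from .evaluation import write_landmarks
    from .transforms import save_transform
    from .volumes import write_volume

    os.makedirs(outdir, exist_ok=True)
    write_volume(fixed, os.path.join(outdir, "fixed.nii.gz"))
    write_volume(moving, os.path.join(outdir, "moving.nii.gz"))
    for name, mask in gt.masks_fixed.items():
        write_volume(mask.volume, os.path.join(outdir, f"fixed_mask_{name}.nii.gz"))
    for name, mask in gt.masks_moving.items():
        write_volume(mask.volume, os.path.join(outdir, f"moving_mask_{name}.nii.gz"))
    write_landmarks(gt.landmarks_fixed, os.path.join(outdir, "landmarks_fixed.txt"))
    write_landmarks(gt.landmarks_moving, os.path.join(outdir, "landmarks_moving.txt"))
    save_transform(gt.composite, os.path.join(outdir, "ground_truth_transform.json"))
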