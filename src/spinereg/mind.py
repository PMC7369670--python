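"""Modality-independent neighbourhood descriptor (MIND) and registration.

MIND represents each voxel by the pattern of self-similarity between the
patch centred there and the patches at its six face neighbours:

    MIND(I, x, r) = (1/n) exp(-Dp(I, x, x + r) / V(I, x)),   r in R,

where ``Dp`` is a Gaussian-weighted sum of squared differences between the
two 3x3x3 patches, ``V(I, x)`` is the mean of the six patch distances (a
local variance estimate, floored to avoid division blow-up in flat regions),
and ``n`` normalises the largest component at each voxel to 1.  Because both
``Dp`` and ``V`` scale with the square of any global intensity scaling, the
descriptor is invariant to affine intensity changes — which is what makes it
usable across modalities.

Two descriptor fields are compared by the mean sum of absolute differences
over the |R| = 6 components (values in [0, 1]).  ``MINDRegistration`` plugs
this similarity into the same hierarchical B-spline/ASGD machinery as the
proposed method, so comparisons isolate the choice of metric.  No bending
penalty is added.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .pipeline import BSplineRegistration
from .transforms import AffineTransform, BSplineFFD
from .volumes import Volume

__all__ = [
    "MINDDescriptor",
    "compute_mind",
    "patch_distance",
    "mind_sad",
    "MINDRegistration",
    "register_mind",
]

SIX_CONNECTED = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)


class MINDDescriptor:
    """Per-voxel MIND components on a volume's grid.

    ``components`` has shape ``volume.shape + (|R|,)`` with values in (0, 1].
    """

    def __init__(self, components: np.ndarray, reference: Volume,
                 offsets=SIX_CONNECTED, patch_radius: int = 1):
        self.components = components
        self.reference = reference
        self.offsets = tuple(offsets)
        self.patch_radius = patch_radius

    @property
    def n_components(self) -> int:
        return self.components.shape[-1]


def _shift(data: np.ndarray, offset) -> np.ndarray:
    """Shift with nearest-edge padding: out[x] = data[x + offset]."""
    out = data
    for axis, o in enumerate(offset):
        if o == 0:
            continue
        out = np.take(out, np.clip(np.arange(out.shape[axis]) + o, 0,
                                   out.shape[axis] - 1), axis=axis)
    return out


def _patch_distance_field(data: np.ndarray, offset, sigma: float = 0.5) -> np.ndarray:
    """Gaussian-weighted SSD between the patch at every voxel and the patch at
    voxel + offset (3x3x3 support, sigma in voxels)."""
    diff = data - _shift(data, offset)
    return ndimage.gaussian_filter(diff * diff, sigma=sigma, mode="nearest",
                                   radius=1)


def patch_distance(img: Volume, x, r, p: int = 1, sigma: float = 0.5) -> float:
    """Dp(I, x, x + r) at a single voxel index x (r in voxel offsets)."""
    del p  # patch radius fixed at 1 (3x3x3) by the kernel radius
    field = _patch_distance_field(img.data, tuple(r), sigma=sigma)
    i, j, k = (int(v) for v in x)
    return float(field[i, j, k])


def compute_mind(
    img: Volume,
    offsets=SIX_CONNECTED,
    patch_radius: int = 1,
    sigma: float = 0.5,
    variance_floor_rel: float = 1e-6,
) -> MINDDescriptor:
    """Dense MIND field with six-connected search region and 3x3x3 patches."""
    if min(img.shape) < 5:
        raise ValueError("MIND needs at least 5 voxels per axis")
    dist = np.stack(
        [_patch_distance_field(img.data, o, sigma=sigma) for o in offsets],
        axis=-1,
    )
    v = dist.mean(axis=-1)
    floor = max(variance_floor_rel * max(float(v.mean()), np.finfo(float).tiny),
                np.finfo(float).tiny)
    v = np.maximum(v, floor)
    comp = np.exp(-dist / v[..., None])
    comp /= comp.max(axis=-1, keepdims=True)  # per-voxel max-normalisation
    return MINDDescriptor(comp, img, offsets=offsets, patch_radius=patch_radius)


def _sample_components(desc: MINDDescriptor, points: np.ndarray):
    """Trilinear interpolation of all descriptor components at physical
    points, with analytic spatial gradients; returns (vals (N,C),
    grads (N,C,3), inside (N,))."""
    ref = desc.reference
    idx = ref.physical_to_voxel(points)
    shape = np.array(ref.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    i0 = np.clip(np.floor(idx).astype(int), 0, np.maximum(shape - 2, 0))
    f = idx - i0
    d = desc.components
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    g = {}
    for a in range(2):
        for b in range(2):
            for c in range(2):
                g[(a, b, c)] = d[ix + a, iy + b, iz + c]
    fx, fy, fz = (f[:, i][:, None] for i in range(3))
    c00 = g[0, 0, 0] * (1 - fx) + g[1, 0, 0] * fx
    c10 = g[0, 1, 0] * (1 - fx) + g[1, 1, 0] * fx
    c01 = g[0, 0, 1] * (1 - fx) + g[1, 0, 1] * fx
    c11 = g[0, 1, 1] * (1 - fx) + g[1, 1, 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    vals = c0 * (1 - fz) + c1 * fz
    gx = (((g[1, 0, 0] - g[0, 0, 0]) * (1 - fy) + (g[1, 1, 0] - g[0, 1, 0]) * fy)
          * (1 - fz)
          + ((g[1, 0, 1] - g[0, 0, 1]) * (1 - fy) + (g[1, 1, 1] - g[0, 1, 1]) * fy)
          * fz)
    gy = (c10 - c00) * (1 - fz) + (c11 - c01) * fz
    gz = c1 - c0
    grads_idx = np.stack([gx, gy, gz], axis=-1)  # (N, C, 3)
    grads = (grads_idx / ref.spacing) @ ref.direction.T
    vals[~inside] = 0.0
    grads[~inside] = 0.0
    return vals, grads, inside


def mind_sad(
    fixed_mind: MINDDescriptor,
    moving_mind: MINDDescriptor,
    transform=None,
    points: np.ndarray | None = None,
) -> float:
    """Mean over sampled voxels of the per-voxel SAD between descriptors.

    ``points`` defaults to every fixed voxel centre; samples mapping outside
    the moving image are discarded.
    """
    if points is None:
        points = fixed_mind.reference.grid_points()
    points = np.atleast_2d(np.asarray(points, float))
    mapped = transform.apply(points) if transform is not None else points
    fvals, _, fin = _sample_components(fixed_mind, points)
    mvals, _, min_ = _sample_components(moving_mind, mapped)
    keep = fin & min_
    if not keep.any():
        raise ValueError("empty overlap region for MIND-SAD")
    return float(np.abs(fvals[keep] - mvals[keep]).mean())


def mind_sad_cost_and_gradient(fixed_mind, moving_mind, transform, points):
    """SAD cost and its analytic gradient with respect to the transform
    parameters (subgradient of |.| at exact ties taken as 0)."""
    points = np.atleast_2d(np.asarray(points, float))
    mapped = transform.apply(points)
    fvals, _, fin = _sample_components(fixed_mind, points)
    mvals, mgrads, min_ = _sample_components(moving_mind, mapped)
    keep = fin & min_
    if keep.sum() < 2:
        raise ValueError("empty overlap region for MIND-SAD")
    diff = fvals[keep] - mvals[keep]  # (N, C)
    n, c = diff.shape
    cost = float(np.abs(diff).mean())
    # d|f-m|/dm = -sign(f-m); average over components and samples
    w = -np.sign(diff) / (n * c)
    vectors = np.einsum("nc,ncd->nd", w, mgrads[keep])
    grad = transform.accumulate_parameter_gradient(points[keep], vectors)
    return cost, grad


class MINDRegistration(BSplineRegistration):
    """Hierarchical B-spline registration driven by MIND-SAD.

    Reuses the BEP-NMI pipeline's lattice schedule, smoothing and ASGD
    settings, swapping only the similarity; descriptors are recomputed per
    pyramid level on the smoothed images.  ``gamma2`` is ignored (no penalty
    term, the baseline runs unregularised).
    """

    def _prepare_level(self, fixed_s: Volume, moving_s: Volume) -> dict:
        return {
            "fixed_mind": compute_mind(fixed_s),
            "moving_mind": compute_mind(moving_s),
        }

    def _cost_and_gradient(self, fixed_s, moving_s, transform, pts, level_data):
        return mind_sad_cost_and_gradient(
            level_data["fixed_mind"], level_data["moving_mind"], transform, pts
        )


def register_mind(
    fixed: Volume, moving: Volume, init: AffineTransform | None = None, **params
) -> BSplineFFD:
    return MINDRegistration(**params).fit(fixed, moving, init_affine=init).ffd_
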