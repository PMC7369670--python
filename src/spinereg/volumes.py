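"""3D scalar volumes with physical-space metadata.

A :class:`Volume` couples a 3D intensity array with voxel spacing, origin and
an orthonormal direction matrix, so that every operation downstream (sampling,
resampling, metric evaluation, landmark arithmetic) works in physical
millimetre coordinates.  This matters for CT/MR spine pairs, whose grids
differ in both in-plane resolution and slice thickness: voxel-index arithmetic
between the two modalities is meaningless.

Arrays are indexed ``[x, y, z]``; the physical position of voxel ``(i, j, k)``
is ``origin + direction @ (spacing * (i, j, k))``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Volume",
    "PyramidSpec",
    "read_volume",
    "write_volume",
    "sample",
    "sample_with_gradient",
    "resample",
    "gaussian_smooth",
    "build_pyramid",
]

_SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mhd", ".mha")


@dataclass
class Volume:
    """3D scalar image plus grid-to-physical metadata (mm)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D image: data has {self.data.ndim} dimensions")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (N, 3), to physical mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return ((pts - self.origin) @ self.direction) / self.spacing

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape (nx*ny*nz, 3)."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.voxel_to_physical(idx)

    def physical_center(self) -> np.ndarray:
        return self.voxel_to_physical((np.array(self.shape, float) - 1) / 2)[0]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned physical bounding box (min, max) of the voxel centres."""
        corners_idx = np.array(
            [
                [i, j, k]
                for i in (0, self.shape[0] - 1)
                for j in (0, self.shape[1] - 1)
                for k in (0, self.shape[2] - 1)
            ],
            dtype=float,
        )
        corners = self.voxel_to_physical(corners_idx)
        return corners.min(axis=0), corners.max(axis=0)

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else np.asarray(data, float),
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            direction=self.direction.copy(),
        )

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class PyramidSpec:
    """Multi-resolution schedule, coarsest level first.

    ``downsample_factors[k] == 1`` means "smooth only" (the Gaussian pyramid
    used by the deformable stage); larger factors subsample the grid.  When
    ``smoothing_sigmas`` is None each level defaults to ``factor / 2`` voxels
    (in mm, per axis), the usual anti-aliasing heuristic.
    """

    levels: int
    downsample_factors: tuple[int, ...]
    smoothing_sigmas: tuple | None = None

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.downsample_factors) != self.levels:
            raise ValueError("downsample_factors length must equal levels")
        if any(f < 1 for f in self.downsample_factors):
            raise ValueError("downsample factors must be >= 1")
        if any(
            a < b
            for a, b in zip(self.downsample_factors, self.downsample_factors[1:])
        ):
            raise ValueError("factors must be non-increasing toward the finest level")
        if self.smoothing_sigmas is not None and len(self.smoothing_sigmas) != self.levels:
            raise ValueError("smoothing_sigmas length must equal levels")

    def sigmas_mm(self, spacing: np.ndarray) -> list[np.ndarray]:
        if self.smoothing_sigmas is not None:
            return [np.asarray(s, float) * np.ones(3) for s in self.smoothing_sigmas]
        return [f / 2.0 * np.asarray(spacing, float) for f in self.downsample_factors]


# ---------------------------------------------------------------------------
# file I/O


def _check_extension(path: str) -> None:
    if not str(path).endswith(_SUPPORTED_EXTENSIONS):
        raise ValueError(
            f"unsupported extension for {path!r}; supported formats: "
            + ", ".join(_SUPPORTED_EXTENSIONS)
        )


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) file."""
    path = str(path)
    _check_extension(path)
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # pragma: no cover - message re-raise
        raise IOError(f"cannot read {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D image: {path!r} has dimension {img.GetDimension()}")
    # SimpleITK arrays come back [z, y, x]; we store [x, y, z].
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return Volume(
        data=data,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
    )


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume; the extension selects the format."""
    path = str(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(v.spacing))
    img.SetOrigin(tuple(v.origin))
    img.SetDirection(tuple(v.direction.ravel()))
    sitk.WriteImage(img, path)


# ---------------------------------------------------------------------------
# sampling


def sample_with_gradient(
    v: Volume, points: np.ndarray, fill_value: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trilinear interpolation of ``v`` at physical points, with the analytic
    spatial gradient of the interpolant.

    Returns ``(values (N,), gradients (N, 3) in 1/mm, inside (N,) bool)``.
    Out-of-domain points get ``fill_value`` and a zero gradient.  The gradient
    is the exact derivative of the piecewise-trilinear interpolant, so central
    finite differences of :func:`sample` reproduce it whenever the probe stays
    within one grid cell.
    """
    idx = v.physical_to_voxel(points)
    n = idx.shape[0]
    shape = np.array(v.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)

    i0 = np.clip(np.floor(idx).astype(int), 0, np.maximum(shape - 2, 0))
    f = idx - i0

    d = v.data
    nx, ny, nz = v.shape
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    ix1 = np.minimum(ix + 1, nx - 1)
    iy1 = np.minimum(iy + 1, ny - 1)
    iz1 = np.minimum(iz + 1, nz - 1)

    c000 = d[ix, iy, iz]
    c100 = d[ix1, iy, iz]
    c010 = d[ix, iy1, iz]
    c110 = d[ix1, iy1, iz]
    c001 = d[ix, iy, iz1]
    c101 = d[ix1, iy, iz1]
    c011 = d[ix, iy1, iz1]
    c111 = d[ix1, iy1, iz1]

    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    values = c0 * (1 - fz) + c1 * fz

    # partials with respect to continuous index
    dx0 = c100 - c000
    dx1 = c110 - c010
    dx2 = c101 - c001
    dx3 = c111 - c011
    gx = ((dx0 * (1 - fy) + dx1 * fy) * (1 - fz)
          + (dx2 * (1 - fy) + dx3 * fy) * fz)
    gy = ((c10 - c00) * (1 - fz) + (c11 - c01) * fz)
    gz = c1 - c0
    grad_idx = np.stack([gx, gy, gz], axis=1)
    # chain rule: index = direction.T @ (p - origin) / spacing
    grad_phys = (grad_idx / v.spacing) @ v.direction.T

    values = np.where(inside, values, fill_value)
    grad_phys[~inside] = 0.0
    if not np.all(np.isfinite(idx)):
        bad = ~np.all(np.isfinite(idx), axis=1)
        values = np.where(bad, fill_value, values)
        grad_phys[bad] = 0.0
        inside = inside & ~bad
    return values, grad_phys, inside


def sample(v: Volume, points: np.ndarray, fill_value: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of ``v`` at physical mm points (N, 3)."""
    values, _, _ = sample_with_gradient(v, points, fill_value=fill_value)
    return values


def sample_nearest(v: Volume, points: np.ndarray, fill_value: float = 0.0) -> np.ndarray:
    """Nearest-neighbour interpolation (used for binary label masks)."""
    idx = v.physical_to_voxel(points)
    shape = np.array(v.shape)
    inside = np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=1)
    i0 = np.clip(np.rint(idx).astype(int), 0, shape - 1)
    values = v.data[i0[:, 0], i0[:, 1], i0[:, 2]]
    return np.where(inside, values, fill_value)


def resample(
    moving: Volume,
    transform,
    reference: Volume,
    fill_value: float = 0.0,
    nearest: bool = False,
) -> Volume:
    """Pull-back resampling of ``moving`` onto ``reference``'s grid.

    ``transform`` maps reference-space physical points into moving-space
    physical points (the standard resampling convention); ``transform=None``
    means identity.
    """
    pts = reference.grid_points()
    if transform is not None:
        pts = transform.apply(pts)
    if nearest:
        vals = sample_nearest(moving, pts, fill_value=fill_value)
    else:
        vals = sample(moving, pts, fill_value=fill_value)
    out = reference.copy(data=vals.reshape(reference.shape))
    return out


# ---------------------------------------------------------------------------
# smoothing and pyramids


def gaussian_smooth(v: Volume, sigma_mm) -> Volume:
    """Separable Gaussian smoothing with sigma given in millimetres."""
    sigma_mm = np.asarray(sigma_mm, dtype=float) * np.ones(3)
    if np.any(sigma_mm < 0):
        raise ValueError(f"sigma must be >= 0, got {sigma_mm}")
    if np.all(sigma_mm == 0):
        return v.copy()
    sigma_vox = sigma_mm / v.spacing
    data = ndimage.gaussian_filter(v.data, sigma=sigma_vox, mode="nearest")
    return v.copy(data=data)


def build_pyramid(v: Volume, spec: PyramidSpec) -> list[Volume]:
    """Smooth-then-subsample pyramid, coarsest level first.

    Subsampling keeps voxel ``0`` so voxel-centre positions are preserved;
    spacing is scaled by the factor so the physical extent is unchanged up to
    one (coarse) voxel.
    """
    out = []
    for factor, sigma in zip(spec.downsample_factors, spec.sigmas_mm(v.spacing)):
        if factor >= min(v.shape):
            raise ValueError(
                f"downsample factor {factor} too large for shape {v.shape}"
            )
        level = gaussian_smooth(v, sigma)
        if factor > 1:
            level = Volume(
                data=level.data[::factor, ::factor, ::factor].copy(),
                spacing=v.spacing * factor,
                origin=v.origin.copy(),
                direction=v.direction.copy(),
            )
        out.append(level)
    return out
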