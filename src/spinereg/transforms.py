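"""Spatial transform models: affine and cubic B-spline free-form deformation.

All transforms map *fixed-image* physical coordinates (mm) to *moving-image*
physical coordinates, the convention under which pull-back resampling of the
moving image onto the fixed grid is directly computable.

The affine model is ``T(x) = R (x - c) + t + c`` with 12 free parameters (the
nine entries of R plus the translation t; the rotation centre c is fixed
metadata, not optimised).  The deformable model is a free-form deformation
(FFD): displacement vectors on a regular control-point lattice, interpolated
by the tensor product of uniform cubic B-splines

    B0(u) = (1-u)^3 / 6
    B1(u) = (3u^3 - 6u^2 + 4) / 6
    B2(u) = (-3u^3 + 3u^2 + 3u + 1) / 6
    B3(u) = u^3 / 6,   0 <= u < 1.

The basis is a partition of unity and C2-smooth, which gives the deformation
local support (a control point influences a 4x4x4-cell neighbourhood) and
well-defined analytic second derivatives for the bending-energy penalty.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AffineTransform",
    "BSplineFFD",
    "CompositeTransform",
    "bspline_basis",
    "bspline_basis_d1",
    "bspline_basis_d2",
    "save_transform",
    "load_transform",
]


def _poly_basis(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    u2 = u * u
    u3 = u2 * u
    return np.stack(
        [
            (1 - u) ** 3 / 6.0,
            (3 * u3 - 6 * u2 + 4) / 6.0,
            (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0,
            u3 / 6.0,
        ],
        axis=-1,
    )


def bspline_basis(u) -> np.ndarray:
    """The four cubic B-spline basis values (B0..B3) at fraction u in [0, 1)."""
    ua = np.asarray(u, dtype=float)
    if np.any(ua < 0) or np.any(ua >= 1):
        raise ValueError("u must lie in [0, 1)")
    return _poly_basis(ua)


def bspline_basis_d1(u) -> np.ndarray:
    """First derivatives dB/du of the four basis functions."""
    u = np.asarray(u, dtype=float)
    u2 = u * u
    return np.stack(
        [
            -((1 - u) ** 2) / 2.0,
            (3 * u2 - 4 * u) / 2.0,
            (-3 * u2 + 2 * u + 1) / 2.0,
            u2 / 2.0,
        ],
        axis=-1,
    )


def bspline_basis_d2(u) -> np.ndarray:
    """Second derivatives d2B/du2 of the four basis functions."""
    u = np.asarray(u, dtype=float)
    return np.stack([1 - u, 3 * u - 2, -3 * u + 1, u], axis=-1)


@dataclass
class AffineTransform:
    """12-parameter affine map about a fixed centre: T(x) = R(x-c) + t + c."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    c: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.c = np.asarray(self.c, dtype=float).reshape(3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.R)) or abs(np.linalg.det(self.R)) <= 1e-12:
            raise ValueError("R must be finite and invertible")

    @property
    def n_parameters(self) -> int:
        return 12

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.c) @ self.R.T + self.t + self.c

    def inverse(self) -> "AffineTransform":
        Rinv = np.linalg.inv(self.R)
        return AffineTransform(R=Rinv, c=self.c, t=-Rinv @ self.t)

    def get_parameters(self) -> np.ndarray:
        """mu: row-major R followed by t (length 12)."""
        return np.concatenate([self.R.ravel(), self.t])

    def set_parameters(self, mu: np.ndarray) -> None:
        mu = np.asarray(mu, dtype=float).ravel()
        if mu.size != 12:
            raise ValueError(f"expected 12 parameters, got {mu.size}")
        self.R = mu[:9].reshape(3, 3)
        self.t = mu[9:].copy()

    def accumulate_parameter_gradient(
        self, points: np.ndarray, vectors: np.ndarray
    ) -> np.ndarray:
        """Given per-point cost gradients w.r.t. T(x) (N, 3), return the chain
        product sum_i vectors_i^T dT(x_i)/dmu as a length-12 vector."""
        pts = np.atleast_2d(points) - self.c
        g = np.zeros(12)
        g[:9] = (vectors.T @ pts).ravel()  # dT_a/dR_ab = (x-c)_b
        g[9:] = vectors.sum(axis=0)
        return g

    def to_dict(self) -> dict:
        return {
            "type": "affine",
            "R": self.R.tolist(),
            "c": self.c.tolist(),
            "t": self.t.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(R=np.array(d["R"]), c=np.array(d["c"]), t=np.array(d["t"]))


class BSplineFFD:
    """Cubic B-spline free-form deformation on a regular lattice.

    ``coefficients`` has shape (px, py, pz, 3): one displacement vector (mm)
    per control point.  For a point x, grid-local coordinates are
    ``g = (x - grid_origin) / grid_spacing``; the supporting control points are
    ``i + l`` for ``i = floor(g) - 1`` and ``l = 0..3``, weighted by the basis
    at fraction ``u = g - floor(g)``.  The full spatial map is
    ``T(x) = x + displacement(x)``.
    """

    def __init__(self, grid_origin, grid_spacing, grid_shape, coefficients=None):
        self.grid_origin = np.asarray(grid_origin, dtype=float).reshape(3)
        self.grid_spacing = np.asarray(grid_spacing, dtype=float).reshape(3)
        if np.any(self.grid_spacing <= 0):
            raise ValueError("grid_spacing must be positive")
        self.grid_shape = tuple(int(s) for s in grid_shape)
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("lattice needs at least 4 control points per axis")
        if coefficients is None:
            coefficients = np.zeros(self.grid_shape + (3,))
        self.coefficients = np.asarray(coefficients, dtype=float).reshape(
            self.grid_shape + (3,)
        )

    @classmethod
    def from_domain(cls, bbox_min, bbox_max, grid_spacing) -> "BSplineFFD":
        """Lattice covering a physical bounding box with full cubic support
        plus one extra control-point layer on every face."""
        bbox_min = np.asarray(bbox_min, float)
        bbox_max = np.asarray(bbox_max, float)
        spacing = np.asarray(grid_spacing, float) * np.ones(3)
        origin = bbox_min - 2.0 * spacing
        extent = (bbox_max - origin) / spacing
        shape = np.floor(extent).astype(int) + 4
        return cls(grid_origin=origin, grid_spacing=spacing, grid_shape=shape)

    @property
    def n_parameters(self) -> int:
        px, py, pz = self.grid_shape
        return 3 * px * py * pz

    # -- lattice bookkeeping -------------------------------------------------

    def _local(self, points: np.ndarray):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = (pts - self.grid_origin) / self.grid_spacing
        base = np.floor(g).astype(int)
        u = g - base
        i = base - 1
        shape = np.array(self.grid_shape)
        if np.any(i < 0) or np.any(i + 3 > shape - 1):
            raise ValueError("point outside the region covered by the lattice")
        return i, u

    def covers(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = (pts - self.grid_origin) / self.grid_spacing
        base = np.floor(g).astype(int)
        shape = np.array(self.grid_shape)
        return np.all((base - 1 >= 0) & (base + 2 <= shape - 1), axis=1)

    def support_indices(self, points: np.ndarray):
        """Flat control-point indices (N, 64) in x-fastest lattice order and the
        per-axis basis fractions; shared by value/derivative evaluation."""
        i, u = self._local(points)
        px, py, pz = self.grid_shape
        offs = np.arange(4)
        # flat lattice index n = ix + px*(iy + py*iz)
        gx = i[:, 0:1] + offs  # (N, 4)
        gy = i[:, 1:2] + offs
        gz = i[:, 2:3] + offs
        flat = (
            gx[:, :, None, None]
            + px * (gy[:, None, :, None] + py * gz[:, None, None, :])
        ).reshape(-1, 64)
        return flat, u

    def _tensor_weights(self, u: np.ndarray, dx: int = 0, dy: int = 0, dz: int = 0):
        basis = {0: _poly_basis, 1: bspline_basis_d1, 2: bspline_basis_d2}
        wx = basis[dx](u[:, 0]) / self.grid_spacing[0] ** dx
        wy = basis[dy](u[:, 1]) / self.grid_spacing[1] ** dy
        wz = basis[dz](u[:, 2]) / self.grid_spacing[2] ** dz
        w = (
            wx[:, :, None, None]
            * wy[:, None, :, None]
            * wz[:, None, None, :]
        ).reshape(-1, 64)
        return w

    def interp_weights(self, points: np.ndarray):
        """(flat_indices (N, 64), weights (N, 64)) for value interpolation."""
        flat, u = self.support_indices(points)
        return flat, self._tensor_weights(u)

    # -- evaluation ----------------------------------------------------------

    def displacement(self, points: np.ndarray) -> np.ndarray:
        flat, w = self.interp_weights(points)
        coef = self.coefficients.transpose(2, 1, 0, 3).reshape(-1, 3)
        return np.einsum("nk,nkd->nd", w, coef[flat])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self.displacement(pts)

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """Spatial Jacobian of the full map T(x) = x + u(x), shape (N, 3, 3):
        J[d, a] = delta_da + du_d/dx_a (unitless)."""
        flat, u = self.support_indices(points)
        coef = self.coefficients.transpose(2, 1, 0, 3).reshape(-1, 3)
        n = flat.shape[0]
        out = np.tile(np.eye(3), (n, 1, 1))
        for a in range(3):
            orders = [0, 0, 0]
            orders[a] = 1
            w = self._tensor_weights(u, *orders)
            out[:, :, a] += np.einsum("nk,nkd->nd", w, coef[flat])
        return out

    _DERIV_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))

    def second_derivative_weights(self, points: np.ndarray):
        """Weights (N, 6, 64) for the six distinct second partials in the order
        (xx, yy, zz, xy, yz, zx), plus the flat support indices (N, 64)."""
        flat, u = self.support_indices(points)
        ws = []
        for a, b in self._DERIV_PAIRS:
            orders = [0, 0, 0]
            orders[a] += 1
            orders[b] += 1
            ws.append(self._tensor_weights(u, *orders))
        return flat, np.stack(ws, axis=1)

    def second_derivatives(self, points: np.ndarray) -> np.ndarray:
        """Analytic second partials d2T_d/(da db), shape (N, 3, 3, 3) symmetric
        in the last two axes, units 1/mm."""
        flat, w6 = self.second_derivative_weights(points)
        coef = self.coefficients.transpose(2, 1, 0, 3).reshape(-1, 3)
        vals = np.einsum("nqk,nkd->ndq", w6, coef[flat])  # (N, 3, 6)
        n = vals.shape[0]
        out = np.zeros((n, 3, 3, 3))
        for q, (a, b) in enumerate(self._DERIV_PAIRS):
            out[:, :, a, b] = vals[:, :, q]
            out[:, :, b, a] = vals[:, :, q]
        return out

    # -- parameter vector ----------------------------------------------------

    def get_parameters(self) -> np.ndarray:
        """mu in x-fastest lattice order, 3 displacement components per point."""
        return self.coefficients.transpose(2, 1, 0, 3).ravel().copy()

    def set_parameters(self, mu: np.ndarray) -> None:
        mu = np.asarray(mu, dtype=float).ravel()
        if mu.size != self.n_parameters:
            raise ValueError(
                f"expected {self.n_parameters} parameters, got {mu.size}"
            )
        px, py, pz = self.grid_shape
        self.coefficients = (
            mu.reshape(pz, py, px, 3).transpose(2, 1, 0, 3).copy()
        )

    def accumulate_parameter_gradient(
        self, points: np.ndarray, vectors: np.ndarray
    ) -> np.ndarray:
        """sum_i vectors_i^T dT(x_i)/dmu over the lattice, returned flat."""
        flat, w = self.interp_weights(points)
        n_pts = np.prod(self.grid_shape)
        grad = np.zeros((n_pts, 3))
        wv = w[:, :, None] * vectors[:, None, :]  # (N, 64, 3)
        for d in range(3):
            grad[:, d] = np.bincount(
                flat.ravel(), weights=wv[:, :, d].ravel(), minlength=n_pts
            )
        return grad.ravel()

    def control_point_positions(self) -> np.ndarray:
        px, py, pz = self.grid_shape
        ii, jj, kk = np.meshgrid(
            np.arange(px), np.arange(py), np.arange(pz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.grid_origin + idx * self.grid_spacing

    def to_dict(self) -> dict:
        return {
            "type": "bspline_ffd",
            "grid_origin": self.grid_origin.tolist(),
            "grid_spacing": self.grid_spacing.tolist(),
            "grid_shape": list(self.grid_shape),
            "coefficients": self.coefficients.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineFFD":
        shape = tuple(d["grid_shape"])
        coef = np.array(d["coefficients"]).reshape(shape + (3,))
        return cls(d["grid_origin"], d["grid_spacing"], shape, coef)


class CompositeTransform:
    """Affine stage followed by an additive FFD refinement.

    ``T(x) = affine(x) + ffd_displacement(x)`` — the displacement field is
    parameterised over the *fixed-image* frame, which keeps the bending-energy
    penalty a pure function of the FFD stage and leaves the affine result
    untouched as the deformable stage's frozen initialisation.
    """

    def __init__(self, affine: AffineTransform, ffd: BSplineFFD):
        self.affine = affine
        self.ffd = ffd

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.affine.apply(pts) + self.ffd.displacement(pts)

    @property
    def n_parameters(self) -> int:
        return self.ffd.n_parameters

    def get_parameters(self) -> np.ndarray:
        return self.ffd.get_parameters()

    def set_parameters(self, mu: np.ndarray) -> None:
        self.ffd.set_parameters(mu)

    def accumulate_parameter_gradient(self, points, vectors) -> np.ndarray:
        # affine is frozen; only the FFD coefficients carry gradient
        return self.ffd.accumulate_parameter_gradient(points, vectors)

    def to_dict(self) -> dict:
        return {
            "type": "composite",
            "affine": self.affine.to_dict(),
            "ffd": self.ffd.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeTransform":
        return cls(
            AffineTransform.from_dict(d["affine"]),
            BSplineFFD.from_dict(d["ffd"]),
        )


_TYPES = {
    "affine": AffineTransform,
    "bspline_ffd": BSplineFFD,
    "composite": CompositeTransform,
}


def save_transform(transform, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh)


def load_transform(path: str | os.PathLike):
    with open(path) as fh:
        d = json.load(fh)
    try:
        cls = _TYPES[d["type"]]
    except KeyError as exc:
        raise ValueError(f"unknown transform type in {path!r}: {d.get('type')}") from exc
    return cls.from_dict(d)
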