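"""Coarse-to-fine registration estimators.

The framework registers a multimodal pair in two stages:

1. **Affine stage** — a 12-parameter affine transform maximises NMI over a
   3-level recursive pyramid (smooth + downsample by 2 per level), giving
   global positioning of the whole body.
2. **Deformable stage** — a cubic B-spline free-form deformation refines the
   frozen affine result by minimising bending-energy-penalised NMI
   (C = -NMI + gamma2 * P) over a Gaussian pyramid *without* downsampling,
   with the control-point spacing tightened level by level.

Both stages are driven by adaptive stochastic gradient descent on a fresh
random voxel subset per iteration.

The estimators follow scikit-learn conventions: constructor arguments are
plain hyperparameters, ``fit(fixed, moving)`` performs the registration, and
fitted results live in trailing-underscore attributes (``transform_``,
``traces_`` ...).  ``register_affine`` / ``register_deformable`` /
``register_coarse_to_fine`` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from . import metrics
from .optimizer import ASGDConfig, SamplerConfig, asgd_minimize, draw_samples
from .transforms import AffineTransform, BSplineFFD, CompositeTransform
from .volumes import PyramidSpec, Volume, build_pyramid, gaussian_smooth, resample

__all__ = [
    "AffineRegistration",
    "BSplineRegistration",
    "CoarseToFineRegistration",
    "RegistrationResult",
    "register_affine",
    "register_deformable",
    "register_coarse_to_fine",
    "dense_nmi",
]


def _center_of_mass(v: Volume) -> np.ndarray:
    w = v.data - v.data.min()
    total = w.sum()
    if total <= 0:
        return v.physical_center()
    nx, ny, nz = v.shape
    idx = np.array(
        [
            (w.sum(axis=(1, 2)) * np.arange(nx)).sum(),
            (w.sum(axis=(0, 2)) * np.arange(ny)).sum(),
            (w.sum(axis=(0, 1)) * np.arange(nz)).sum(),
        ]
    ) / total
    return v.voxel_to_physical(idx)[0]


def dense_nmi(fixed: Volume, moving: Volume, transform, bins: int = 32,
              step: int = 2, kernel: str = "discrete") -> float:
    """Deterministic NMI on a regular subgrid of fixed voxel centres (no
    stochastic sampling), by default with the discrete (nearest-bin)
    histogram, for which NMI(I, I) = 2 holds exactly; used for reporting and
    monotonicity checks."""
    nx, ny, nz = fixed.shape
    ii, jj, kk = np.meshgrid(
        np.arange(0, nx, step), np.arange(0, ny, step), np.arange(0, nz, step),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = fixed.voxel_to_physical(idx)
    h = metrics.estimate_joint_histogram(fixed, moving, transform, pts, bins,
                                         kernel=kernel)
    return metrics.normalized_mutual_information(h)


def _trace_frame(records: list[dict], **extra) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records)
    for k, v in extra.items():
        df[k] = v
    return df


class AffineRegistration(BaseEstimator):
    """Global affine/NMI registration over a downsampling pyramid.

    Parameters
    ----------
    levels : pyramid depth (coarsest level downsampled by 2**(levels-1)).
    bins : intensity bins for the Parzen joint histogram.
    iterations : ASGD iterations per pyramid level.
    n_samples : stochastic samples per iteration.
    init_step : target size of the first parameter update (mm-equivalent).
    center_init : "com" aligns centres of mass before optimisation, "none"
        starts from the identity.
    seed : seed for all stochastic sampling.
    """

    def __init__(
        self,
        levels: int = 3,
        smoothing_sigmas: Sequence[float] | None = (2.0, 1.0, 0.0),
        bins: int = 64,
        iterations: int = 300,
        n_samples: int = 2048,
        init_step: float = 0.5,
        A: float = 20.0,
        alpha: float = 1.0,
        center_init: str = "com",
        seed: int = 0,
    ):
        self.levels = levels
        self.smoothing_sigmas = smoothing_sigmas
        self.bins = bins
        self.iterations = iterations
        self.n_samples = n_samples
        self.init_step = init_step
        self.A = A
        self.alpha = alpha
        self.center_init = center_init
        self.seed = seed

    def pyramid_spec(self, spacing=None) -> PyramidSpec:
        """Smoothing sigmas are given in voxels of the target image; sigma 0 at
        the finest level preserves the sharp detail that pins down rotation."""
        factors = tuple(2 ** (self.levels - 1 - k) for k in range(self.levels))
        sigmas = None
        if self.smoothing_sigmas is not None and spacing is not None:
            sigmas = tuple(
                np.asarray(s, float) * np.asarray(spacing, float)
                for s in self.smoothing_sigmas
            )
        return PyramidSpec(levels=self.levels, downsample_factors=factors,
                           smoothing_sigmas=sigmas)

    def fit(self, fixed: Volume, moving: Volume) -> "AffineRegistration":
        if np.ptp(fixed.data) == 0 or np.ptp(moving.data) == 0:
            raise ValueError("registration needs intensity variation in both images")
        # one physical smoothing schedule for both images (sigmas interpreted
        # in fixed-image voxels) so the two modalities are blurred equally
        fpyr = build_pyramid(fixed, self.pyramid_spec(fixed.spacing))
        mpyr = build_pyramid(moving, self.pyramid_spec(fixed.spacing))

        center = fixed.physical_center()
        t0 = np.zeros(3)
        if self.center_init == "com":
            t0 = _center_of_mass(moving) - _center_of_mass(fixed)
        transform = AffineTransform(R=np.eye(3), c=center, t=t0)
        mu = transform.get_parameters()

        # Parameter scaling: an R-entry step of size s displaces points by
        # ~s * |x - c|, so R entries are scaled by the mean squared extent.
        lo, hi = fixed.bounding_box()
        half = (hi - lo) / 2.0
        var = np.maximum(half**2 / 3.0, 1.0)  # E[(x-c)_b^2] over the box
        scales = np.concatenate([np.tile(var, 3), np.ones(3)])

        self.traces_ = []
        for level, (flev, mlev) in enumerate(zip(fpyr, mpyr)):
            rf = metrics.robust_intensity_range(flev)
            rm = metrics.robust_intensity_range(mlev)
            sampler = SamplerConfig(
                n_samples=self.n_samples,
                seed=int(np.random.SeedSequence([self.seed, 1, level]).generate_state(1)[0] % (2**31)),
            )

            def cost_and_grad(mu_k, k, flev=flev, mlev=mlev, rf=rf, rm=rm,
                              sampler=sampler):
                transform.set_parameters(mu_k)
                pts = draw_samples(flev, sampler, k)
                terms, grad = metrics.cost_and_gradient(
                    flev, mlev, transform, pts, bins=self.bins,
                    gamma1=1.0, gamma2=0.0, range_fixed=rf, range_moving=rm,
                )
                return terms.total, grad

            cfg = ASGDConfig(
                max_iterations=self.iterations, A=self.A, alpha=self.alpha,
                init_step=self.init_step,
            )
            try:
                mu, rec = asgd_minimize(cost_and_grad, mu, cfg, scales=scales)
            except ValueError as exc:
                raise RuntimeError(f"affine stage failed at level {level}: {exc}") from exc
            self.traces_.append(_trace_frame(rec, stage="affine", level=level))

        transform.set_parameters(mu)
        self.transform_ = transform
        return self

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-space physical points into moving space."""
        return self.transform_.apply(points)


class BSplineRegistration(BaseEstimator):
    """Hierarchical B-spline deformation driven by BEP-NMI.

    The affine initialisation is frozen; only FFD coefficients are optimised.
    ``grid_spacing_schedule`` gives the control-point spacing (mm) per level,
    coarse to fine; ``smoothing_sigmas`` the Gaussian smoothing per level in
    voxels (no downsampling).  ``gamma1``/``gamma2`` weigh similarity against
    bending energy (defaults 1 and 1).
    """

    def __init__(
        self,
        grid_spacing_schedule: Sequence[float] = (28.0, 20.0),
        smoothing_sigmas: Sequence[float] = (1.0, 0.5),
        bins: int = 32,
        iterations: int = 300,
        n_samples: int = 2048,
        gamma1: float = 1.0,
        gamma2: float = 1.0,
        init_step: float = 0.5,
        A: float = 20.0,
        alpha: float = 1.0,
        seed: int = 0,
    ):
        self.grid_spacing_schedule = grid_spacing_schedule
        self.smoothing_sigmas = smoothing_sigmas
        self.bins = bins
        self.iterations = iterations
        self.n_samples = n_samples
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.init_step = init_step
        self.A = A
        self.alpha = alpha
        self.seed = seed

    # hook: subclasses may substitute a different similarity (e.g. MIND-SAD)
    def _prepare_level(self, fixed_s: Volume, moving_s: Volume) -> dict:
        return {
            "range_fixed": metrics.robust_intensity_range(fixed_s),
            "range_moving": metrics.robust_intensity_range(moving_s),
        }

    def _cost_and_gradient(self, fixed_s, moving_s, transform, pts, level_data):
        terms, grad = metrics.cost_and_gradient(
            fixed_s, moving_s, transform, pts, bins=self.bins,
            gamma1=self.gamma1, gamma2=self.gamma2,
            range_fixed=level_data["range_fixed"],
            range_moving=level_data["range_moving"],
        )
        return terms.total, grad

    def fit(
        self,
        fixed: Volume,
        moving: Volume,
        init_affine: AffineTransform | None = None,
    ) -> "BSplineRegistration":
        if init_affine is None:
            init_affine = AffineTransform(c=fixed.physical_center())
        schedule = list(self.grid_spacing_schedule)
        sigmas = list(self.smoothing_sigmas)
        if len(sigmas) != len(schedule):
            raise ValueError("smoothing_sigmas and grid_spacing_schedule lengths differ")
        lo, hi = fixed.bounding_box()

        self.traces_ = []
        prev_ffd: BSplineFFD | None = None
        for level, (gspace, sig) in enumerate(zip(schedule, sigmas)):
            sigma_mm = np.asarray(sig) * fixed.spacing
            fixed_s = gaussian_smooth(fixed, sigma_mm)
            moving_s = gaussian_smooth(moving, sigma_mm)
            ffd = BSplineFFD.from_domain(lo, hi, gspace)
            if prev_ffd is not None:
                # initialise the finer lattice from the coarser field by
                # evaluating the previous displacement at the new control points
                cp = ffd.control_point_positions()
                ok = prev_ffd.covers(cp)
                disp = np.zeros_like(cp)
                if ok.any():
                    disp[ok] = prev_ffd.displacement(cp[ok])
                ffd.coefficients = disp.reshape(ffd.grid_shape + (3,))
            transform = CompositeTransform(init_affine, ffd)
            mu = transform.get_parameters()
            level_data = self._prepare_level(fixed_s, moving_s)
            sampler = SamplerConfig(
                n_samples=self.n_samples,
                seed=int(np.random.SeedSequence([self.seed, 2, level]).generate_state(1)[0] % (2**31)),
            )

            def cost_and_grad(mu_k, k, fixed_s=fixed_s, moving_s=moving_s,
                              transform=transform, level_data=level_data,
                              sampler=sampler):
                transform.set_parameters(mu_k)
                pts = draw_samples(fixed_s, sampler, k)
                return self._cost_and_gradient(
                    fixed_s, moving_s, transform, pts, level_data
                )

            cfg = ASGDConfig(
                max_iterations=self.iterations, A=self.A, alpha=self.alpha,
                init_step=self.init_step,
            )
            try:
                mu, rec = asgd_minimize(cost_and_grad, mu, cfg)
            except ValueError as exc:
                raise RuntimeError(
                    f"deformable stage failed at level {level}: {exc}"
                ) from exc
            ffd.set_parameters(mu)
            prev_ffd = ffd
            self.traces_.append(_trace_frame(rec, stage="deformable", level=level))

        self.ffd_ = prev_ffd
        self.affine_ = init_affine
        self.transform_ = CompositeTransform(init_affine, prev_ffd)
        return self

    def predict(self, points: np.ndarray) -> np.ndarray:
        return self.transform_.apply(points)


@dataclass
class RegistrationResult:
    """Everything the two-stage pipeline produces."""

    affine: AffineTransform
    ffd: BSplineFFD
    composite: CompositeTransform
    traces: pd.DataFrame
    warped_moving: Volume


class CoarseToFineRegistration(BaseEstimator):
    """Full two-stage pipeline: affine/NMI, then B-spline/BEP-NMI.

    ``affine`` and ``deformable`` are estimator prototypes (cloned before
    fitting, scikit-learn style); ``seed`` overrides both stages' seeds so a
    single integer reproduces the whole run.
    """

    def __init__(
        self,
        affine: AffineRegistration | None = None,
        deformable: BSplineRegistration | None = None,
        seed: int = 0,
    ):
        self.affine = affine
        self.deformable = deformable
        self.seed = seed

    def fit(self, fixed: Volume, moving: Volume) -> "CoarseToFineRegistration":
        aff_est = clone(self.affine) if self.affine is not None else AffineRegistration()
        def_est = (
            clone(self.deformable) if self.deformable is not None
            else BSplineRegistration()
        )
        aff_est.set_params(seed=self.seed)
        def_est.set_params(seed=self.seed)
        try:
            aff_est.fit(fixed, moving)
        except Exception as exc:
            raise RuntimeError(f"affine stage: {exc}") from exc
        try:
            def_est.fit(fixed, moving, init_affine=aff_est.transform_)
        except Exception as exc:
            raise RuntimeError(f"deformable stage: {exc}") from exc

        composite = def_est.transform_
        traces = pd.concat(aff_est.traces_ + def_est.traces_, ignore_index=True)
        self.affine_estimator_ = aff_est
        self.deformable_estimator_ = def_est
        self.result_ = RegistrationResult(
            affine=aff_est.transform_,
            ffd=def_est.ffd_,
            composite=composite,
            traces=traces,
            warped_moving=resample(moving, composite, fixed),
        )
        self.transform_ = composite
        return self

    def predict(self, points: np.ndarray) -> np.ndarray:
        return self.transform_.apply(points)


# ---------------------------------------------------------------------------
# functional wrappers


def register_affine(fixed: Volume, moving: Volume, **params) -> AffineTransform:
    return AffineRegistration(**params).fit(fixed, moving).transform_


def register_deformable(
    fixed: Volume, moving: Volume, init: AffineTransform | None = None, **params
) -> BSplineFFD:
    return BSplineRegistration(**params).fit(fixed, moving, init_affine=init).ffd_


def register_coarse_to_fine(
    fixed: Volume,
    moving: Volume,
    affine: AffineRegistration | None = None,
    deformable: BSplineRegistration | None = None,
    seed: int = 0,
) -> RegistrationResult:
    est = CoarseToFineRegistration(affine=affine, deformable=deformable, seed=seed)
    return est.fit(fixed, moving).result_
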