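"""Similarity metrics and regularisation for multimodal registration.

The similarity driving both stages is normalized mutual information,

    NMI(IF; IM) = (H(IF) + H(IM)) / H(IF, IM),

estimated from a Parzen-windowed joint histogram: each stochastic sample
spreads kernel mass over intensity bins — a first-order (linear) kernel along
the fixed-intensity axis and a cubic B-spline kernel along the moving axis.
The cubic kernel makes the joint density, and hence NMI, twice continuously
differentiable in the moving intensities, which is what permits an analytic
gradient with respect to the transform parameters.

The deformable stage adds a bending-energy penalty: the discretely sampled
mean of the squared second spatial derivatives of the transform,

    P = (1/N) sum_x [ Txx^2 + Tyy^2 + Tzz^2 + 2 Txy^2 + 2 Tyz^2 + 2 Tzx^2 ]

summed over the three displacement components (derivatives in 1/mm, so P
carries mm^-2 scale).  P vanishes exactly on affine fields, so rigid
structures pay no penalty, while strongly curved deformations do.  The
combined cost is ``C = gamma1 * S + gamma2 * P`` with ``S = -NMI`` (minimising
C maximises NMI); both weights default to 1.

Entropies use the natural logarithm (nats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import (
    BSplineFFD,
    CompositeTransform,
    bspline_basis,
    bspline_basis_d1,
)
from .volumes import Volume, sample_with_gradient

__all__ = [
    "JointHistogram",
    "CostTerms",
    "robust_intensity_range",
    "estimate_joint_histogram",
    "mutual_information",
    "normalized_mutual_information",
    "bending_energy",
    "bending_energy_gradient",
    "bep_nmi_cost",
    "cost_and_gradient",
]

# weights of the six distinct second-derivative terms (cross terms doubled)
_BEP_WEIGHTS = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


@dataclass
class JointHistogram:
    """Parzen-smoothed joint intensity mass, normalised to total mass 1.

    ``counts`` has one guard bin below/above the fixed range and two along the
    moving range so the kernels never truncate; the guard bins hold genuine
    mass and enter the entropies.
    """

    counts: np.ndarray
    bins: int
    range_fixed: tuple[float, float]
    range_moving: tuple[float, float]
    n_samples: int

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        return self.counts.sum(axis=1), self.counts.sum(axis=0)


@dataclass
class CostTerms:
    """Decomposed registration cost C = gamma1 * S + gamma2 * P."""

    similarity: float  # S = -NMI
    penalty: float  # P = bending energy (mm^-2)
    gamma1: float
    gamma2: float
    nmi: float
    n_samples: int

    @property
    def total(self) -> float:
        return self.gamma1 * self.similarity + self.gamma2 * self.penalty


def robust_intensity_range(v: Volume, lo: float = 0.5, hi: float = 99.5):
    """Percentile-clipped intensity range, resistant to outliers and
    bias-field tails."""
    a, b = np.percentile(v.data, [lo, hi])
    if b <= a:
        b = a + 1.0
    return float(a), float(b)


def _parzen_terms(values: np.ndarray, vrange, bins: int):
    """Bin coordinates, support offsets and kernel weights for the cubic
    Parzen kernel; returns (base_bin, weights (N,4), dweights/dvalue (N,4))."""
    lo, hi = vrange
    scale = (bins - 1) / (hi - lo)
    b = (values - lo) * scale
    clipped = (b < 0) | (b > bins - 1)
    b = np.clip(b, 0.0, bins - 1)
    base = np.floor(b).astype(int)
    u = b - base
    w = bspline_basis(u)
    dw = bspline_basis_d1(u) * scale
    dw[clipped] = 0.0
    return base, w, dw


def _linear_terms(values: np.ndarray, vrange, bins: int):
    lo, hi = vrange
    scale = (bins - 1) / (hi - lo)
    b = np.clip((values - lo) * scale, 0.0, bins - 1)
    base = np.floor(b).astype(int)
    u = b - base
    w = np.stack([1.0 - u, u], axis=1)
    return base, w


def joint_histogram_from_values(
    fixed_values: np.ndarray,
    moving_values: np.ndarray,
    bins: int,
    range_fixed,
    range_moving,
    kernel: str = "parzen",
) -> JointHistogram:
    """Build the joint histogram from paired intensity samples.

    ``kernel="parzen"`` (linear x cubic B-spline) gives the differentiable
    estimate used during optimisation; ``kernel="discrete"`` assigns each
    sample to its nearest bin pair, the classical estimator for which the
    identities MI(X, X) = H(X) and NMI(X, X) = 2 hold exactly — use it for
    reporting and evaluation.
    """
    n = fixed_values.size
    if n < 2:
        raise ValueError("need at least 2 samples inside the overlap region")
    nf, nm = bins + 1, bins + 3  # guard bins: 1 above fixed, 2 around moving
    counts = np.zeros(nf * nm)
    if kernel == "discrete":
        flo, fhi = range_fixed
        mlo, mhi = range_moving
        fi = np.clip(np.rint((fixed_values - flo) / (fhi - flo) * (bins - 1)),
                     0, bins - 1).astype(int)
        mi = np.clip(np.rint((moving_values - mlo) / (mhi - mlo) * (bins - 1)),
                     0, bins - 1).astype(int) + 1
        np.add.at(counts, fi * nm + mi, 1.0)
    elif kernel == "parzen":
        fb, fw = _linear_terms(fixed_values, range_fixed, bins)
        mb, mw, _ = _parzen_terms(moving_values, range_moving, bins)
        for lf in range(2):
            fi = fb + lf
            for lm in range(4):
                mi = mb - 1 + lm + 1  # kernel offset -1..2, +1 guard shift
                np.add.at(counts, fi * nm + mi, fw[:, lf] * mw[:, lm])
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    counts = counts.reshape(nf, nm) / n
    return JointHistogram(
        counts=counts,
        bins=bins,
        range_fixed=tuple(range_fixed),
        range_moving=tuple(range_moving),
        n_samples=n,
    )


def estimate_joint_histogram(
    fixed: Volume,
    moving: Volume,
    transform,
    samples: np.ndarray,
    bins: int = 32,
    range_fixed=None,
    range_moving=None,
    kernel: str = "parzen",
) -> JointHistogram:
    """Joint histogram over fixed-space sample points mapped through
    ``transform`` (None = identity).  Samples whose transformed position falls
    outside the moving image are discarded, so the differing fields of view of
    the two scans never bias the estimate."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    samples = np.atleast_2d(np.asarray(samples, float))
    mapped = transform.apply(samples) if transform is not None else samples
    fvals, _, fin = sample_with_gradient(fixed, samples)
    mvals, _, min_ = sample_with_gradient(moving, mapped)
    keep = fin & min_
    if keep.sum() < 2:
        raise ValueError("empty overlap region: all samples map outside the moving image")
    if range_fixed is None:
        range_fixed = robust_intensity_range(fixed)
    if range_moving is None:
        range_moving = robust_intensity_range(moving)
    return joint_histogram_from_values(
        fvals[keep], mvals[keep], bins, range_fixed, range_moving, kernel=kernel
    )


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(h: JointHistogram) -> float:
    """MI = H(IF) + H(IM) - H(IF, IM), in nats."""
    pf, pm = h.marginals()
    return _entropy(pf) + _entropy(pm) - _entropy(h.counts.ravel())


def normalized_mutual_information(h: JointHistogram) -> float:
    """NMI = (H(IF) + H(IM)) / H(IF, IM); range (1, 2] for nondegenerate data."""
    pf, pm = h.marginals()
    hj = _entropy(h.counts.ravel())
    if hj <= 0:
        raise ValueError("degenerate intensity distribution: zero joint entropy")
    return (_entropy(pf) + _entropy(pm)) / hj


# ---------------------------------------------------------------------------
# bending energy


def _ffd_of(transform) -> BSplineFFD | None:
    if isinstance(transform, BSplineFFD):
        return transform
    if isinstance(transform, CompositeTransform):
        return transform.ffd
    return None


def bending_energy(ffd: BSplineFFD, points: np.ndarray) -> float:
    """Mean squared second-derivative magnitude of the FFD over the points."""
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] == 0:
        raise ValueError("bending energy needs a non-empty point set")
    flat, w6 = ffd.second_derivative_weights(points)
    coef = ffd.coefficients.transpose(2, 1, 0, 3).reshape(-1, 3)
    h = np.einsum("nqk,nkd->ndq", w6, coef[flat])  # (N, 3, 6)
    return float(np.einsum("ndq,q->", h * h, _BEP_WEIGHTS) / points.shape[0])


def bending_energy_gradient(ffd: BSplineFFD, points: np.ndarray):
    """(P, dP/dmu) with the gradient flat in the FFD's parameter order."""
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    flat, w6 = ffd.second_derivative_weights(points)
    n_cp = int(np.prod(ffd.grid_shape))
    coef = ffd.coefficients.transpose(2, 1, 0, 3).reshape(-1, 3)
    h = np.einsum("nqk,nkd->ndq", w6, coef[flat])  # (N, 3, 6)
    value = float(np.einsum("ndq,q->", h * h, _BEP_WEIGHTS) / n)
    # dP/dPhi_{p,d} = (2/N) sum_i sum_q c_q h_{i,d,q} w6_{i,q,->p}
    hw = h * _BEP_WEIGHTS  # (N, 3, 6)
    contrib = np.einsum("ndq,nqk->nkd", hw, w6) * (2.0 / n)  # (N, 64, 3)
    grad = np.zeros((n_cp, 3))
    for d in range(3):
        grad[:, d] = np.bincount(
            flat.ravel(), weights=contrib[:, :, d].ravel(), minlength=n_cp
        )
    return value, grad.ravel()


# ---------------------------------------------------------------------------
# combined cost and analytic gradient


def bep_nmi_cost(
    fixed: Volume,
    moving: Volume,
    transform,
    samples: np.ndarray,
    bins: int = 32,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    range_fixed=None,
    range_moving=None,
    bep_points: np.ndarray | None = None,
    kernel: str = "parzen",
) -> CostTerms:
    """Evaluate C = gamma1 * (-NMI) + gamma2 * P for any transform.

    For a pure affine transform the penalty is defined as 0.  By default the
    penalty reuses the metric's sample points (one shared stochastic pass);
    pass ``bep_points`` for a dense full-grid evaluation.
    """
    h = estimate_joint_histogram(
        fixed, moving, transform, samples, bins, range_fixed, range_moving,
        kernel=kernel,
    )
    nmi = normalized_mutual_information(h)
    ffd = _ffd_of(transform)
    if ffd is not None and gamma2 != 0.0:
        pts = samples if bep_points is None else bep_points
        penalty = bending_energy(ffd, np.atleast_2d(pts))
    else:
        penalty = 0.0
    return CostTerms(
        similarity=-nmi,
        penalty=penalty,
        gamma1=gamma1,
        gamma2=gamma2,
        nmi=nmi,
        n_samples=h.n_samples,
    )


def _nmi_value_and_sample_gradient(
    fvals: np.ndarray, mvals: np.ndarray, bins: int, range_fixed, range_moving
):
    """NMI and its derivative with respect to each moving intensity sample."""
    n = fvals.size
    fb, fw = _linear_terms(fvals, range_fixed, bins)
    mb, mw, mdw = _parzen_terms(mvals, range_moving, bins)
    nf, nm = bins + 1, bins + 3
    counts = np.zeros(nf * nm)
    for lf in range(2):
        fi = fb + lf
        for lm in range(4):
            mi = mb + lm  # -1 kernel offset cancels +1 guard shift
            np.add.at(counts, fi * nm + mi, fw[:, lf] * mw[:, lm])
    p = counts.reshape(nf, nm) / n
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    hf, hm, hj = _entropy(pf), _entropy(pm), _entropy(p.ravel())
    if hj <= 0:
        raise ValueError("degenerate intensity distribution: zero joint entropy")
    nmi = (hf + hm) / hj

    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.maximum(p, 1e-300)), 0.0)
        logpf = np.where(pf > 0, np.log(np.maximum(pf, 1e-300)), 0.0)
        logpm = np.where(pm > 0, np.log(np.maximum(pm, 1e-300)), 0.0)
    # dNMI/dp_kl; additive constants cancel because sum_l dp/dm = 0
    G = (-(logpf[:, None] + logpm[None, :]) * hj + (hf + hm) * logp) / hj**2

    beta = np.zeros(n)
    for lf in range(2):
        fi = fb + lf
        for lm in range(4):
            mi = mb + lm
            beta += G[fi, mi] * fw[:, lf] * mdw[:, lm]
    beta /= n
    return nmi, beta, int(n)


def cost_and_gradient(
    fixed: Volume,
    moving: Volume,
    transform,
    samples: np.ndarray,
    bins: int = 32,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    range_fixed=None,
    range_moving=None,
):
    """Cost C and its analytic gradient dC/dmu over a stochastic sample set.

    The NMI term is differentiated through the Parzen kernels (chain rule:
    histogram -> moving intensity -> moving-image spatial gradient -> transform
    Jacobian); the bending-energy term is a quadratic form in the FFD
    coefficients and is differentiated exactly.  Returns
    ``(CostTerms, gradient)`` with the gradient laid out in the transform's
    parameter order.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    mapped = transform.apply(samples)
    fvals, _, fin = sample_with_gradient(fixed, samples)
    mvals, mgrad, min_ = sample_with_gradient(moving, mapped)
    keep = fin & min_
    if keep.sum() < 2:
        raise ValueError("empty overlap region: all samples map outside the moving image")
    if range_fixed is None:
        range_fixed = robust_intensity_range(fixed)
    if range_moving is None:
        range_moving = robust_intensity_range(moving)

    kept = samples[keep]
    nmi, beta, n_kept = _nmi_value_and_sample_gradient(
        fvals[keep], mvals[keep], bins, range_fixed, range_moving
    )
    # dC_sim/dmu = -gamma1 * sum_i beta_i * grad IM(T(x_i)) . dT/dmu
    vectors = (-gamma1) * beta[:, None] * mgrad[keep]
    grad = transform.accumulate_parameter_gradient(kept, vectors)

    ffd = _ffd_of(transform)
    penalty = 0.0
    if ffd is not None and gamma2 != 0.0:
        penalty, pgrad = bending_energy_gradient(ffd, kept)
        grad = grad + gamma2 * pgrad
    terms = CostTerms(
        similarity=-nmi,
        penalty=penalty,
        gamma1=gamma1,
        gamma2=gamma2,
        nmi=nmi,
        n_samples=n_kept,
    )
    return terms, grad
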