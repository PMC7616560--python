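"""Differentiable quadratic priors with optional MR guidance.

The smoothness penalty is the pairwise weighted Tikhonov form

    R(x) = 1/2 * sum_j sum_{b in N_j} w_jb (x_j - x_b)^2

with N_j the full 8-connected neighbourhood, so each unordered voxel pair
contributes twice. Weights may encode anatomical guidance: a Gaussian kernel
on MR intensity differences downweights smoothing across MR edges.

Gradient convention
-------------------
``tikhonov_gradient`` returns the one-sided stencil sum
``g_j = sum_{b in N_j} w_jb (x_j - x_b)``. For symmetric weights this is
exactly HALF the Euclidean gradient of ``tikhonov_value`` (each pair appears
twice in R). The one-sided form is the one the splitting algorithm's
regularization step and the De Pierro reduction are written in — the
substitution beta = 1/2, gamma_j = 1 / sum_b w_jb turns the gradient-descent
step into the De Pierro neighbourhood average exactly — so it is the
convention used throughout; callers needing the Euclidean gradient multiply
by 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "PriorModel",
    "neighbourhood_8",
    "distance_weights",
    "gaussian_mr_weights",
    "tikhonov_value",
    "tikhonov_gradient",
    "depierro_reg_image",
    "tikhonov_prior",
]


def neighbourhood_8() -> list[tuple[int, int]]:
    """Offsets of the 8-connected 2D stencil (both directions of each pair)."""
    return [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def _shift(x: np.ndarray, di: int, dj: int) -> np.ndarray:
    """x shifted so that out[i,j] = x[i+di, j+dj]; out-of-grid entries 0."""
    out = np.zeros_like(x)
    H, W = x.shape
    si = slice(max(di, 0), H + min(di, 0))
    sj = slice(max(dj, 0), W + min(dj, 0))
    ti = slice(max(-di, 0), H + min(-di, 0))
    tj = slice(max(-dj, 0), W + min(-dj, 0))
    out[ti, tj] = x[si, sj]
    return out


def _valid_mask(shape: tuple[int, int], di: int, dj: int) -> np.ndarray:
    """Boolean mask of voxels whose (di, dj) neighbour lies inside the grid."""
    m = np.zeros(shape, dtype=bool)
    H, W = shape
    ti = slice(max(-di, 0), H + min(-di, 0))
    tj = slice(max(-dj, 0), W + min(-dj, 0))
    m[ti, tj] = True
    return m


def distance_weights(shape: tuple[int, int], offsets=None) -> np.ndarray:
    """Inverse Euclidean inter-voxel distance per stencil arm, zero off-grid."""
    offsets = offsets or neighbourhood_8()
    w = np.zeros((len(offsets),) + tuple(shape))
    for k, (di, dj) in enumerate(offsets):
        w[k] = _valid_mask(shape, di, dj) / np.hypot(di, dj)
    return w


def gaussian_mr_weights(
    mr: np.ndarray,
    offsets=None,
    sigma_mr: float | str = "auto",
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """MR-guided Gaussian similarity weights, one plane per stencil arm.

    w[k, j] = exp(-(m_j - m_{j+off_k})^2 / (2 sigma^2)), symmetrised by
    averaging with the transposed arm (exact already for this kernel, but the
    averaging also zeroes both directions of off-grid pairs). ``sigma_mr``
    "auto" uses the standard deviation of neighbour MR differences over the
    brain mask (whole grid if none); a constant MR image falls back to
    uniform weights.
    """
    offsets = offsets or neighbourhood_8()
    mr = np.asarray(mr, dtype=np.float64)
    diffs = np.stack([mr - _shift(mr, di, dj) for di, dj in offsets])
    valid = np.stack([_valid_mask(mr.shape, di, dj) for di, dj in offsets])

    if sigma_mr == "auto":
        sel = valid if brain_mask is None else valid & brain_mask[None]
        sigma = float(np.std(diffs[sel])) if np.any(sel) else 0.0
        if sigma <= 0:  # constant MR: no edges to respect
            return valid.astype(np.float64)
    else:
        sigma = float(sigma_mr)
        if sigma <= 0:
            raise ValueError("sigma_mr must be positive")

    w = np.exp(-(diffs**2) / (2.0 * sigma**2)) * valid
    # enforce w_jb == w_bj: average each arm with its reversed-offset transpose
    sym = np.empty_like(w)
    rev = {off: k for k, off in enumerate(offsets)}
    for k, (di, dj) in enumerate(offsets):
        kr = rev[(-di, -dj)]
        sym[k] = 0.5 * (w[k] + _shift(w[kr], di, dj))
    return sym * valid


def tikhonov_value(x: np.ndarray, weights: np.ndarray, offsets=None) -> float:
    """R(x) = 1/2 sum_j sum_{b in N_j} w_jb (x_j - x_b)^2 (pairs counted twice)."""
    offsets = offsets or neighbourhood_8()
    total = 0.0
    for k, (di, dj) in enumerate(offsets):
        total += np.sum(weights[k] * (x - _shift(x, di, dj)) ** 2)
    return 0.5 * float(total)


def tikhonov_gradient(x: np.ndarray, weights: np.ndarray, offsets=None) -> np.ndarray:
    """One-sided stencil sum g_j = sum_b w_jb (x_j - x_b) (see module note)."""
    offsets = offsets or neighbourhood_8()
    g = np.zeros_like(x, dtype=np.float64)
    for k, (di, dj) in enumerate(offsets):
        g += weights[k] * (x - _shift(x, di, dj))
    return g


def depierro_reg_image(x: np.ndarray, weights: np.ndarray, offsets=None) -> np.ndarray:
    """De Pierro's regularized image: the weighted average of
    (x_j + x_b) / 2 over the neighbourhood.

    Equals the generic gradient step with beta = 1/2 and per-voxel
    gamma_j = 1 / sum_b w_jb. Voxels with zero total weight are returned
    unchanged.
    """
    offsets = offsets or neighbourhood_8()
    wsum = np.sum(weights, axis=0)
    acc = np.zeros_like(x, dtype=np.float64)
    for k, (di, dj) in enumerate(offsets):
        acc += weights[k] * (x + _shift(x, di, dj))
    out = np.where(wsum > 0, acc / np.maximum(2.0 * wsum, 1e-300), x)
    return out


@dataclass
class PriorModel:
    """A differentiable prior: value, (one-sided) gradient and weight data."""

    value: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    weights: np.ndarray | None = None
    offsets: list[tuple[int, int]] = field(default_factory=neighbourhood_8)
    beta: float = 1.0
    name: str = "prior"

    def weight_sum(self) -> np.ndarray:
        """Per-voxel sum_b w_jb (the De Pierro per-voxel 1/gamma_j)."""
        if self.weights is None:
            raise ValueError("prior has no neighbourhood weights")
        return np.sum(self.weights, axis=0)


def tikhonov_prior(
    shape: tuple[int, int],
    mr: np.ndarray | None = None,
    sigma_mr: float | str = "auto",
    beta: float = 1.0,
    include_distance: bool = True,
    brain_mask: np.ndarray | None = None,
) -> PriorModel:
    """Build the (optionally MR-weighted) Tikhonov prior on an 8-stencil.

    Weights are the MR Gaussian similarity (all-ones if ``mr`` is None)
    multiplied, by default, by inverse inter-voxel distance.
    """
    offsets = neighbourhood_8()
    if mr is not None:
        if mr.shape != tuple(shape):
            raise ValueError("MR shape does not match image shape")
        w = gaussian_mr_weights(mr, offsets, sigma_mr, brain_mask)
    else:
        w = np.stack([_valid_mask(tuple(shape), di, dj) for di, dj in offsets]).astype(float)
    if include_distance:
        w = w * distance_weights(shape, offsets)
    return PriorModel(
        value=lambda x: tikhonov_value(x, w, offsets),
        gradient=lambda x: tikhonov_gradient(x, w, offsets),
        weights=w,
        offsets=offsets,
        beta=beta,
        name="tikhonov-mr" if mr is not None else "tikhonov",
    )
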