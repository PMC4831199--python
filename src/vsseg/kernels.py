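"""Truncated discrete Gaussian kernels.

The local statistics and the fitting energies are both "volume scalable":
every local quantity is a kernel-weighted aggregate over a neighbourhood
whose effective size is set by the scale of a Gaussian kernel

    K_sigma(u) = (2 pi)^{-3/2} sigma^{-3} exp(-|u|^2 / (2 sigma^2)),

sampled on the integer voxel lattice, truncated to a finite cube and
renormalised to unit total weight.  The 3-D kernel factorises exactly into
the product of its 1-D profiles, which the convolution helpers exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = ["DiscreteKernel", "make_gaussian_kernel", "convolve", "kernel_taps"]


@dataclass(frozen=True)
class DiscreteKernel:
    """A truncated, renormalised, axis-separable Gaussian kernel.

    Attributes
    ----------
    sigma : float
        Scale in voxel units.
    radius : int
        Truncation radius per axis; the support is a (2*radius+1)^3 cube.
    weights : ndarray
        Full 3-D weight grid, non-negative, summing to 1.
    k1d : ndarray
        The 1-D profile whose triple outer product equals ``weights``.
    separable : bool
        Always True for Gaussian kernels; kept explicit because downstream
        code chooses between separable passes and full-window sums.
    """

    sigma: float
    radius: int
    weights: np.ndarray = field(repr=False)
    k1d: np.ndarray = field(repr=False)
    separable: bool = True

    def __post_init__(self):
        w = self.weights
        if np.any(w < 0):
            raise InvalidParameterError("kernel weights must be non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise InvalidParameterError("kernel weights must sum to 1")


def make_gaussian_kernel(sigma: float, radius_factor: float = 3.0) -> DiscreteKernel:
    """Sample a Gaussian on the voxel lattice, truncate and renormalise.

    Parameters
    ----------
    sigma : float
        Positive scale in voxel units.
    radius_factor : float, default 3.0
        The truncation radius is ``max(1, ceil(radius_factor * sigma))``;
        the default keeps >99.7% of the continuous mass per axis.
    """
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    if radius_factor < 1:
        raise InvalidParameterError("radius_factor must be >= 1")
    radius = max(1, int(np.ceil(radius_factor * sigma)))
    u = np.arange(-radius, radius + 1, dtype=np.float64)
    k1d = np.exp(-(u ** 2) / (2.0 * sigma ** 2))
    k1d /= k1d.sum()
    weights = k1d[:, None, None] * k1d[None, :, None] * k1d[None, None, :]
    # renormalise defensively against rounding
    weights = weights / weights.sum()
    return DiscreteKernel(sigma=float(sigma), radius=radius, weights=weights, k1d=k1d)


def convolve(arr: np.ndarray, kernel: DiscreteKernel) -> np.ndarray:
    """Correlate ``arr`` with the kernel under replicate (nearest) padding.

    Symmetric kernels make correlation and convolution identical.  The three
    1-D passes with edge padding are exactly equivalent to a full 3-D window
    sum over the edge-padded volume, including at corners.
    """
    out = np.asarray(arr, dtype=np.float64)
    for axis in range(3):
        out = ndimage.correlate1d(out, kernel.k1d, axis=axis, mode="nearest")
    return out


def kernel_taps(kernel: DiscreteKernel):
    """Flattened (offsets, weights) of the kernel support, for loop kernels.

    Returns
    -------
    offsets : (M, 3) int64 array of lattice offsets u.
    weights : (M,) float64 array, K(u), summing to 1.
    """
    r = kernel.radius
    ax = np.arange(-r, r + 1)
    oi, oj, ok = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.stack([oi.ravel(), oj.ravel(), ok.ravel()], axis=1).astype(np.int64)
    return offsets, kernel.weights.ravel().astype(np.float64)
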