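"""Volume-scalable robust-statistics features.

Each voxel x is described by a 3-vector computed over the Gaussian-weighted
neighbourhood B(x):

* ``VSMEAN`` -- the kernel-weighted local intensity mean,
  (K_sigma * I) / (K_sigma * 1);
* ``VSIQR`` -- the distance between the kernel-weighted first and third
  quartiles of the windowed intensities (robust local spread, immune to
  intensity outliers);
* ``WIV``   -- the square-rooted kernel-weighted variance of the window
  about the centre voxel's VSMEAN.

All three use replicate (nearest) boundary handling so the windowed weights
always carry unit mass; the (K*1) denominators are then exactly one but are
kept in the formulas for clarity.  Replicate padding together with the
explicit normalisation keeps the statistics unbiased at the volume border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import GeometryError, InvalidParameterError
from .io import VolumeImage
from .kernels import DiscreteKernel, convolve, make_gaussian_kernel

__all__ = ["FeatureVolume", "vsmean", "vsiqr", "wiv", "compute_feature_volume"]

#: feature channel indices
CH_MEAN, CH_IQR, CH_WIV = 0, 1, 2


@dataclass
class FeatureVolume:
    """Per-voxel feature 3-vectors (VSMEAN, VSIQR, WIV) on the image grid."""

    data: np.ndarray  # (nx, ny, nz, 3)
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    sigma: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise GeometryError("FeatureVolume requires an (nx,ny,nz,3) grid")

    @property
    def shape(self):
        return self.data.shape[:3]

    def channel(self, c: int) -> np.ndarray:
        return self.data[..., c]


def _as_array(image) -> np.ndarray:
    arr = image.data if isinstance(image, VolumeImage) else np.asarray(image)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3:
        raise GeometryError("expected a 3-D scalar volume")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("image must be finite-valued")
    return arr


def vsmean(image, kernel: DiscreteKernel) -> np.ndarray:
    """Kernel-weighted local mean (K*I)/(K*1) with replicate boundaries."""
    arr = _as_array(image)
    num = convolve(arr, kernel)
    den = convolve(np.ones_like(arr), kernel)
    return num / den


def _weighted_quantile(vs: np.ndarray, cum: np.ndarray, q: float) -> np.ndarray:
    """Quantile of rows of sorted values ``vs`` with cumulative weights ``cum``.

    The quantile is read off the weighted empirical CDF: the first order
    statistic whose cumulative weight reaches q, linearly interpolated from
    the previous order statistic.  The caller must supply a deterministic
    sort (ties broken by tap weight) so the result is order-independent.
    """
    k = np.argmax(cum >= q - 1e-12, axis=1)
    rows = np.arange(vs.shape[0])
    vk = vs[rows, k]
    ck = cum[rows, k]
    km1 = np.maximum(k - 1, 0)
    vkm1 = np.where(k > 0, vs[rows, km1], vs[rows, 0])
    ckm1 = np.where(k > 0, cum[rows, km1], 0.0)
    denom = ck - ckm1
    frac = np.where(denom > 1e-300, (q - ckm1) / np.maximum(denom, 1e-300),
                    0.0)
    return vkm1 + frac * (vk - vkm1)


def vsiqr(image, kernel: DiscreteKernel) -> np.ndarray:
    """Kernel-weighted inter-quartile range Q3 - Q1 of the local window."""
    arr = _as_array(image)
    r = kernel.radius
    w = 2 * r + 1
    pad = np.pad(arr, r, mode="edge")
    wflat = kernel.weights.ravel()
    # pre-order taps by ascending weight so the stable value sort breaks
    # ties deterministically (by weight), independent of flattening order
    worder = np.argsort(wflat, kind="stable")
    wflat = wflat[worder]
    nx, ny, nz = arr.shape
    out = np.empty(arr.shape, dtype=np.float64)
    # z-slab chunking bounds the transient window array to ~200 MB
    win_len = w ** 3
    per_slab = max(1, int(2.5e7) // max(1, ny * nz * win_len))
    for i0 in range(0, nx, per_slab):
        i1 = min(nx, i0 + per_slab)
        wins = sliding_window_view(pad[i0:i1 + 2 * r], (w, w, w))
        flat = wins.reshape(-1, win_len)[:, worder]
        idx = np.argsort(flat, axis=1, kind="stable")
        vs = np.take_along_axis(flat, idx, axis=1)
        ws = wflat[idx]
        cum = np.cumsum(ws, axis=1)
        q1 = _weighted_quantile(vs, cum, 0.25)
        q3 = _weighted_quantile(vs, cum, 0.75)
        out[i0:i1] = (q3 - q1).reshape(i1 - i0, ny, nz)
    return np.maximum(out, 0.0)


def wiv(image, kernel: DiscreteKernel, vsmean_grid: np.ndarray) -> np.ndarray:
    """Weighted intensity deviation sqrt( K*(I - VSMEAN(x))^2 / K*1 ).

    The deviation is taken about the *centre* voxel's VSMEAN, i.e. a true
    local variance about the local mean, which expands algebraically into
    three separable convolutions.
    """
    arr = _as_array(image)
    m = np.asarray(vsmean_grid, dtype=np.float64)
    if m.shape != arr.shape:
        raise GeometryError("vsmean_grid shape does not match image")
    den = convolve(np.ones_like(arr), kernel)
    ki = convolve(arr, kernel)
    ki2 = convolve(arr * arr, kernel)
    var = (ki2 - 2.0 * m * ki) / den + m * m
    return np.sqrt(np.clip(var, 0.0, None))


def compute_feature_volume(image, sigma: float,
                           radius_factor: float = 3.0) -> FeatureVolume:
    """Stack the (VSMEAN, VSIQR, WIV) channels computed with one kernel."""
    if not sigma > 0:
        raise InvalidParameterError("sigma must be positive")
    arr = _as_array(image)
    kernel = make_gaussian_kernel(sigma, radius_factor)
    m = vsmean(arr, kernel)
    q = vsiqr(arr, kernel)
    v = wiv(arr, kernel, m)
    spacing = (image.spacing if isinstance(image, VolumeImage)
               else np.ones(3))
    return FeatureVolume(data=np.stack([m, q, v], axis=-1),
                         spacing=np.asarray(spacing, dtype=np.float64),
                         sigma=float(sigma))
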