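"""Synthetic 3-D phantoms with analytic ground truth.

The generator reproduces the stress conditions under which seed-driven
active contours are usually evaluated on simulated brain MR data:

* piecewise-constant objects at a configurable intensity contrast
  (default 200 foreground on 0 background);
* partial-volume-like weak boundaries, emulated by Gaussian-blurring the
  binary edge;
* smooth multiplicative intensity non-uniformity (INU), realised as the
  exponential of a band-limited random field (a sum of three broad 3-D
  Gaussians) rescaled so its peak-to-peak variation over the foreground is
  a stated percentage of its mean there;
* i.i.d. zero-mean Gaussian noise of a stated standard deviation, clamped
  to non-negative intensities.

The ground-truth mask depends only on the geometry, never on the INU or
noise settings, so one geometry can be reused across a whole degradation
grid.  Seed strokes are straight axis-aligned runs placed uniformly at
random strictly inside the requested region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .errors import InvalidSpecError, StrokePlacementError
from .io import SeedLabelMap, VolumeImage

__all__ = ["PhantomSpec", "make_phantom", "make_seed_strokes"]

SHAPES = ("sphere", "two-blobs", "folded-sheet", "low-contrast-blob")


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic volume.

    ``inu`` is the peak-to-peak bias variation over the foreground as a
    fraction of its mean there (0.4 = 40%); ``noise_std`` is in intensity
    units; ``edge_width`` the Gaussian blur (voxels) applied to the binary
    object before bias and noise.
    """

    size: int = 48
    shape: str = "sphere"
    radius: float = 12.0
    center: tuple | None = None
    fg_intensity: float = 200.0
    bg_intensity: float = 0.0
    inu: float = 0.0
    noise_std: float = 0.0
    edge_width: float = 0.0
    rng_seed: int = 0
    spacing: tuple = (1.0, 1.0, 1.0)
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise InvalidSpecError(f"unknown shape {self.shape!r}")
        if self.inu < 0 or self.noise_std < 0 or self.edge_width < 0:
            raise InvalidSpecError("inu, noise_std, edge_width must be >= 0")
        if self.size < 8:
            raise InvalidSpecError("grid too small")


def _rasterize(spec: PhantomSpec) -> np.ndarray:
    n = spec.size
    ii, jj, kk = np.indices((n, n, n), dtype=np.float64)
    c = spec.center if spec.center is not None else ((n - 1) / 2.0,) * 3
    if spec.shape in ("sphere", "low-contrast-blob"):
        if spec.radius >= n / 2.0:
            raise InvalidSpecError("sphere radius exceeds the grid")
        r2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        return r2 <= spec.radius ** 2
    if spec.shape == "two-blobs":
        g = spec.geometry
        off = g.get("offset", spec.radius + 4.0)
        r1 = g.get("radius1", spec.radius)
        r2_ = g.get("radius2", 0.7 * spec.radius)
        c1 = (c[0] - off / 2, c[1], c[2])
        c2 = (c[0] + off / 2, c[1], c[2])
        if max(r1, r2_) + off / 2 >= n / 2.0:
            raise InvalidSpecError("blobs exceed the grid")
        m1 = (ii - c1[0]) ** 2 + (jj - c1[1]) ** 2 + (kk - c1[2]) ** 2 <= r1 ** 2
        m2 = (ii - c2[0]) ** 2 + (jj - c2[1]) ** 2 + (kk - c2[2]) ** 2 <= r2_ ** 2
        return m1 | m2
    if spec.shape == "folded-sheet":
        g = spec.geometry
        amp = g.get("amplitude", n / 6.0)
        period = g.get("period", n / 1.5)
        thick = g.get("thickness", max(2.0, n / 12.0))
        if amp + thick >= n / 2.0:
            raise InvalidSpecError("sheet exceeds the grid")
        mid = c[2] + amp * np.sin(2 * np.pi * ii / period) \
            * np.cos(2 * np.pi * jj / period)
        return np.abs(kk - mid) <= thick
    raise InvalidSpecError(spec.shape)


def _bias_field(mask: np.ndarray, inu: float,
                rng: np.random.Generator) -> np.ndarray:
    """exp of a sum of 3 broad random Gaussians, rescaled so that
    (max - min) / mean over the foreground equals ``inu``."""
    n = mask.shape[0]
    ii, jj, kk = np.indices(mask.shape, dtype=np.float64)
    g = np.zeros(mask.shape)
    for _ in range(3):
        ctr = rng.uniform(0.2 * n, 0.8 * n, size=3)
        width = rng.uniform(0.4 * n, 0.8 * n)
        sign = rng.choice([-1.0, 1.0])
        g += sign * np.exp(-(((ii - ctr[0]) ** 2 + (jj - ctr[1]) ** 2
                              + (kk - ctr[2]) ** 2) / (2 * width ** 2)))
    fgv = g[mask]
    span = float(fgv.max() - fgv.min())
    if span < 1e-12:  # degenerate flat draw: fall back to a linear ramp
        g = ii / n
        fgv = g[mask]
        span = float(fgv.max() - fgv.min())
    gn = (g - fgv.mean()) / span  # fg peak-to-peak 1, fg mean ~0

    def ptp_over_mean(a):
        b = np.exp(a * gn[mask])
        return float((b.max() - b.min()) / b.mean()) - inu

    hi = 4.0
    while ptp_over_mean(hi) < 0:
        hi *= 2.0
    a = brentq(ptp_over_mean, 0.0, hi, xtol=1e-10) if inu > 0 else 0.0
    return np.exp(a * gn)


def make_phantom(spec: PhantomSpec):
    """Generate (VolumeImage, ground-truth mask) from a spec.

    Deterministic for a fixed ``rng_seed``; the mask is the exact
    rasterised geometry, independent of degradation settings.
    """
    mask = _rasterize(spec)
    if not mask.any() or mask.all():
        raise InvalidSpecError("degenerate geometry: empty or full mask")
    rng = np.random.default_rng(spec.rng_seed)
    soft = mask.astype(np.float64)
    if spec.edge_width > 0:
        soft = ndimage.gaussian_filter(soft, spec.edge_width)
    img = spec.bg_intensity + (spec.fg_intensity - spec.bg_intensity) * soft
    if spec.inu > 0:
        img = img * _bias_field(mask, spec.inu, rng)
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    img = np.clip(img, 0.0, None)
    return VolumeImage(data=img, spacing=np.asarray(spec.spacing)), mask


def make_seed_strokes(mask: np.ndarray, n_strokes: int = 3,
                      stroke_length: int = 8, region: str = "fg",
                      rng_seed: int = 0,
                      existing: SeedLabelMap | None = None) -> SeedLabelMap:
    """Place straight axis-aligned strokes uniformly at random, fully
    inside the requested region (mask eroded by 1 so strokes never touch
    the boundary).  Strokes are mutually non-adjacent so they form exactly
    ``n_strokes`` connected components.  Deterministic per ``rng_seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    region_mask = mask if region == "fg" else ~mask
    if not region_mask.any():
        raise StrokePlacementError(f"region {region!r} is empty")
    eroded = ndimage.binary_erosion(region_mask)
    if not eroded.any():
        raise StrokePlacementError(
            f"region {region!r} too thin to host a stroke; "
            "shorten the stroke or grow the region")
    labels = (existing.labels.copy() if existing is not None
              else np.zeros(mask.shape, dtype=np.uint8))
    code = 1 if region == "fg" else 2
    rng = np.random.default_rng(rng_seed)
    candidates = np.argwhere(eroded)
    occupied_dilated = labels > 0
    placed = 0
    for _ in range(2000 * n_strokes):
        if placed == n_strokes:
            break
        start = candidates[rng.integers(len(candidates))]
        axis = int(rng.integers(3))
        direction = int(rng.choice([-1, 1]))
        pts = np.repeat(start[None, :], stroke_length, axis=0)
        pts[:, axis] += direction * np.arange(stroke_length)
        if pts[:, axis].min() < 0 or pts[:, axis].max() >= mask.shape[axis]:
            continue
        inside = eroded[pts[:, 0], pts[:, 1], pts[:, 2]]
        if not inside.all():
            continue
        if occupied_dilated[pts[:, 0], pts[:, 1], pts[:, 2]].any():
            continue
        labels[pts[:, 0], pts[:, 1], pts[:, 2]] = code
        stroke_mask = np.zeros(mask.shape, dtype=bool)
        stroke_mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        occupied_dilated |= ndimage.binary_dilation(
            stroke_mask, structure=np.ones((3, 3, 3), dtype=bool))
        placed += 1
    if placed < n_strokes:
        raise StrokePlacementError(
            f"could only place {placed}/{n_strokes} strokes of length "
            f"{stroke_length}; shorten the stroke")
    return SeedLabelMap(labels)
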