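"""Voxel characterisation by hybrid probability densities.

Each voxel is scored for the foreground (i=1) and background (i=2) class by
blending two Gaussian likelihood terms:

* a *seed term*: the mean density of (f(x) - f(z)) over the feature vectors
  f(z) sampled at the user's seed voxels of class i, with per-class
  per-channel variances derived from the seeds' WIV values;
* a *local term*: a kernel-weighted density of (mu_i(x) - f(y)) over the
  phase-i neighbourhood of x, where mu_i is the local phase feature mean and
  the variance tracks the WIV channel of mu_i(x).

A mixing weight omega in [0, 1] balances seed anchoring (omega -> 0)
against purely local adaptation (omega -> 1); at omega = 1 the seed bank
has no influence at all, which recovers a region-scalable fitting scheme
driven entirely by local statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fast import local_term_points, seed_term_grid
from .errors import GeometryError, InvalidParameterError, UnusableSeedsError
from .features import CH_WIV, FeatureVolume
from .io import SeedLabelMap
from .kernels import DiscreteKernel, convolve, kernel_taps

__all__ = ["SeedFeatureBank", "LocalFeatureMeans", "FittingField",
           "build_seed_bank", "gaussian_density", "local_feature_means",
           "fitting_functions", "seed_density_grid", "DEN_FLOOR"]

#: floor applied to phase-indicator denominators in the local means
DEN_FLOOR = 1e-8


@dataclass
class SeedFeatureBank:
    """Per-class seed feature vectors and density variances.

    ``feats[i]`` is an (N_i, 3) array of feature vectors sampled at class-i
    seed voxels; ``variances[i]`` the per-channel density variances used for
    the class-i seed term; ``floor`` the standard-deviation floor (1% of the
    feature dynamic range) that prevents degenerate densities.
    """

    feats: tuple  # (feats_fg, feats_bg)
    variances: tuple  # ((3,), (3,)) per-class channel variances
    floor: float
    cap: int
    rng_seed: int
    auto_background: bool = False

    def __post_init__(self):
        for f in self.feats:
            if f.shape[0] == 0:
                raise UnusableSeedsError("seed bank class is empty")

    def class_feats(self, i: int) -> np.ndarray:
        return self.feats[i - 1]

    def class_variances(self, i: int) -> np.ndarray:
        return self.variances[i - 1]


@dataclass
class LocalFeatureMeans:
    """Kernel-weighted phase feature means mu_1, mu_2 (each (nx,ny,nz,3))."""

    mu1: np.ndarray
    mu2: np.ndarray


@dataclass
class FittingField:
    """The fitting functions P_1, P_2 plus the blend/scale they used."""

    p1: np.ndarray
    p2: np.ndarray
    omega: float
    eta: float = 0.0

    def __post_init__(self):
        if not (np.all(np.isfinite(self.p1)) and np.all(np.isfinite(self.p2))):
            raise InvalidParameterError("fitting functions must be finite")
        if np.any(self.p1 < 0) or np.any(self.p2 < 0):
            raise InvalidParameterError("fitting functions must be >= 0")


def _border_shell(shape) -> np.ndarray:
    shell = np.zeros(shape, dtype=bool)
    shell[0, :, :] = shell[-1, :, :] = True
    shell[:, 0, :] = shell[:, -1, :] = True
    shell[:, :, 0] = shell[:, :, -1] = True
    return shell


def _subsample(coords: np.ndarray, cap: int, rng: np.random.Generator):
    if coords.shape[0] <= cap:
        return coords
    idx = rng.choice(coords.shape[0], size=cap, replace=False)
    return coords[np.sort(idx)]


def build_seed_bank(features: FeatureVolume, seeds, cap: int = 2000,
                    rng_seed: int = 0,
                    auto_background: bool = True) -> SeedFeatureBank:
    """Collect per-class seed feature vectors and derive density variances.

    If no background seeds are present and ``auto_background`` is on, the
    background bank is drawn from the 1-voxel border shell of the volume,
    assumed to lie outside any target.  Classes larger than ``cap`` are
    uniformly subsampled with a generator seeded by ``rng_seed`` so repeated
    calls are identical.
    """
    if isinstance(seeds, SeedLabelMap):
        fg, bg = seeds.foreground, seeds.background
    else:
        labels = np.asarray(seeds)
        fg, bg = labels == 1, labels == 2
    if fg.shape != features.shape:
        raise GeometryError("seed map shape does not match feature volume")
    if not fg.any():
        raise UnusableSeedsError("no foreground seed voxels")
    used_auto = False
    if not bg.any():
        if not auto_background:
            raise UnusableSeedsError(
                "no background seeds and auto_background disabled")
        bg = _border_shell(fg.shape) & ~fg
        used_auto = True

    rng = np.random.default_rng(rng_seed)
    banks = []
    for mask in (fg, bg):
        coords = np.argwhere(mask)
        coords = _subsample(coords, cap, rng)
        banks.append(np.ascontiguousarray(
            features.data[coords[:, 0], coords[:, 1], coords[:, 2], :]))

    ch0 = features.channel(0)
    floor = max(0.01 * float(ch0.max() - ch0.min()), 1e-6)
    variances = []
    for f in banks:
        v = np.empty(3)
        v[0] = max(float(f[:, CH_WIV].mean()), floor) ** 2
        for c in (1, 2):
            ddof = 1 if f.shape[0] > 1 else 0
            v[c] = max(float(np.var(f[:, c], ddof=ddof)), floor ** 2)
        variances.append(v)
    return SeedFeatureBank(feats=tuple(banks), variances=tuple(variances),
                           floor=floor, cap=int(cap), rng_seed=int(rng_seed),
                           auto_background=used_auto)


def gaussian_density(diff, variances) -> float:
    """Product of independent zero-mean 1-D Gaussian densities per channel."""
    d = np.asarray(diff, dtype=np.float64)
    v = np.asarray(variances, dtype=np.float64)
    if np.any(v <= 0):
        raise InvalidParameterError("variances must be positive (pre-floored)")
    norm = (2.0 * np.pi) ** (-d.size / 2.0) / np.sqrt(np.prod(v))
    return float(norm * np.exp(-0.5 * np.sum(d * d / v)))


def local_feature_means(features: FeatureVolume, heaviside_field: np.ndarray,
                        kernel_eta: DiscreteKernel) -> LocalFeatureMeans:
    """Kernel-weighted feature means of each phase.

    mu_1 = K*(f H) / K*H and mu_2 = K*(f (1-H)) / K*(1-H) per channel, with
    denominators floored at 1e-8 where a phase is locally absent.
    """
    h = np.asarray(heaviside_field, dtype=np.float64)
    if h.shape != features.shape:
        raise GeometryError("heaviside field shape does not match features")
    den1 = np.maximum(convolve(h, kernel_eta), DEN_FLOOR)
    den2 = np.maximum(convolve(1.0 - h, kernel_eta), DEN_FLOOR)
    mu1 = np.empty_like(features.data)
    mu2 = np.empty_like(features.data)
    for c in range(3):
        f = features.channel(c)
        mu1[..., c] = convolve(f * h, kernel_eta) / den1
        mu2[..., c] = convolve(f * (1.0 - h), kernel_eta) / den2
    return LocalFeatureMeans(mu1=mu1, mu2=mu2)


def seed_density_grid(features: FeatureVolume, bank: SeedFeatureBank,
                      class_index: int) -> np.ndarray:
    """Seed term of class i over the whole grid (independent of the contour).

    The density scale at x is max(WIV(x), floor): sharp in flat regions,
    tolerant at boundaries and in noise.
    """
    feats = bank.class_feats(class_index)
    out = np.empty(features.shape, dtype=np.float64)
    f = features.data
    seed_term_grid(np.ascontiguousarray(f[..., 0]),
                   np.ascontiguousarray(f[..., 1]),
                   np.ascontiguousarray(f[..., 2]),
                   np.ascontiguousarray(f[..., CH_WIV]),
                   float(bank.floor), feats, out)
    return out


def _local_density_grid(features: FeatureVolume, mu: np.ndarray,
                        phase: np.ndarray, kernel_eta: DiscreteKernel,
                        floor: float, coords: np.ndarray | None = None
                        ) -> np.ndarray:
    """Local term over ``coords`` (default: every voxel), returned as a grid
    (unset voxels zero when coords are restricted)."""
    shape = features.shape
    if coords is None:
        idx = np.indices(shape).reshape(3, -1).T
        coords = np.ascontiguousarray(idx.astype(np.int64))
    offs, kw = kernel_taps(kernel_eta)
    vals = np.empty(coords.shape[0], dtype=np.float64)
    f = features.data
    local_term_points(coords,
                      np.ascontiguousarray(f[..., 0]),
                      np.ascontiguousarray(f[..., 1]),
                      np.ascontiguousarray(f[..., 2]),
                      np.ascontiguousarray(phase),
                      np.ascontiguousarray(mu[..., 0]),
                      np.ascontiguousarray(mu[..., 1]),
                      np.ascontiguousarray(mu[..., 2]),
                      np.ascontiguousarray(f[..., CH_WIV]),
                      float(floor), offs, kw, vals)
    out = np.zeros(shape, dtype=np.float64)
    out[coords[:, 0], coords[:, 1], coords[:, 2]] = vals
    return out


def fitting_functions(features: FeatureVolume, bank: SeedFeatureBank,
                      means: LocalFeatureMeans, heaviside_field: np.ndarray,
                      kernel_eta: DiscreteKernel, omega: float) -> FittingField:
    """Blend the seed and local density terms into P_1 and P_2.

    P_i(x) = (1-omega) * mean_z p(f(x) - f(z))
             + omega * sum_y K_eta(x-y) p(mu_i(x) - f(y)) phase_i(y)

    with phase_1 = H and phase_2 = 1 - H.  The degenerate blends are exact:
    omega = 0 drops the contour-dependent term entirely, omega = 1 never
    touches the seed bank.
    """
    if not 0.0 <= omega <= 1.0:
        raise InvalidParameterError("omega must lie in [0, 1]")
    h = np.asarray(heaviside_field, dtype=np.float64)
    if h.shape != features.shape:
        raise GeometryError("heaviside field shape does not match features")
    p = []
    for i, (mu, phase) in enumerate(((means.mu1, h), (means.mu2, 1.0 - h)),
                                    start=1):
        total = np.zeros(features.shape, dtype=np.float64)
        if omega < 1.0:
            total += (1.0 - omega) * seed_density_grid(features, bank, i)
        if omega > 0.0:
            total += omega * _local_density_grid(features, mu, phase,
                                                 kernel_eta, bank.floor)
        p.append(total)
    return FittingField(p1=p[0], p2=p[1], omega=float(omega),
                        eta=kernel_eta.sigma)
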