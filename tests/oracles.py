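"""Independent brute-force reference implementations.

Everything here is written as plain Python loops over voxels and window
offsets with clamped (replicate) indexing, deliberately avoiding the
package's convolution/numba code paths, so the fast implementations can be
checked against them on tiny grids.
"""

from __future__ import annotations

import numpy as np

TWO_PI_32 = (2.0 * np.pi) ** 1.5


def _clamp(i, n):
    return 0 if i < 0 else (n - 1 if i >= n else i)


def window_iter(shape, center, radius):
    """Yield (offset, clamped neighbour index) pairs for a cubic window."""
    cx, cy, cz = center
    for ux in range(-radius, radius + 1):
        for uy in range(-radius, radius + 1):
            for uz in range(-radius, radius + 1):
                yield (ux, uy, uz), (_clamp(cx - ux, shape[0]),
                                     _clamp(cy - uy, shape[1]),
                                     _clamp(cz - uz, shape[2]))


def conv_oracle(arr, kernel):
    """Full-window replicate-boundary correlation with kernel.weights."""
    r = kernel.radius
    w = kernel.weights
    out = np.zeros_like(arr, dtype=float)
    for idx in np.ndindex(arr.shape):
        acc = 0.0
        for (ux, uy, uz), nb in window_iter(arr.shape, idx, r):
            acc += w[ux + r, uy + r, uz + r] * arr[nb]
        out[idx] = acc
    return out


def vsmean_oracle(arr, kernel):
    num = conv_oracle(arr, kernel)
    den = conv_oracle(np.ones_like(arr, dtype=float), kernel)
    return num / den


def weighted_quartiles_oracle(values, weights, q):
    """Weighted quantile: sort by (value, weight) — the weight tie-break
    makes the ordering deterministic — accumulate weights, and interpolate
    between adjacent order statistics at the crossing of the cumulative
    weight."""
    pairs = sorted(zip(values, weights), key=lambda t: (t[0], t[1]))
    v = np.array([p[0] for p in pairs], dtype=float)
    c = np.cumsum([p[1] for p in pairs])
    k = int(np.argmax(c >= q - 1e-12))
    vk, ck = v[k], c[k]
    vkm1 = v[k - 1] if k > 0 else v[0]
    ckm1 = c[k - 1] if k > 0 else 0.0
    if ck - ckm1 <= 0:
        return vk
    return vkm1 + (q - ckm1) / (ck - ckm1) * (vk - vkm1)


def vsiqr_oracle(arr, kernel):
    r = kernel.radius
    w = kernel.weights
    out = np.zeros_like(arr, dtype=float)
    for idx in np.ndindex(arr.shape):
        vals, wts = [], []
        for (ux, uy, uz), nb in window_iter(arr.shape, idx, r):
            vals.append(arr[nb])
            wts.append(w[ux + r, uy + r, uz + r])
        q1 = weighted_quartiles_oracle(vals, wts, 0.25)
        q3 = weighted_quartiles_oracle(vals, wts, 0.75)
        out[idx] = q3 - q1
    return out


def wiv_oracle(arr, kernel, vsmean_grid):
    r = kernel.radius
    w = kernel.weights
    out = np.zeros_like(arr, dtype=float)
    den = conv_oracle(np.ones_like(arr, dtype=float), kernel)
    for idx in np.ndindex(arr.shape):
        m = vsmean_grid[idx]
        acc = 0.0
        for (ux, uy, uz), nb in window_iter(arr.shape, idx, r):
            acc += w[ux + r, uy + r, uz + r] * (arr[nb] - m) ** 2
        out[idx] = np.sqrt(max(acc / den[idx], 0.0))
    return out


def local_means_oracle(fdata, h, kernel, floor=1e-8):
    """mu_1 and mu_2 per Eq.-style window sums with floored denominators."""
    r = kernel.radius
    w = kernel.weights
    shape = h.shape
    mu1 = np.zeros(shape + (3,))
    mu2 = np.zeros(shape + (3,))
    for idx in np.ndindex(shape):
        n1 = np.zeros(3)
        n2 = np.zeros(3)
        d1 = d2 = 0.0
        for (ux, uy, uz), nb in window_iter(shape, idx, r):
            kw = w[ux + r, uy + r, uz + r]
            n1 += kw * fdata[nb] * h[nb]
            n2 += kw * fdata[nb] * (1.0 - h[nb])
            d1 += kw * h[nb]
            d2 += kw * (1.0 - h[nb])
        mu1[idx] = n1 / max(d1, floor)
        mu2[idx] = n2 / max(d2, floor)
    return mu1, mu2


def gauss_iso(diff, s):
    """Isotropic 3-channel Gaussian density with std s per channel."""
    d = np.asarray(diff, dtype=float)
    return np.exp(-float(d @ d) / (2.0 * s * s)) / (TWO_PI_32 * s ** 3)


def seed_term_oracle(fdata, wiv, floor, seed_feats):
    shape = fdata.shape[:3]
    out = np.zeros(shape)
    for idx in np.ndindex(shape):
        s = max(wiv[idx], floor)
        acc = 0.0
        for z in seed_feats:
            acc += gauss_iso(fdata[idx] - z, s)
        out[idx] = acc / len(seed_feats)
    return out


def local_term_oracle(fdata, wiv, floor, mu, phase, kernel):
    r = kernel.radius
    w = kernel.weights
    shape = fdata.shape[:3]
    out = np.zeros(shape)
    for idx in np.ndindex(shape):
        s = max(wiv[idx], floor)
        acc = 0.0
        for (ux, uy, uz), nb in window_iter(shape, idx, r):
            acc += (w[ux + r, uy + r, uz + r] * phase[nb]
                    * gauss_iso(mu[idx] - fdata[nb], s))
        out[idx] = acc
    return out


def fitting_oracle(fdata, wiv, floor, seed1, seed2, mu1, mu2, h, kernel,
                   omega):
    p1 = np.zeros(h.shape)
    p2 = np.zeros(h.shape)
    if omega < 1.0:
        p1 += (1 - omega) * seed_term_oracle(fdata, wiv, floor, seed1)
        p2 += (1 - omega) * seed_term_oracle(fdata, wiv, floor, seed2)
    if omega > 0.0:
        p1 += omega * local_term_oracle(fdata, wiv, floor, mu1, h, kernel)
        p2 += omega * local_term_oracle(fdata, wiv, floor, mu2, 1.0 - h,
                                        kernel)
    return p1, p2


def rsf_fitting_oracle(arr, h, kernel, floor=1e-8):
    num1 = conv_oracle(h * arr, kernel)
    den1 = conv_oracle(h, kernel)
    num2 = conv_oracle((1.0 - h) * arr, kernel)
    den2 = conv_oracle(1.0 - h, kernel)
    return (num1 / np.maximum(den1, floor), num2 / np.maximum(den2, floor))


def energy_oracle(phi, p1, p2, kernel, lambda1, lambda2, mu, nu, eps):
    """Total functional: kernel-windowed fitting part plus voxel-sum
    regularisers, all with replicate boundaries and central differences."""
    h = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))
    fit = -(lambda1 * conv_oracle(p1 * h, kernel).sum()
            + lambda2 * conv_oracle(p2 * (1.0 - h), kernel).sum())
    gh = np.gradient(h)
    gp = np.gradient(phi)
    length = np.sqrt(gh[0] ** 2 + gh[1] ** 2 + gh[2] ** 2).sum()
    reg = 0.5 * ((np.sqrt(gp[0] ** 2 + gp[1] ** 2 + gp[2] ** 2) - 1.0)
                 ** 2).sum()
    return float(fit + nu * length + mu * reg)
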