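"""Numba inner loops for the seed and local fitting terms and the
semi-implicit level-set sweep.

These are plain lattice loops with replicate (clamped-index) boundary
handling, kept free of Python objects so they compile to tight machine
code; everything here is deterministic for fixed inputs.

The Gaussian densities use an isotropic per-voxel standard deviation
s(x) = max(WIV(x), floor): the local intensity variability of the very
window being characterised, so flat regions get sharp, selective
densities while boundary and noisy regions get tolerant ones.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI_POW_3_2 = (2.0 * np.pi) ** 1.5


@njit(cache=False, fastmath=True)
def seed_term_grid(f0, f1, f2, wiv, floor, seed_feats, out):
    """Mean Gaussian density of (f(x) - f(z)) over the seed feature bank.

    Parameters
    ----------
    f0, f1, f2 : 3-D feature channel grids
    wiv : 3-D grid, the WIV feature channel (density scale source)
    floor : standard-deviation floor
    seed_feats : (M, 3) seed feature vectors f(z)
    out : 3-D output grid, overwritten
    """
    nx, ny, nz = f0.shape
    m = seed_feats.shape[0]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                s = wiv[i, j, k]
                if s < floor:
                    s = floor
                inv2v = 1.0 / (2.0 * s * s)
                c = 1.0 / (TWO_PI_POW_3_2 * s * s * s)
                x0 = f0[i, j, k]
                x1 = f1[i, j, k]
                x2 = f2[i, j, k]
                acc = 0.0
                for t in range(m):
                    d0 = x0 - seed_feats[t, 0]
                    d1 = x1 - seed_feats[t, 1]
                    d2 = x2 - seed_feats[t, 2]
                    acc += np.exp(-(d0 * d0 + d1 * d1 + d2 * d2) * inv2v)
                out[i, j, k] = c * acc / m


@njit(cache=False, fastmath=True)
def local_term_points(coords, f0, f1, f2, phase, mu0, mu1, mu2, wiv,
                      floor, offs, kw, out):
    """Windowed density term  sum_u K(u) p(mu_i(x) - f(x-u)) phase(x-u).

    Parameters
    ----------
    coords : (N, 3) voxel indices x at which to evaluate
    phase : H(phi) for the inside term or 1 - H(phi) for the outside term
    mu0, mu1, mu2 : channels of the local phase feature mean mu_i
    wiv : the WIV feature channel (density scale source at x)
    offs, kw : kernel taps (offsets and weights)
    out : (N,) output vector, overwritten
    """
    nx, ny, nz = f0.shape
    n = coords.shape[0]
    m = offs.shape[0]
    for t in range(n):
        i = coords[t, 0]
        j = coords[t, 1]
        k = coords[t, 2]
        s = wiv[i, j, k]
        if s < floor:
            s = floor
        inv2v = 1.0 / (2.0 * s * s)
        c = 1.0 / (TWO_PI_POW_3_2 * s * s * s)
        m0 = mu0[i, j, k]
        m1 = mu1[i, j, k]
        m2 = mu2[i, j, k]
        acc = 0.0
        for q in range(m):
            yi = i - offs[q, 0]
            if yi < 0:
                yi = 0
            elif yi >= nx:
                yi = nx - 1
            yj = j - offs[q, 1]
            if yj < 0:
                yj = 0
            elif yj >= ny:
                yj = ny - 1
            yk = k - offs[q, 2]
            if yk < 0:
                yk = 0
            elif yk >= nz:
                yk = nz - 1
            h = phase[yi, yj, yk]
            if h <= 0.0:
                continue
            d0 = m0 - f0[yi, yj, yk]
            d1 = m1 - f1[yi, yj, yk]
            d2 = m2 - f2[yi, yj, yk]
            acc += kw[q] * h * np.exp(-(d0 * d0 + d1 * d1 + d2 * d2) * inv2v)
        out[t] = c * acc


@njit(cache=False)
def gauss_seidel_step(phi, explicit, band, dt, mu):
    """One forward-time step with an in-place lexicographic Laplacian sweep.

    phi[x] += dt * (explicit[x] + mu * lap(phi)[x]) where the Laplacian uses
    already-updated neighbours (semi-implicit Gauss-Seidel) and replicate
    boundary handling.  Only voxels with band != 0 are updated.
    """
    nx, ny, nz = phi.shape
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            for k in range(nz):
                if band[i, j, k] == 0:
                    continue
                km = k - 1 if k > 0 else 0
                kp = k + 1 if k < nz - 1 else nz - 1
                c = phi[i, j, k]
                lap = (phi[im, j, k] + phi[ip, j, k] + phi[i, jm, k]
                       + phi[i, jp, k] + phi[i, j, km] + phi[i, j, kp]
                       - 6.0 * c)
                phi[i, j, k] = c + dt * (explicit[i, j, k] + mu * lap)
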