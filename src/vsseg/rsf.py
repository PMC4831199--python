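"""Region-scalable fitting (RSF) baseline.

RSF drives the contour with local *intensity* means instead of robust
feature densities: two spatially varying functions f_1, f_2 approximate the
image on either side of the contour within a Gaussian window, and the
forces are kernel-weighted squared residuals

    e_i(x) = int K_sigma(y - x) |I(x) - f_i(y)|^2 dy,

which expand into three separable convolutions.  The flow

    dphi/dt = -delta(phi)(lambda1 e1 - lambda2 e2)
              + nu delta(phi) div(grad phi/|grad phi|)
              + mu (lap phi - div(grad phi/|grad phi|))

shares the mollifier, discretisation, band handling and stopping rule of
the volume-scalable engine so the two models differ only in their data
term.  It is both the comparison baseline and the structural omega -> 1
limit of the volume-scalable model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fast import gauss_seidel_step
from .errors import InvalidParameterError, NumericalFailureError
from .io import VolumeImage
from .kernels import DiscreteKernel, convolve, make_gaussian_kernel
from .levelset import curvature, dirac_delta
from .evolution import (LevelSetState, _band_needs_rebuild, _converged,
                        _rebuild_band)

__all__ = ["RsfParams", "rsf_fitting", "rsf_data_force", "rsf_segment"]

DEN_FLOOR = 1e-8


@dataclass
class RsfParams:
    """RSF parameters; mirrors EvolutionParams where the models overlap."""

    sigma: float = 3.0          # fitting kernel scale, voxels
    lambda1: float = 1.0
    lambda2: float = 2.0
    mu: float = 1.0
    nu: float = 0.0
    dt: float = 0.1
    eps: float = 1.0
    max_iters: int = 300
    tol: float = 1e-4
    convergence_window: int = 10
    narrow_band: bool = True
    band_width: float = 6.0
    band_margin: float = 2.0
    radius_factor: float = 2.0
    force_normalize: bool = True
    force_softness: float = 0.5  # linear zone, fraction of front scale
    force_gain: float = 10.0

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise InvalidParameterError("lambda1, lambda2 must be positive")
        if self.dt <= 0 or self.eps <= 0 or self.sigma <= 0:
            raise InvalidParameterError("dt, eps, sigma must be positive")
        if self.mu < 0 or self.nu < 0:
            raise InvalidParameterError("mu and nu must be non-negative")


def rsf_fitting(image, heaviside_field: np.ndarray,
                kernel: DiscreteKernel):
    """Local phase intensity means f_1 = K*(H I)/K*H, f_2 analogous."""
    arr = image.data if isinstance(image, VolumeImage) else np.asarray(
        image, dtype=np.float64)
    h = np.asarray(heaviside_field, dtype=np.float64)
    if h.shape != arr.shape:
        raise InvalidParameterError("heaviside field shape mismatch")
    f1 = convolve(h * arr, kernel) / np.maximum(convolve(h, kernel),
                                                DEN_FLOOR)
    f2 = convolve((1.0 - h) * arr, kernel) / np.maximum(
        convolve(1.0 - h, kernel), DEN_FLOOR)
    return f1, f2


def rsf_data_force(image, f1: np.ndarray, f2: np.ndarray,
                   kernel: DiscreteKernel, lambda1: float, lambda2: float
                   ) -> np.ndarray:
    """lambda1 e1 - lambda2 e2 with the squared-residual e_i expanded as
    I^2 (K*1) - 2 I (K*f_i) + K*(f_i^2)."""
    arr = image.data if isinstance(image, VolumeImage) else np.asarray(
        image, dtype=np.float64)
    kone = convolve(np.ones_like(arr), kernel)
    e1 = arr * arr * kone - 2.0 * arr * convolve(f1, kernel) \
        + convolve(f1 * f1, kernel)
    e2 = arr * arr * kone - 2.0 * arr * convolve(f2, kernel) \
        + convolve(f2 * f2, kernel)
    return lambda1 * e1 - lambda2 * e2


def rsf_segment(image, init_phi: np.ndarray,
                params: RsfParams | None = None):
    """Evolve the RSF flow from ``init_phi`` until the sign-change fraction
    over the convergence window drops below tolerance.

    Returns (mask, diagnostics)."""
    if params is None:
        params = RsfParams()
    phi = np.asarray(init_phi, dtype=np.float64).copy()
    if not np.all(np.isfinite(phi)):
        raise InvalidParameterError("init_phi must be finite")
    kernel = make_gaussian_kernel(params.sigma, params.radius_factor)
    state = LevelSetState(phi=phi)
    while state.iteration < params.max_iters:
        if params.narrow_band:
            if state.band is None or _band_needs_rebuild(state, params):
                _rebuild_band(state, params,
                              redistance=state.band is not None)
            band = state.band
        else:
            band = np.ones(phi.shape, dtype=bool)
            state.band = band
        h = state.heaviside(params.eps)
        f1, f2 = rsf_fitting(image, h, kernel)
        force = -rsf_data_force(image, f1, f2, kernel,
                                params.lambda1, params.lambda2)
        delta = dirac_delta(state.phi, params.eps)
        if params.force_normalize:
            # saturate at a fraction of the near-front magnitude so the
            # resting position is not biased by force asymmetry
            scale = float((delta * np.abs(force)).sum() / delta.sum())
            if scale > 0:
                force = np.clip(force / (params.force_softness * scale),
                                -1.0, 1.0) * params.force_gain
        kappa = curvature(state.phi)
        explicit = delta * force + params.nu * delta * kappa \
            - params.mu * kappa
        prev_sign = state.phi > 0
        gauss_seidel_step(state.phi, explicit, band.astype(np.uint8),
                          params.dt, params.mu)
        if not np.all(np.isfinite(state.phi)):
            raise NumericalFailureError(
                f"non-finite phi at iteration {state.iteration}",
                iteration=state.iteration)
        state.iteration += 1
        state.changed_fraction.append(
            float(np.mean((state.phi > 0) != prev_sign)))
        state.sign_history.append(state.phi > 0)
        if len(state.sign_history) > params.convergence_window + 1:
            state.sign_history.pop(0)
        if _converged(state, params):
            break
    diagnostics = {
        "n_iter": state.iteration,
        "changed_fraction": list(state.changed_fraction),
        "converged": _converged(state, params),
        "state": state,
    }
    return state.mask, diagnostics
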