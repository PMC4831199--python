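"""Level-set primitives: mollifiers, curvature, signed-distance init.

The contour is the zero level of a scalar field phi, positive inside the
object.  Region integrals become differentiable through the arctan-type
smoothed Heaviside H_eps and its derivative, the Lorentzian-shaped
delta_eps; the heavy 1/z^2 tails of delta_eps let the data force act at a
distance, which is what allows a small seed stroke to capture a whole
object.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, UnusableSeedsError
from .io import SeedLabelMap

__all__ = ["smoothed_heaviside", "dirac_delta", "curvature", "initialize_phi",
           "signed_distance", "gradient_magnitude"]

GRAD_FLOOR = 1e-8


def smoothed_heaviside(phi: np.ndarray, eps: float) -> np.ndarray:
    """H_eps(z) = 1/2 (1 + (2/pi) arctan(z/eps)); strictly increasing,
    H_eps(0) = 1/2, limits 0 and 1."""
    if not eps > 0:
        raise InvalidParameterError("eps must be positive")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(phi) / eps))


def dirac_delta(phi: np.ndarray, eps: float) -> np.ndarray:
    """delta_eps(z) = (1/pi) eps / (eps^2 + z^2), the derivative of H_eps."""
    if not eps > 0:
        raise InvalidParameterError("eps must be positive")
    phi = np.asarray(phi)
    return (eps / np.pi) / (eps * eps + phi * phi)


def gradient_magnitude(phi: np.ndarray) -> np.ndarray:
    gx, gy, gz = np.gradient(phi)
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|) by central differences, |grad| floored."""
    gx, gy, gz = np.gradient(phi)
    norm = np.sqrt(gx * gx + gy * gy + gz * gz)
    norm = np.maximum(norm, GRAD_FLOOR)
    nx_, ny_, nz_ = gx / norm, gy / norm, gz / norm
    return (np.gradient(nx_, axis=0) + np.gradient(ny_, axis=1)
            + np.gradient(nz_, axis=2))


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, positive inside."""
    mask = np.asarray(mask, dtype=bool)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def initialize_phi(seeds, spacing=None, dilate: int = 0) -> np.ndarray:
    """Signed distance to the foreground-seed boundary, in voxel units.

    ``dilate`` grows the seed mask by that many voxels first; the evolution
    uses one voxel so a thin stroke starts with a finite interior that the
    distance-regularisation term cannot immediately smooth away.
    """
    if isinstance(seeds, SeedLabelMap):
        fg = seeds.foreground
    else:
        fg = np.asarray(seeds) == 1
    if not fg.any():
        raise UnusableSeedsError("no foreground seed voxels to initialize phi")
    if dilate > 0:
        fg = ndimage.binary_dilation(fg, iterations=dilate)
    return signed_distance(fg)
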