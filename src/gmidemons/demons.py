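"""Classic demons force and regularised iterative update.

The demons scheme treats registration as a diffusion process: intensity
differences between the reference and the (currently warped) floating image
exert per-voxel forces along the reference gradient, and a Gaussian filter
regularises the accumulated displacement field after each additive update.

Sign convention: with the pull-warp convention used throughout this package
(the warped floating image samples ``F(P + v)``), the force

    force(P) = (r - f) * grad_r / (||grad_r||^2 + (r - f)^2 / k^2)

is the Gauss–Newton descent step on the squared intensity difference; ``f``
denotes the warped-floating intensity at ``P``.  Statements of the demons
force with the opposite sign assume the forward-warp convention.  Where the
denominator vanishes (f = r and grad_r = 0) the force is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import (
    DisplacementField,
    RegistrationConfig,
    ScalarImage,
    image_gradient,
    warp_image,
)

logger = logging.getLogger("gmidemons")

__all__ = ["DemonsStepDiagnostics", "demons_force", "demons_iteration"]


@dataclass
class DemonsStepDiagnostics:
    """Per-iteration convergence indicators."""

    max_update_magnitude: float  # voxels
    mean_squared_intensity_diff: float

    def __post_init__(self):
        if self.max_update_magnitude < 0 or self.mean_squared_intensity_diff < 0:
            raise ValueError("diagnostics must be nonnegative")


def demons_force(
    r_img: ScalarImage,
    warped_f: ScalarImage,
    grad_r: np.ndarray,
    k: float,
) -> np.ndarray:
    """Per-voxel demons force (voxel units), shape ``grid + (ndim,)``.

    ``warped_f`` is the floating image already resampled onto the reference
    grid through the current field; ``grad_r`` the reference gradient.
    The force magnitude is bounded by ``k/2`` at every voxel.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if warped_f.shape != r_img.shape or grad_r.shape[:-1] != r_img.shape:
        raise ValueError("reference, warped floating and gradient shapes must match")
    diff = r_img.data - warped_f.data
    grad_sq = np.sum(grad_r**2, axis=-1)
    denom = grad_sq + diff**2 / k**2
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return grad_r * scale[..., None]


def _smooth_field(vectors: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return vectors
    out = np.empty_like(vectors)
    for a in range(vectors.shape[-1]):
        out[..., a] = ndimage.gaussian_filter(vectors[..., a], sigma, mode="nearest")
    return out


def _cap_step(step: np.ndarray, max_step: float) -> np.ndarray:
    mag = np.sqrt(np.sum(step**2, axis=-1))
    factor = np.where(mag > max_step, max_step / np.where(mag > 0, mag, 1.0), 1.0)
    return step * factor[..., None]


def demons_iteration(
    field_n: DisplacementField,
    r_img: ScalarImage,
    f_img: ScalarImage,
    cfg: RegistrationConfig,
) -> DisplacementField:
    """One regularised demons update: ``G_sigma * (v_n + force)``.

    The floating image is sampled through the current field before the force
    is evaluated; the Gaussian filter is applied component-wise to the summed
    field (diffusion-like regularisation).  ``sigma = 0`` disables smoothing.
    """
    if field_n.grid_shape != r_img.shape:
        raise ValueError("field grid must match the reference grid")
    warped = warp_image(f_img, field_n, pad=cfg.pad, pad_value=cfg.pad_value)
    grad_r = image_gradient(r_img)
    force = demons_force(r_img, warped, grad_r, cfg.k)
    force = _cap_step(force, cfg.max_step)
    diag = DemonsStepDiagnostics(
        max_update_magnitude=float(np.sqrt(np.sum(force**2, axis=-1)).max()),
        mean_squared_intensity_diff=float(np.mean((warped.data - r_img.data) ** 2)),
    )
    logger.debug(
        "demons step: max|u|=%.4f vox, MSD=%.6f",
        diag.max_update_magnitude,
        diag.mean_squared_intensity_diff,
    )
    new = _smooth_field(field_n.vectors + force, cfg.sigma)
    return DisplacementField(new, level=field_n.level)
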