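"""GMI-demons update and the multiresolution coarse-to-fine driver.

The deformable update augments the classic demons force with the gradient of
mutual information,

    v_{n+1} = G_sigma * ( v_n + demons_force(v_n) + alpha * grad MI(v_n) ),

which keeps the optical-flow speed of demons while remaining meaningful when
the two images' intensity mappings differ (the multimodal case, where the
intensity-difference force is misdirected).

Registration runs coarse-to-fine on Gaussian image pyramids: per level the
update iterates until the MI increment between successive iterations falls
below a threshold (or an iteration cap), then the field is upsampled and
rescaled to seed the next finer level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .demons import _cap_step, _smooth_field, demons_force, demons_iteration
from .image_model import (
    DisplacementField,
    RegistrationConfig,
    RegistrationResult,
    ScalarImage,
    image_gradient,
    warped_image_and_gradient,
)
from .mi import _force_from_warped, estimate_joint_density, mutual_information
from .rigid import RigidTransform, apply_rigid, rigid_register

logger = logging.getLogger("gmidemons")

# moving-average window (iterations) for the MI-increment stopping rule
_STOP_WINDOW = 8

__all__ = [
    "ImagePyramid",
    "gmi_demons_iteration",
    "build_pyramid",
    "upsample_field",
    "register",
    "total_displacement",
]


@dataclass
class ImagePyramid:
    """Downsampled image stack, ordered coarsest to finest."""

    levels: list
    factor: int

    def __post_init__(self):
        if len(self.levels) < 1:
            raise ValueError("pyramid needs at least one level")
        for coarse, fine in zip(self.levels, self.levels[1:]):
            if any(c > f for c, f in zip(coarse.shape, fine.shape)):
                raise ValueError("levels must be ordered coarsest to finest")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _gmi_step(
    field_n: DisplacementField,
    r_img: ScalarImage,
    f_img: ScalarImage,
    grad_r: np.ndarray,
    cfg: RegistrationConfig,
):
    """One GMI-demons update; returns ``(new_field, mi_of_current_field)``.

    With ``alpha = 0`` the MI force is skipped and the update is the classic
    demons iteration body; MI is still evaluated for the stopping rule.
    """
    warped, grad_f = warped_image_and_gradient(
        f_img, field_n, pad=cfg.pad, pad_value=cfg.pad_value
    )
    force = demons_force(r_img, warped, grad_r, cfg.k)
    if cfg.alpha > 0:
        mi_vec, mi = _force_from_warped(
            r_img, warped, grad_f, cfg.parzen_delta, cfg.lattice_size
        )
        # alpha scales the per-sample MI gradient (N * grad MI): the raw
        # gradient carries a 1/N factor, so a fixed step on it would shrink
        # with resolution and unbalance the pyramid levels
        force = force + cfg.alpha * r_img.data.size * mi_vec
    else:
        jd = estimate_joint_density(
            r_img, warped, delta=cfg.parzen_delta, lattice_size=cfg.lattice_size
        )
        mi = mutual_information(jd)
    force = _cap_step(force, cfg.max_step)
    new = _smooth_field(field_n.vectors + force, cfg.sigma)
    return DisplacementField(new, level=field_n.level), mi


def gmi_demons_iteration(
    field_n: DisplacementField,
    r_img: ScalarImage,
    f_img: ScalarImage,
    cfg: RegistrationConfig,
) -> DisplacementField:
    """One regularised GMI-demons update of the displacement field.

    ``G_sigma * (v_n + demons force + alpha * grad MI)``; with ``alpha = 0``
    this is bit-identical to :func:`gmidemons.demons.demons_iteration`.
    """
    if field_n.grid_shape != r_img.shape:
        raise ValueError("field grid must match the reference grid")
    if cfg.alpha == 0:
        return demons_iteration(field_n, r_img, f_img, cfg)
    grad_r = image_gradient(r_img)
    new_field, _ = _gmi_step(field_n, r_img, f_img, grad_r, cfg)
    return new_field


def build_pyramid(img: ScalarImage, n_levels: int, factor: int = 2) -> ImagePyramid:
    """Gaussian image pyramid by successive anti-aliased subsampling.

    Each coarser level smooths the previous one with sigma = 0.5 * factor and
    keeps every ``factor``-th voxel; spacing metadata scales accordingly.
    ``n_levels`` is reduced (with a warning) if the coarsest level would drop
    below 8 voxels on any axis.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = [img]
    current = img
    for _ in range(n_levels - 1):
        next_shape = tuple(-(-n // factor) for n in current.shape)
        if min(next_shape) < 8:
            logger.warning(
                "pyramid truncated at %d levels (coarsest level would fall "
                "below 8 voxels per axis)",
                len(levels),
            )
            break
        smoothed = ndimage.gaussian_filter(current.data, 0.5 * factor, mode="nearest")
        sub = smoothed[tuple(slice(None, None, factor) for _ in current.shape)]
        spacing = tuple(s * factor for s in current.spacing)
        current = ScalarImage(sub, spacing, current.origin)
        levels.append(current)
    return ImagePyramid(levels=levels[::-1], factor=factor)


def upsample_field(
    field: DisplacementField, target_shape, factor: int = 2
) -> DisplacementField:
    """Linearly interpolate a field to a finer grid and rescale to its units.

    Components are multiplied by ``factor`` because offsets are stored in
    voxel units of the level they belong to.
    """
    target_shape = tuple(target_shape)
    src_shape = field.grid_shape
    if len(target_shape) != len(src_shape):
        raise ValueError("target shape rank mismatch")
    for t, s in zip(target_shape, src_shape):
        if not s <= t <= s * factor + factor:
            raise ValueError(
                f"target shape {target_shape} incompatible with source "
                f"{src_shape} at factor {factor}"
            )
    coords = np.indices(target_shape, dtype=np.float64)
    for a, (t, s) in enumerate(zip(target_shape, src_shape)):
        scale = (s - 1) / (t - 1) if t > 1 else 0.0
        coords[a] *= scale
    out = np.empty(target_shape + (field.ndim,))
    for a in range(field.ndim):
        out[..., a] = ndimage.map_coordinates(
            field.vectors[..., a], coords, order=1, mode="nearest"
        )
    return DisplacementField(out * factor, level=max(field.level - 1, 0))


def _run_level(
    r_img: ScalarImage,
    f_img: ScalarImage,
    field: DisplacementField,
    cfg: RegistrationConfig,
):
    """Iterate the GMI-demons update at one pyramid level.

    Stops when the MI increment falls below ``cfg.mi_stop_threshold`` or the
    iteration cap is reached; if the last step decreased MI the previous
    field is kept.  Returns ``(field, mi_trace, iterations, converged)``.
    """
    grad_r = image_gradient(r_img)
    trace = []
    iterations = 0
    converged = False
    start_field = field
    # individual demons steps overshoot, so the raw per-iteration MI
    # increment oscillates in sign well before convergence; the stopping
    # increment is therefore measured per iteration on a moving average
    w = _STOP_WINDOW
    for _ in range(cfg.max_iters_per_level):
        new_field, mi = _gmi_step(field, r_img, f_img, grad_r, cfg)
        trace.append(mi)
        if len(trace) >= 2 * w:
            inc = (np.mean(trace[-w:]) - np.mean(trace[-2 * w : -w])) / w
            if inc < cfg.mi_stop_threshold:
                converged = True
                break
        field = new_field
        iterations += 1
    if trace[-1] < trace[0]:
        # a level must never leave the configuration worse than it found it
        field = start_field
    logger.info(
        "level %d: %d iterations, MI %.5f -> %.5f%s",
        field.level,
        iterations,
        trace[0],
        max(trace),
        "" if converged else " (iteration cap reached)",
    )
    return field, trace, iterations, converged


def register(
    reference: ScalarImage,
    floating: ScalarImage,
    cfg: RegistrationConfig = None,
) -> RegistrationResult:
    """Full pipeline: rigid pre-alignment + multiresolution GMI demons.

    Both images are min-max normalised to [0, 1] internally.  The rigid
    transform is applied once, by resampling the floating image, before the
    deformable stage; the returned field therefore describes only the
    deformable part (compose with ``global_transform`` via
    :func:`total_displacement` for the end-to-end mapping).
    """
    if cfg is None:
        cfg = RegistrationConfig()
    cfg.validate()
    if reference.shape != floating.shape:
        raise ValueError(
            "register expects reference and floating on a common grid; "
            f"got {reference.shape} vs {floating.shape}"
        )
    ref = reference.normalized()
    flo = floating.normalized()
    if cfg.skip_global:
        transform = RigidTransform.identity(
            ref.ndim, center=tuple((np.asarray(ref.shape, dtype=float) - 1) / 2)
        )
    else:
        transform = rigid_register(ref, flo, cfg)
    flo_aligned = apply_rigid(flo, transform, pad=cfg.pad, pad_value=cfg.pad_value)

    ref_pyr = build_pyramid(ref, cfg.n_levels, cfg.pyramid_factor)
    flo_pyr = build_pyramid(flo_aligned, cfg.n_levels, cfg.pyramid_factor)
    n_levels = ref_pyr.n_levels

    field = DisplacementField.zeros(ref_pyr.levels[0].shape, level=n_levels - 1)
    traces, iters, convs = [], [], []
    for li in range(n_levels):
        field.level = n_levels - 1 - li
        field, trace, it, conv = _run_level(
            ref_pyr.levels[li], flo_pyr.levels[li], field, cfg
        )
        traces.append(trace)
        iters.append(it)
        convs.append(conv)
        if li < n_levels - 1:
            field = upsample_field(
                field, ref_pyr.levels[li + 1].shape, cfg.pyramid_factor
            )
    return RegistrationResult(
        field=field,
        global_transform=transform,
        mi_trace=traces,
        iterations_used=iters,
        converged=convs,
    )


def total_displacement(
    field: DisplacementField, transform: RigidTransform
) -> DisplacementField:
    """Compose the deformable field with the rigid stage into one field.

    The pipeline samples the original floating image at
    ``t(P + v(P))``, so the end-to-end displacement is
    ``v_total(P) = t(P + v(P)) - P``.
    """
    grid = np.indices(field.grid_shape, dtype=np.float64)
    pts = np.moveaxis(grid, 0, -1) + field.vectors
    flat = pts.reshape(-1, field.ndim)
    mapped = transform.apply_to_points(flat).reshape(pts.shape)
    total = mapped - np.moveaxis(grid, 0, -1)
    return DisplacementField(total, level=field.level)
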