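"""Synthetic multimodal phantom pairs with known ground-truth misalignment.

One anatomy (nested soft-tissue ellipses inside a body outline) is rendered
twice: the reference channel emulates a functional (PET-like) image — it
additionally carries a bright focal "lesion" blob emulating tracer uptake —
and the floating channel emulates an anatomical (CT-like) image by passing
the same anatomy through a different intensity transfer function.  The
default transfer function is deliberately *non-monotone* (interior structures
swap their contrast polarity), so that an intensity-difference force alone is
actively misdirected inside the body while MI-driven forces are not: the
multimodal claim the registration method exists for, made testable.

The floating channel is then deformed by the inverse of a known smooth random
displacement field and rigidly displaced, so that recovering exactly
``truth_rigid`` then ``truth_field`` (under the pull-warp convention
``F(P + v)``) re-aligns it with the reference.  Additive Gaussian noise is
applied to both channels.  All randomness derives from ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import DisplacementField, ScalarImage
from .rigid import RigidTransform

logger = logging.getLogger("gmidemons")

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "generate_phantom_pair",
    "endpoint_error",
    "EndpointErrorSummary",
]

# (kind, center fractions, semi-axis fractions, intensity); the anatomy the
# default phantom renders: a body outline with several internal organs of
# distinct intensities spread through it, so that both boundary and interior
# carry alignment information (piecewise-constant interiors with no internal
# structure would make organ-scale motion unobservable for any method)
_DEFAULT_STRUCTURES = (
    ("ellipse", (0.50, 0.50), (0.38, 0.30), 0.35),  # body outline
    ("ring", (0.50, 0.50), (0.30, 0.24), 0.45),  # muscle/fat ring
    ("ellipse", (0.42, 0.44), (0.14, 0.10), 0.65),  # bright organ
    ("ellipse", (0.62, 0.60), (0.08, 0.12), 0.50),  # second organ
    ("ellipse", (0.35, 0.65), (0.09, 0.07), 0.55),  # third organ
    ("ellipse", (0.65, 0.35), (0.07, 0.08), 0.20),  # low-uptake organ
    ("ellipse", (0.52, 0.28), (0.06, 0.05), 0.60),  # small node
    ("ellipse", (0.30, 0.38), (0.05, 0.06), 0.25),  # small dark node
)

# non-monotone transfer function: body becomes the brightest tissue while the
# organ that is brightest in the reference turns darker than its surround
_NONMONOTONE_REMAP = ((0.0, 0.05), (0.35, 0.85), (0.50, 0.75), (0.65, 0.60), (1.0, 0.30))
_MONOTONE_REMAP = ((0.0, 0.05), (0.35, 0.45), (0.50, 0.60), (0.65, 0.75), (1.0, 0.90))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic multimodal test case.

    Defaults are the standard study conditions used across the test suite:
    a 64x64 grid, 5-voxel maximum deformation with a 10-voxel smoothness
    length (a smooth organ-scale motion), a (5, -3)-voxel + 5-degree rigid
    offset, 2% additive noise, and the non-monotone intensity remap.
    """

    shape: tuple = (64, 64)
    structures: tuple = _DEFAULT_STRUCTURES
    remap: str = "nonmonotone"  # "nonmonotone" | "monotone" | "identity"
    lesion_center: tuple = (0.47, 0.40)  # fractions of the grid
    lesion_sigma: float = 2.5  # voxels
    lesion_intensity: float = 1.0
    deform_amplitude: float = 5.0  # voxels, max |v|
    deform_scale: float = 10.0  # voxels, smoothness length
    rigid_translation: tuple = (5.0, -3.0)  # voxels
    rigid_rotation_deg: float = 5.0
    noise_sigma: float = 0.02
    seed: int = 42

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) not in (2, 3):
            raise ValueError("phantoms are 2D or 3D")
        if len(self.shape) == 3:
            # promote 2D structure/lesion definitions to 3D: centred in the
            # third axis, with the mean in-plane semi-axis as thickness
            def promote(struct):
                kind, center, semi, intensity = struct
                if len(center) == 2:
                    center = (*center, 0.5)
                if len(semi) == 2:
                    semi = (*semi, float(np.mean(semi)))
                return (kind, center, semi, intensity)

            self.structures = tuple(promote(s) for s in self.structures)
            if len(self.lesion_center) == 2:
                self.lesion_center = (*self.lesion_center, 0.5)
            if len(self.rigid_translation) == 2:
                self.rigid_translation = (*self.rigid_translation, 0.0)
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.deform_scale <= 0:
            raise ValueError("deform_scale must be > 0")

    @property
    def ndim(self) -> int:
        return len(self.shape)


@dataclass
class PhantomPair:
    """A generated test case with its ground truth."""

    reference: ScalarImage
    floating: ScalarImage
    truth_field: DisplacementField
    truth_rigid: RigidTransform
    body_mask: np.ndarray

    def __iter__(self):
        # unpack like (reference, floating, truth_field, truth_rigid)
        return iter((self.reference, self.floating, self.truth_field, self.truth_rigid))


def _render_anatomy(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.shape, dtype=float)
    grids = np.indices(spec.shape, dtype=np.float64)
    img = np.zeros(spec.shape)
    for kind, center, semi, intensity in spec.structures:
        c = np.asarray(center) * (shape - 1)
        a = np.maximum(np.asarray(semi) * shape, 1.0)
        q = sum(((g - ci) / ai) ** 2 for g, ci, ai in zip(grids, c, a))
        if kind == "ellipse":
            img[q <= 1.0] = intensity
        elif kind == "ring":
            img[(q <= 1.0) & (q >= 0.49)] = intensity  # inner radius 0.7x
        else:
            raise ValueError(f"unknown structure kind {kind!r}")
    # soften edges a little so gradients are informative
    return ndimage.gaussian_filter(img, 1.0, mode="nearest")


def _render_lesion(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.shape, dtype=float)
    grids = np.indices(spec.shape, dtype=np.float64)
    c = np.asarray(spec.lesion_center) * (shape - 1)
    q = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return spec.lesion_intensity * np.exp(-q / (2.0 * spec.lesion_sigma**2))


def _apply_remap(anatomy: np.ndarray, remap) -> np.ndarray:
    if remap == "identity":
        return anatomy.copy()
    if remap == "nonmonotone":
        pts = _NONMONOTONE_REMAP
    elif remap == "monotone":
        pts = _MONOTONE_REMAP
    elif isinstance(remap, (tuple, list)):
        pts = remap
    else:
        raise ValueError(f"unknown remap {remap!r}")
    xs, ys = zip(*pts)
    return np.interp(anatomy, xs, ys)


def _smooth_random_field(
    spec: PhantomSpec, rng: np.random.Generator, body: np.ndarray
) -> np.ndarray:
    """Gaussian-filtered white-noise vectors, windowed to the body support
    (tissue moves, surrounding air does not) and scaled so the maximum
    magnitude equals ``deform_amplitude``."""
    vecs = np.stack(
        [
            ndimage.gaussian_filter(
                rng.standard_normal(spec.shape), spec.deform_scale, mode="mirror"
            )
            for _ in range(spec.ndim)
        ],
        axis=-1,
    )
    envelope = ndimage.gaussian_filter(body.astype(np.float64), 4.0, mode="nearest")
    peak_env = envelope.max()
    if peak_env > 0:
        vecs *= (envelope / peak_env)[..., None]
    mags = np.sqrt(np.sum(vecs**2, axis=-1))
    peak = mags.max()
    if peak > 0 and spec.deform_amplitude > 0:
        vecs *= spec.deform_amplitude / peak
    else:
        vecs[:] = 0.0
    return vecs


def _invert_field(vecs: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Fixed-point inversion: find u with u(x) = -v(x + u(x))."""
    ndim = vecs.shape[-1]
    grid = np.indices(vecs.shape[:-1], dtype=np.float64)
    u = np.zeros_like(vecs)
    for _ in range(n_iter):
        coords = grid + np.moveaxis(u, -1, 0)
        sampled = np.stack(
            [
                ndimage.map_coordinates(vecs[..., a], coords, order=1, mode="nearest")
                for a in range(ndim)
            ],
            axis=-1,
        )
        u = -sampled
    return u


def generate_phantom_pair(spec: PhantomSpec = None) -> PhantomPair:
    """Render a reference/floating pair plus its ground truth.

    With ``deform_amplitude = 0``, an identity rigid offset and zero noise,
    the floating image is exactly the remapped anatomy (the reference minus
    its lesion, passed through the transfer function).
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    anatomy = _render_anatomy(spec)
    reference = anatomy + _render_lesion(spec)
    if spec.noise_sigma > 0:
        reference = reference + rng.normal(0.0, spec.noise_sigma, spec.shape)

    body_intensity = min(s[3] for s in spec.structures)
    body_mask = anatomy > 0.5 * body_intensity
    truth_vecs = _smooth_random_field(spec, rng, body_mask)
    center = tuple((np.asarray(spec.shape, dtype=float) - 1) / 2)
    rot = np.deg2rad(spec.rigid_rotation_deg)
    rotation = (rot,) if spec.ndim == 2 else (rot, 0.0, 0.0)
    truth_rigid = RigidTransform(
        rotation=rotation, translation=tuple(spec.rigid_translation), center=center
    )

    remapped = _apply_remap(anatomy, spec.remap)
    if spec.deform_amplitude > 0 or not truth_rigid.is_identity():
        inv = _invert_field(truth_vecs)
        grid = np.indices(spec.shape, dtype=np.float64)
        pts = np.moveaxis(grid, 0, -1).reshape(-1, spec.ndim)
        back = truth_rigid.inverse().apply_to_points(pts).reshape(
            spec.shape + (spec.ndim,)
        )
        coords_rigid = np.moveaxis(back, -1, 0)
        inv_at = np.stack(
            [
                ndimage.map_coordinates(inv[..., a], coords_rigid, order=1, mode="nearest")
                for a in range(spec.ndim)
            ]
        )
        floating = ndimage.map_coordinates(
            remapped, coords_rigid + inv_at, order=1, mode="nearest"
        )
    else:
        floating = remapped
    if spec.noise_sigma > 0:
        floating = floating + rng.normal(0.0, spec.noise_sigma, spec.shape)

    return PhantomPair(
        reference=ScalarImage(reference),
        floating=ScalarImage(floating),
        truth_field=DisplacementField(truth_vecs),
        truth_rigid=truth_rigid,
        body_mask=body_mask,
    )


@dataclass
class EndpointErrorSummary:
    mean: float
    median: float
    max: float

    def to_dict(self) -> dict:
        return {"mean": self.mean, "median": self.median, "max": self.max}


def endpoint_error(
    estimated: DisplacementField,
    truth: DisplacementField,
    mask: np.ndarray = None,
) -> EndpointErrorSummary:
    """Per-voxel Euclidean field error, summarised inside ``mask`` (voxels)."""
    if estimated.grid_shape != truth.grid_shape:
        raise ValueError("fields must share a grid shape")
    err = np.sqrt(np.sum((estimated.vectors - truth.vectors) ** 2, axis=-1))
    if mask is not None:
        if mask.shape != err.shape:
            raise ValueError("mask shape must match the field grid")
        err = err[mask.astype(bool)]
    return EndpointErrorSummary(
        mean=float(np.mean(err)), median=float(np.median(err)), max=float(np.max(err))
    )
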