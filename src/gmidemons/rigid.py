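"""Rigid (rotation + translation) pre-alignment driven by mutual information.

Multimodal pairs usually carry a whole-body pose error on top of local
deformation; removing it first keeps the deformable stage inside its capture
range.  The transform convention matches the displacement-field convention:
``t`` maps reference coordinates onto floating coordinates, and
``apply_rigid(floating, t)(x) = floating(t(x))`` resamples the floating image
onto the reference frame.

The optimizer is a derivative-free simplex (Nelder–Mead) on negative MI,
multi-started from the identity and from the +/- intensity-centroid offset;
the best of all starts and the identity is returned, so the result is never
worse than no transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .image_model import RegistrationConfig, ScalarImage
from .mi import estimate_joint_density, mutual_information

logger = logging.getLogger("gmidemons")

__all__ = ["RigidTransform", "rigid_register", "apply_rigid"]


def _canonical_angle(a: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    a = math.remainder(float(a), 2.0 * math.pi)
    if a <= -math.pi:
        a += 2.0 * math.pi
    return a


def _rotation_matrix(rotation, ndim: int) -> np.ndarray:
    if ndim == 2:
        (th,) = rotation
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])
    a0, a1, a2 = rotation
    r0 = np.array(
        [[1, 0, 0], [0, math.cos(a0), -math.sin(a0)], [0, math.sin(a0), math.cos(a0)]]
    )
    r1 = np.array(
        [[math.cos(a1), 0, math.sin(a1)], [0, 1, 0], [-math.sin(a1), 0, math.cos(a1)]]
    )
    r2 = np.array(
        [[math.cos(a2), -math.sin(a2), 0], [math.sin(a2), math.cos(a2), 0], [0, 0, 1]]
    )
    return r0 @ r1 @ r2


@dataclass
class RigidTransform:
    """Rotation about ``center`` followed by a translation, in voxel units.

    ``rotation`` is one angle (radians) in 2D or three axis angles in 3D
    (rotations about grid axes 0, 1, 2, composed in that order); angles are
    canonicalised to (-pi, pi].  ``t(x) = R (x - c) + c + translation``.
    """

    rotation: tuple
    translation: tuple
    center: tuple
    #: set when the optimizer failed and the identity was returned instead
    warning: str = ""

    def __post_init__(self):
        if np.isscalar(self.rotation):
            self.rotation = (float(self.rotation),)
        self.rotation = tuple(_canonical_angle(a) for a in self.rotation)
        self.translation = tuple(float(t) for t in self.translation)
        self.center = tuple(float(c) for c in self.center)
        ndim = len(self.translation)
        if ndim not in (2, 3) or len(self.rotation) != (1 if ndim == 2 else 3):
            raise ValueError("rotation/translation dimensionality mismatch")
        if len(self.center) != ndim:
            raise ValueError("center dimensionality mismatch")
        vals = self.rotation + self.translation + self.center
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("transform parameters must be finite")

    @property
    def ndim(self) -> int:
        return len(self.translation)

    def is_identity(self) -> bool:
        return all(a == 0.0 for a in self.rotation) and all(
            t == 0.0 for t in self.translation
        )

    @classmethod
    def identity(cls, ndim: int, center=None) -> "RigidTransform":
        if center is None:
            center = (0.0,) * ndim
        rot = (0.0,) if ndim == 2 else (0.0, 0.0, 0.0)
        return cls(rotation=rot, translation=(0.0,) * ndim, center=center)

    def matrix(self) -> np.ndarray:
        return _rotation_matrix(self.rotation, self.ndim)

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        """Map reference-frame coordinates (n, d) into the floating frame."""
        pts = np.asarray(pts, dtype=np.float64)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (pts - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        """Inverse transform about the same center.

        With ``t(x) = R (x - c) + c + tau`` the inverse is
        ``t^-1(x) = R^T (x - c) + c - R^T tau``.
        """
        rinv = self.matrix().T
        tau = np.asarray(self.translation)
        return RigidTransform(
            rotation=_matrix_to_rotation(rinv),
            translation=tuple(-(rinv @ tau)),
            center=self.center,
        )

    def to_dict(self) -> dict:
        return {
            "rotation": list(self.rotation),
            "translation": list(self.translation),
            "center": list(self.center),
            "warning": self.warning,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation=tuple(d["rotation"]),
            translation=tuple(d["translation"]),
            center=tuple(d["center"]),
            warning=d.get("warning", ""),
        )


def _matrix_to_rotation(r: np.ndarray) -> tuple:
    if r.shape == (2, 2):
        return (math.atan2(r[1, 0], r[0, 0]),)
    # ZYX-style extraction for the R0(a0) R1(a1) R2(a2) composition
    a1 = math.asin(max(-1.0, min(1.0, r[0, 2])))
    a0 = math.atan2(-r[1, 2], r[2, 2])
    a2 = math.atan2(-r[0, 1], r[0, 0])
    return (a0, a1, a2)


def apply_rigid(
    floating: ScalarImage,
    t: RigidTransform,
    pad: str = "edge",
    pad_value: float = 0.0,
) -> ScalarImage:
    """Resample ``floating`` through ``t`` with linear interpolation.

    The identity transform returns the input unchanged (bit-exact).
    """
    if t.ndim != floating.ndim:
        raise ValueError("transform/image dimensionality mismatch")
    if t.is_identity():
        return floating.with_data(floating.data.copy())
    a = t.matrix()
    c = np.asarray(t.center)
    offset = c + np.asarray(t.translation) - a @ c
    mode = "nearest" if pad == "edge" else "grid-constant"
    out = ndimage.affine_transform(
        floating.data, a, offset=offset, order=1, mode=mode, cval=pad_value
    )
    return floating.with_data(out)


def _mi_between(
    reference: ScalarImage, resampled: ScalarImage, cfg: RegistrationConfig
) -> float:
    jd = estimate_joint_density(
        reference, resampled, delta=cfg.parzen_delta, lattice_size=cfg.lattice_size
    )
    return mutual_information(jd)


def _centroid(img: ScalarImage) -> np.ndarray:
    w = img.data - img.data.min()
    total = w.sum()
    if total == 0:
        return (np.asarray(img.shape, dtype=float) - 1) / 2
    grids = np.indices(img.shape, dtype=np.float64)
    return np.array([float((g * w).sum() / total) for g in grids])


def rigid_register(
    reference: ScalarImage,
    floating: ScalarImage,
    cfg: RegistrationConfig = None,
) -> RigidTransform:
    """MI-maximising rigid alignment of ``floating`` to ``reference``.

    Returns the transform ``t`` (reference frame onto floating frame) whose
    resampled floating image has the highest mutual information with the
    reference; never worse than the identity.  On optimizer failure the
    identity is returned with ``warning`` set.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    if reference.ndim != floating.ndim:
        raise ValueError("reference/floating dimensionality mismatch")
    ref = reference.normalized()
    flo = floating.normalized()
    ndim = ref.ndim
    n_rot = 1 if ndim == 2 else 3
    center = tuple((np.asarray(flo.shape, dtype=float) - 1) / 2)

    def unpack(params) -> RigidTransform:
        return RigidTransform(
            rotation=tuple(params[:n_rot]),
            translation=tuple(params[n_rot:]),
            center=center,
        )

    def objective(params) -> float:
        t = unpack(params)
        return -_mi_between(ref, apply_rigid(flo, t), cfg)

    identity_mi = _mi_between(ref, flo, cfg)
    centroid_offset = _centroid(flo) - _centroid(ref)
    starts = [np.zeros(n_rot + ndim)]
    for sign in (+1.0, -1.0):
        s = np.zeros(n_rot + ndim)
        s[n_rot:] = sign * centroid_offset
        starts.append(s)

    def _simplex_search(x0, steps, maxiter):
        simplex = np.vstack(
            [x0] + [x0 + steps[i] * np.eye(len(x0))[i] for i in range(len(x0))]
        )
        return optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": 1e-3,
                "fatol": 1e-6,
                "maxiter": maxiter,
            },
        )

    best_params, best_mi, failed = None, identity_mi, False
    coarse_steps = np.concatenate([np.full(n_rot, 0.1), np.full(ndim, 3.0)])
    fine_steps = np.concatenate([np.full(n_rot, 0.02), np.full(ndim, 0.5)])
    for x0 in starts:
        try:
            res = _simplex_search(np.asarray(x0, dtype=float), coarse_steps, 400)
            # polish from the coarse optimum with a tight simplex; Nelder-Mead
            # contracts quickly and can stall short of the basin floor
            res = _simplex_search(res.x, fine_steps, 300)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("rigid optimizer raised: %s", exc)
            failed = True
            continue
        if -res.fun > best_mi:
            best_mi = -res.fun
            best_params = res.x
    if best_params is None:
        t = RigidTransform.identity(ndim, center=center)
        if failed:
            t.warning = "optimizer failure; identity returned"
        else:
            t.warning = "no start improved on the identity"
        logger.info("rigid registration kept the identity (MI=%.5f)", identity_mi)
        return t
    t = unpack(best_params)
    logger.info(
        "rigid registration: MI %.5f -> %.5f, rotation=%s, translation=%s",
        identity_mi,
        best_mi,
        t.rotation,
        t.translation,
    )
    return t
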