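"""Hausdorff-family distances and feature-point extraction.

Registration quality between two images is scored on feature point sets
(here: body isocontour voxels or strong gradient maxima).  The classic
Hausdorff distance

    H(A, B) = max( h(A, B), h(B, A) ),    h(A, B) = max_{a in A} min_{b in B} ||a - b||

reflects the single worst mismatch and is noise-sensitive; the modified
Hausdorff distance (Dubuisson & Jain) replaces the inner maximum with the
mean of the point-to-set distances,

    h_MHD(A, B) = (1/N_A) sum_{a in A} min_{b in B} ||a - b||,

and the reported M-HD symmetrises the two directed means with the outer
maximum.  Smaller values mean better alignment.  Distances are in voxel
units unless a per-axis ``spacing`` is given, in which case they are in the
spacing's physical units (mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .image_model import ScalarImage, image_gradient

logger = logging.getLogger("gmidemons")

__all__ = [
    "PointSet",
    "directed_hausdorff",
    "hausdorff",
    "modified_hausdorff",
    "directed_modified_hausdorff",
    "extract_feature_points",
    "image_feature_distance",
]


@dataclass
class PointSet:
    """A finite, non-empty list of coordinates in voxel units."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size == 0:
            raise ValueError("a PointSet must contain at least one point")
        if self.points.ndim != 2:
            raise ValueError("points must be an (n, d) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def translated(self, offset) -> "PointSet":
        return PointSet(self.points + np.asarray(offset, dtype=np.float64))


def _scaled(a: PointSet, b: PointSet, spacing):
    if a.dim != b.dim:
        raise ValueError("point sets must share dimensionality")
    pa, pb = a.points, b.points
    if spacing is not None:
        s = np.asarray(spacing, dtype=np.float64)
        if s.shape != (a.dim,):
            raise ValueError("spacing must have one entry per coordinate axis")
        pa, pb = pa * s, pb * s
    return pa, pb


def _min_dists(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """d(a, B) for every a: nearest neighbours via a k-d tree.

    Small problems use the full pairwise distance matrix (bit-identical to a
    direct double-loop evaluation); large ones a k-d tree.
    """
    if pa.shape[0] * pb.shape[0] <= 250_000:
        diff = pa[:, None, :] - pb[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1)).min(axis=1)
    _, idx = cKDTree(pb).query(pa, k=1)
    return np.sqrt(np.sum((pa - pb[idx]) ** 2, axis=-1))


def directed_hausdorff(a: PointSet, b: PointSet, spacing=None) -> float:
    """h(A, B) = max over A of the distance to the nearest point of B."""
    pa, pb = _scaled(a, b, spacing)
    return float(_min_dists(pa, pb).max())


def hausdorff(a: PointSet, b: PointSet, spacing=None) -> float:
    """Symmetric Hausdorff distance max(h(A,B), h(B,A))."""
    pa, pb = _scaled(a, b, spacing)
    return float(max(_min_dists(pa, pb).max(), _min_dists(pb, pa).max()))


def modified_hausdorff(a: PointSet, b: PointSet, spacing=None) -> float:
    """Symmetrised modified Hausdorff distance.

    ``max`` of the two directed mean distances; robust to isolated noise
    points because no single pair dominates.
    """
    pa, pb = _scaled(a, b, spacing)
    return float(max(_min_dists(pa, pb).mean(), _min_dists(pb, pa).mean()))


def directed_modified_hausdorff(a: PointSet, b: PointSet, spacing=None) -> float:
    """The one-sided mean distance h_MHD(A, B)."""
    pa, pb = _scaled(a, b, spacing)
    return float(_min_dists(pa, pb).mean())


def extract_feature_points(
    img: ScalarImage, method: str = "isocontour", threshold: float = None
) -> PointSet:
    """Feature points for Hausdorff-family evaluation.

    ``isocontour``
        Boundary voxels of the largest connected component of
        ``img >= threshold`` (default threshold: Otsu).  The body outline is
        the stable structure shared by both modalities.
    ``edge``
        Local maxima of the gradient magnitude (normalised to max 1) above
        ``threshold`` (default 0.5).

    Raises ``ValueError`` when no feature points survive; lower the
    threshold in that case.
    """
    if method == "isocontour":
        if threshold is None:
            threshold = float(threshold_otsu(img.data))
        mask = img.data >= threshold
        if not mask.any():
            raise ValueError(
                f"no voxels at or above threshold {threshold}; lower the threshold"
            )
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
        # keep the outline only: interior holes (organs straddling the
        # threshold in one modality but not the other) are not a stable
        # cross-modality feature
        mask = ndimage.binary_fill_holes(mask)
        boundary = mask & ~ndimage.binary_erosion(mask)
        coords = np.argwhere(boundary)
    elif method == "edge":
        if threshold is None:
            threshold = 0.5
        mag = np.sqrt(np.sum(image_gradient(img) ** 2, axis=-1))
        peak = mag.max()
        if peak > 0:
            mag = mag / peak
        local_max = mag == ndimage.maximum_filter(mag, size=3, mode="nearest")
        coords = np.argwhere(local_max & (mag > threshold))
    else:
        raise ValueError(f"unknown feature method {method!r}")
    if coords.size == 0:
        raise ValueError(
            f"no feature points found with method={method!r} at "
            f"threshold {threshold}; lower the threshold"
        )
    return PointSet(coords.astype(np.float64))


def image_feature_distance(
    a_img: ScalarImage,
    b_img: ScalarImage,
    method: str = "isocontour",
    threshold: float = None,
    spacing=None,
) -> dict:
    """Hausdorff-family distances between two images' feature points.

    Returns a dict with ``hausdorff``, ``modified_hausdorff``, both directed
    M-HD values, and the unit used.
    """
    a = extract_feature_points(a_img, method=method, threshold=threshold)
    b = extract_feature_points(b_img, method=method, threshold=threshold)
    return {
        "hausdorff": hausdorff(a, b, spacing),
        "modified_hausdorff": modified_hausdorff(a, b, spacing),
        "directed_mhd_ab": directed_modified_hausdorff(a, b, spacing),
        "directed_mhd_ba": directed_modified_hausdorff(b, a, spacing),
        "unit": "mm" if spacing is not None else "voxel",
    }
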