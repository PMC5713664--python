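"""Parzen-window joint density, mutual information, and the MI-gradient force.

The joint intensity distribution of the reference image ``R`` and the warped
floating image ``F(P+v)`` is estimated on a regular lattice of
normalised-intensity pairs with a separable Gaussian Parzen kernel of width
``delta``:

    p(i, j) = (1/N) sum_P K_delta(R(P) - i) * K_delta(F(P+v(P)) - j)

with ``N`` the number of overlap voxels.  Mutual information is the lattice
quadrature of ``p log[p / (p_R p_F)]`` in nats, and its gradient with respect
to the displacement field is, per voxel,

    dMI/dv(P) = (1/N) [Psi_delta (x) dL/dj](R(P), F(P+v)) * grad F(P+v)

with ``L(i,j) = 1 + log[p(i,j) / (p_R(i) p_F(j))]``.  ``(x)`` is convolution
over the intensity lattice; the bracket is looked up at each voxel's
intensity pair by bilinear interpolation, and ``grad F`` is the spatial
gradient of the warped floating interpolant.

Implementation notes: the density is computed by bilinear binning of the
intensity pairs onto the lattice followed by Gaussian smoothing (the standard
fast Parzen estimator) and renormalised so its lattice integral is exactly 1;
``dL/dj`` is taken by central differences on the lattice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import DisplacementField, ScalarImage, warped_image_and_gradient

logger = logging.getLogger("gmidemons")

__all__ = [
    "JointDensity",
    "MIForceField",
    "estimate_joint_density",
    "mutual_information",
    "mi_gradient_field",
]

# kernel truncation (in units of delta) for the lattice Gaussian smoothing;
# generous so that the density support has no sharp cliff feeding the
# log-ratio terms
_TRUNCATE = 6.0


@dataclass
class JointDensity:
    """Parzen-smoothed joint intensity density on a regular lattice.

    ``grid[a, b]`` approximates ``p(i_a, j_b)`` for lattice points
    ``i_a = a / (lattice_size - 1)`` on [0, 1]; the lattice integral
    (``h^2 * grid.sum()``) is 1 and the marginals are consistent with the
    grid by summation.
    """

    grid: np.ndarray
    delta: float
    n_samples: int
    marginal_r: np.ndarray
    marginal_f: np.ndarray
    #: lattice integral of the smoothed histogram before renormalisation
    #: (slightly below n_samples * h^2 when kernel mass leaves the lattice)
    raw_integral: float = 1.0

    def __post_init__(self):
        if np.any(self.grid < 0):
            raise ValueError("density values must be nonnegative")

    @property
    def lattice_size(self) -> int:
        return self.grid.shape[0]

    @property
    def h(self) -> float:
        """Lattice spacing on the normalised intensity axis."""
        return 1.0 / (self.lattice_size - 1)

    @property
    def lattice(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.lattice_size)

    def integral(self) -> float:
        return float(self.grid.sum() * self.h**2)


@dataclass
class MIForceField:
    """Per-voxel MI gradient and the MI value of the current configuration."""

    vectors: np.ndarray
    mi_value: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.vectors)) or not np.isfinite(self.mi_value):
            raise ValueError("MI force must be finite")


def _bilinear_histogram(x: np.ndarray, y: np.ndarray, m: int) -> np.ndarray:
    """Scatter unit-mass samples onto an m x m lattice with bilinear weights.

    ``x``/``y`` are lattice-index coordinates (0 .. m-1), assumed in range.
    """
    i0 = np.clip(np.floor(x).astype(np.intp), 0, m - 2)
    j0 = np.clip(np.floor(y).astype(np.intp), 0, m - 2)
    fx = x - i0
    fy = y - j0
    hist = np.zeros((m, m))
    np.add.at(hist, (i0, j0), (1 - fx) * (1 - fy))
    np.add.at(hist, (i0, j0 + 1), (1 - fx) * fy)
    np.add.at(hist, (i0 + 1, j0), fx * (1 - fy))
    np.add.at(hist, (i0 + 1, j0 + 1), fx * fy)
    return hist


def estimate_joint_density(
    r_img: ScalarImage,
    warped_f: ScalarImage,
    delta: float = 0.05,
    lattice_size: int = 64,
) -> JointDensity:
    """Joint density of the intensity pairs ``(R(P), F_warped(P))``.

    Intensities are expected in [0, 1] (values outside are clipped to the
    lattice range).  The returned density integrates to 1 over the lattice
    to within floating-point round-off.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if lattice_size < 8:
        raise ValueError(f"lattice_size must be >= 8, got {lattice_size}")
    if r_img.shape != warped_f.shape:
        raise ValueError("images must share a grid shape")
    n = r_img.data.size
    if n == 0:
        raise ValueError("empty overlap: no voxels contribute to the joint density")
    m = lattice_size
    h = 1.0 / (m - 1)
    x = np.clip(r_img.data.ravel(), 0.0, 1.0) / h
    y = np.clip(warped_f.data.ravel(), 0.0, 1.0) / h
    hist = _bilinear_histogram(x, y, m)
    sigma = delta / h
    smooth = ndimage.gaussian_filter(hist, sigma, mode="constant", truncate=_TRUNCATE)
    smooth = np.maximum(smooth, 0.0)
    total = smooth.sum() * h**2
    grid = smooth / total
    marginal_r = grid.sum(axis=1) * h
    marginal_f = grid.sum(axis=0) * h
    return JointDensity(
        grid=grid,
        delta=delta,
        n_samples=n,
        marginal_r=marginal_r,
        marginal_f=marginal_f,
        raw_integral=total,
    )


def _log_ratio(jd: JointDensity) -> np.ndarray:
    """``log[p / (p_R p_F)]`` on the lattice; 0-density nodes get the most
    negative on-support value (a flat continuation that keeps the lattice
    derivative bounded)."""
    outer = jd.marginal_r[:, None] * jd.marginal_f[None, :]
    support = jd.grid > 0
    log_ratio = np.zeros_like(jd.grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio[support] = np.log(jd.grid[support] / outer[support])
    if not support.all():
        fill = log_ratio[support].min() if support.any() else 0.0
        log_ratio[~support] = fill
    return log_ratio


def mutual_information(jd: JointDensity) -> float:
    """MI in nats by lattice quadrature; zero-density terms contribute 0."""
    outer = jd.marginal_r[:, None] * jd.marginal_f[None, :]
    support = jd.grid > 0
    terms = np.zeros_like(jd.grid)
    terms[support] = jd.grid[support] * np.log(jd.grid[support] / outer[support])
    return float(terms.sum() * jd.h**2)


def mi_gradient_field(
    r_img: ScalarImage,
    f_img: ScalarImage,
    field: DisplacementField,
    delta: float = 0.05,
    lattice_size: int = 64,
    pad: str = "edge",
    pad_value: float = 0.0,
) -> MIForceField:
    """Analytic gradient of MI with respect to the displacement field.

    Returns the raw per-voxel gradient (no step factor applied) together
    with the MI value of the current configuration.
    """
    if field.grid_shape != r_img.shape:
        raise ValueError("field grid must match the reference grid")
    warped, grad_f = warped_image_and_gradient(f_img, field, pad=pad, pad_value=pad_value)
    vectors, mi = _force_from_warped(r_img, warped, grad_f, delta, lattice_size)
    return MIForceField(vectors=vectors, mi_value=mi)


def _force_from_warped(
    r_img: ScalarImage,
    warped: ScalarImage,
    grad_f: np.ndarray,
    delta: float,
    lattice_size: int,
):
    """MI gradient given the already-warped floating image and its gradient."""
    jd = estimate_joint_density(r_img, warped, delta=delta, lattice_size=lattice_size)
    mi = mutual_information(jd)
    m = jd.lattice_size
    h = jd.h
    # The convolution [Psi (x) dL/dj] is discretised as the exact adjoint of
    # the density estimator (bilinear binning + Gaussian smoothing +
    # renormalisation): smooth L on the lattice with the same kernel, then
    # take the per-bin forward difference in j at each voxel's intensity
    # pair.  The constant -(1+MI) is the renormalisation term; it cancels in
    # the j-difference except where the zero-padded kernel loses mass.
    l_grid = 1.0 + _log_ratio(jd)
    sigma = jd.delta / h
    b = ndimage.gaussian_filter(
        l_grid - 1.0 - mi, sigma, mode="constant", truncate=_TRUNCATE
    )
    x = np.clip(r_img.data, 0.0, 1.0) / h
    y = np.clip(warped.data, 0.0, 1.0) / h
    i0 = np.clip(np.floor(x).astype(np.intp), 0, m - 2)
    j0 = np.clip(np.floor(y).astype(np.intp), 0, m - 2)
    fx = x - i0
    dj_b = np.diff(b, axis=1)  # forward difference along the j lattice axis
    per_voxel = (1 - fx) * dj_b[i0, j0] + fx * dj_b[i0 + 1, j0]
    weights = per_voxel * h / jd.raw_integral
    vectors = grad_f * weights[..., None]
    return vectors, mi
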