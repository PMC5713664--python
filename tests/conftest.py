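import numpy as np
import pytest
from scipy import ndimage

from gmidemons import PhantomSpec, ScalarImage, generate_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def standard_pair():
    """The default multimodal phantom case (seed 42)."""
    return generate_phantom_pair(PhantomSpec())


def smooth_random_image(rng, n=16, blur=2.0, lo=0.2, hi=0.8):
    """A smooth random test image with intensities inside (lo, hi)."""
    a = ndimage.gaussian_filter(rng.standard_normal((n, n)), blur)
    a = (a - a.min()) / (a.max() - a.min())
    return ScalarImage(lo + (hi - lo) * a)


def pick_fd_probe(rng, f_img, field, lattice_size, lo=3, hi=13):
    """Interior voxel, unit direction and step for a finite-difference probe
    of the MI gradient.

    The discrete objective is piecewise linear in the perturbed field value:
    its derivative jumps at interpolation-cell borders (in space) and at
    intensity-lattice bin borders (through the binned density).  The probe
    picks the interior voxel whose sampling position sits farthest from both
    kinds of kink, so the +/- eps excursion stays on a single linear piece.
    Returns ``(voxel, direction, eps)``.
    """
    from gmidemons import warp_image

    warped = warp_image(f_img, field)
    h = 1.0 / (lattice_size - 1)
    best, best_score = None, -1.0
    for i in range(lo, hi):
        for j in range(lo, hi):
            pos = np.array([i, j], dtype=float) + field.vectors[i, j]
            frac = pos - np.floor(pos)
            spatial = float(np.min(np.minimum(frac, 1.0 - frac)))
            y = warped.data[i, j] / h
            fy = y - np.floor(y)
            score = min(spatial, min(fy, 1.0 - fy))
            if score > best_score:
                best, best_score = (i, j), score
    d = rng.standard_normal(2)
    return best, d / np.sqrt((d**2).sum()), 0.01
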