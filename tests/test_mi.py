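import numpy as np
import pytest
from scipy import ndimage

from gmidemons import (
    DisplacementField,
    ScalarImage,
    estimate_joint_density,
    mi_gradient_field,
    mutual_information,
    warp_image,
)
from gmidemons.phantom import PhantomSpec, generate_phantom_pair

from conftest import pick_fd_probe, smooth_random_image


class TestJointDensity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_integral_one_and_marginals_consistent(self, seed):
        rng = np.random.default_rng(seed)
        r = ScalarImage(rng.random((12, 12)))
        f = ScalarImage(rng.random((12, 12)))
        jd = estimate_joint_density(r, f, delta=0.05, lattice_size=64)
        assert jd.integral() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(jd.marginal_r, jd.grid.sum(axis=1) * jd.h)
        assert np.allclose(jd.marginal_f, jd.grid.sum(axis=0) * jd.h)
        assert jd.marginal_r.sum() * jd.h == pytest.approx(1.0, abs=1e-6)

    def test_constant_pair_concentrates_at_their_intensity(self):
        r = ScalarImage(np.full((6, 6), 0.5))
        jd = estimate_joint_density(r, r, delta=0.03, lattice_size=64)
        peak = np.unravel_index(np.argmax(jd.grid), jd.grid.shape)
        assert jd.lattice[peak[0]] == pytest.approx(0.5, abs=jd.h)
        assert jd.lattice[peak[1]] == pytest.approx(0.5, abs=jd.h)
        assert jd.integral() == pytest.approx(1.0, abs=1e-6)

    def test_two_symbol_pair_has_two_equal_modes(self):
        r = ScalarImage(np.array([[0.0, 0.0], [1.0, 1.0]]))
        jd = estimate_joint_density(r, r, delta=0.02, lattice_size=64)
        m = jd.lattice_size
        q = m // 2
        quadrant_mass = np.array(
            [
                jd.grid[:q, :q].sum(),
                jd.grid[q:, q:].sum(),
                jd.grid[:q, q:].sum(),
                jd.grid[q:, :q].sum(),
            ]
        ) * jd.h**2
        assert quadrant_mass[0] == pytest.approx(0.5, abs=1e-3)
        assert quadrant_mass[1] == pytest.approx(0.5, abs=1e-3)
        assert quadrant_mass[2] == pytest.approx(0.0, abs=1e-9)
        assert quadrant_mass[3] == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_joint_density(
                ScalarImage(np.zeros((4, 4))), ScalarImage(np.zeros((5, 5)))
            )


class TestMutualInformation:
    def test_independent_product_density_gives_zero(self, rng):
        # spatially varying reference against a constant floating image:
        # p(i,j) factorises exactly, so MI must vanish
        r = ScalarImage(rng.random((10, 10)))
        f = ScalarImage(np.full((10, 10), 0.5))
        jd = estimate_joint_density(r, f, delta=0.04, lattice_size=64)
        assert mutual_information(jd) == pytest.approx(0.0, abs=1e-9)

    def test_two_symbol_dependent_density_gives_log_two(self):
        r = ScalarImage(np.array([[0.0, 0.0], [1.0, 1.0]]))
        jd = estimate_joint_density(r, r, delta=0.02, lattice_size=64)
        assert mutual_information(jd) == pytest.approx(np.log(2.0), abs=0.02)

    def test_symmetric_in_the_two_images(self, rng):
        r = ScalarImage(rng.random((9, 9)))
        f = ScalarImage(rng.random((9, 9)))
        mi_rf = mutual_information(estimate_joint_density(r, f))
        mi_fr = mutual_information(estimate_joint_density(f, r))
        assert mi_rf == pytest.approx(mi_fr, rel=1e-10)

    def test_self_information_exceeds_shuffled(self, rng):
        data = rng.random((12, 12))
        r = ScalarImage(data)
        shuffled = ScalarImage(rng.permutation(data.ravel()).reshape(12, 12))
        mi_self = mutual_information(estimate_joint_density(r, r))
        mi_shuf = mutual_information(estimate_joint_density(r, shuffled))
        assert mi_self > mi_shuf


def directional_derivative_oracle(r, f, field, voxel, direction, delta, m, eps=0.02):
    """Central finite difference of MI along a single-voxel perturbation."""

    def mi_at(vecs):
        w = warp_image(f, DisplacementField(vecs))
        return mutual_information(estimate_joint_density(r, w, delta, m))

    vp = field.vectors.copy()
    vp[voxel] += eps * direction
    vm = field.vectors.copy()
    vm[voxel] -= eps * direction
    return (mi_at(vp) - mi_at(vm)) / (2 * eps)




class TestMIGradient:
    def test_constant_floating_image_zero_force(self, rng):
        r = ScalarImage(rng.random((10, 10)))
        f = ScalarImage(np.full((10, 10), 0.4))
        out = mi_gradient_field(r, f, DisplacementField.zeros((10, 10)))
        assert np.all(out.vectors == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_finite_differences_of_mi(self, seed):
        """The analytic field gradient agrees with central finite differences
        of the Parzen MI under single-voxel perturbations."""
        rng = np.random.default_rng(seed)
        delta, m = 0.05, 128
        r = smooth_random_image(rng)
        f = smooth_random_image(rng)
        field = DisplacementField(
            ndimage.gaussian_filter(rng.standard_normal((16, 16, 2)), (1.5, 1.5, 0))
        )
        grad = mi_gradient_field(r, f, field, delta=delta, lattice_size=m).vectors
        voxel, direction, eps = pick_fd_probe(rng, f, field, m)
        fd = directional_derivative_oracle(r, f, field, voxel, direction, delta, m, eps)
        an = float(grad[voxel] @ direction)
        assert abs(fd - an) <= 1e-2 * max(abs(fd), abs(an))

    def test_gradient_ascent_step_does_not_decrease_mi(self):
        """One small step along the MI gradient from a perturbed field must
        not lower MI on a smooth multimodal phantom pair."""
        pair = generate_phantom_pair(
            PhantomSpec(seed=5, rigid_translation=(0, 0), rigid_rotation_deg=0.0)
        )
        r = pair.reference.normalized()
        f = pair.floating.normalized()
        rng = np.random.default_rng(1)
        vecs = pair.truth_field.vectors + 0.5 * ndimage.gaussian_filter(
            rng.standard_normal(pair.truth_field.vectors.shape), (2, 2, 0)
        )
        field = DisplacementField(vecs)
        out = mi_gradient_field(r, f, field)
        # small enough that the (piecewise-linear) discrete MI responds in
        # its linear regime
        step = 0.02 / np.abs(out.vectors).max()
        stepped = DisplacementField(vecs + step * out.vectors)
        mi_after = mi_gradient_field(r, f, stepped).mi_value
        assert mi_after >= out.mi_value

    def test_mi_peaks_at_true_alignment(self):
        """MI at the ground-truth field beats MI at jittered fields for an
        intensity-remapped phantom pair."""
        pair = generate_phantom_pair(
            PhantomSpec(seed=9, rigid_translation=(0, 0), rigid_rotation_deg=0.0)
        )
        r = pair.reference.normalized()
        f = pair.floating.normalized()

        def mi_at(vecs):
            w = warp_image(f, DisplacementField(vecs))
            return mutual_information(estimate_joint_density(r, w))

        mi_truth = mi_at(pair.truth_field.vectors)
        rng = np.random.default_rng(3)
        for _ in range(3):
            jitter = ndimage.gaussian_filter(
                rng.standard_normal(pair.truth_field.vectors.shape), (2, 2, 0)
            )
            jitter *= 1.5 / np.sqrt((jitter**2).sum(-1)).mean()
            assert mi_truth >= mi_at(pair.truth_field.vectors + jitter)
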