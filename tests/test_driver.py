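import numpy as np
import pytest

from gmidemons import (
    DisplacementField,
    RegistrationConfig,
    ScalarImage,
    build_pyramid,
    demons_iteration,
    endpoint_error,
    gmi_demons_iteration,
    register,
    total_displacement,
    upsample_field,
)
from gmidemons.driver import _run_level
from gmidemons.mi import estimate_joint_density, mutual_information
from gmidemons.image_model import warp_image
from gmidemons.phantom import PhantomSpec, generate_phantom_pair


class TestBuildPyramid:
    def test_single_level_is_original(self, rng):
        img = ScalarImage(rng.random((20, 20)))
        pyr = build_pyramid(img, 1)
        assert pyr.n_levels == 1
        assert np.array_equal(pyr.levels[0].data, img.data)

    def test_three_level_shapes_from_64(self, rng):
        img = ScalarImage(rng.random((64, 64)))
        pyr = build_pyramid(img, 3, factor=2)
        assert [lv.shape for lv in pyr.levels] == [(16, 16), (32, 32), (64, 64)]
        assert pyr.levels[0].spacing == (4.0, 4.0)

    def test_constant_image_stays_constant(self):
        img = ScalarImage(np.full((32, 32), 2.5))
        pyr = build_pyramid(img, 3)
        for lv in pyr.levels:
            assert np.allclose(lv.data, 2.5)

    def test_depth_reduced_for_small_images(self, rng):
        img = ScalarImage(rng.random((16, 16)))
        pyr = build_pyramid(img, 4, factor=2)
        # 16 -> 8 is allowed, 8 -> 4 would drop below 8 voxels per axis
        assert pyr.n_levels == 2


class TestUpsampleField:
    def test_zero_field_stays_zero(self):
        out = upsample_field(DisplacementField.zeros((8, 8)), (16, 16), 2)
        assert np.all(out.vectors == 0.0)
        assert out.grid_shape == (16, 16)

    def test_uniform_field_rescaled_by_factor(self):
        vec = np.zeros((8, 8, 2))
        vec[..., 0] = 1.0
        out = upsample_field(DisplacementField(vec), (16, 16), 2)
        assert np.allclose(out.vectors[..., 0], 2.0)
        assert np.allclose(out.vectors[..., 1], 0.0)

    def test_incompatible_shapes_rejected(self):
        with pytest.raises(ValueError):
            upsample_field(DisplacementField.zeros((8, 8)), (64, 64), 2)


class TestGMIIteration:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_alpha_zero_reduces_to_classic_demons_bit_exact(self, seed):
        rng = np.random.default_rng(seed)
        r = ScalarImage(rng.random((12, 12)))
        f = ScalarImage(rng.random((12, 12)))
        field = DisplacementField(rng.standard_normal((12, 12, 2)) * 0.5)
        cfg = RegistrationConfig(alpha=0.0)
        a = gmi_demons_iteration(field, r, f, cfg)
        b = demons_iteration(field, r, f, cfg)
        assert np.array_equal(a.vectors, b.vectors)

    def test_identical_images_level_returns_zero_field(self, standard_pair):
        # at exact alignment MI cannot increase, so the per-level guard must
        # hand back the (zero) starting field untouched
        img = standard_pair.reference.normalized()
        cfg = RegistrationConfig(max_iters_per_level=30)
        field, trace, _, _ = _run_level(
            img, img, DisplacementField.zeros(img.shape), cfg
        )
        assert np.array_equal(field.vectors, np.zeros(img.shape + (2,)))
        assert max(trace) <= trace[0] + cfg.mi_stop_threshold * len(trace)


class TestRegister:
    def test_identical_pair_near_identity(self, standard_pair):
        ref = standard_pair.reference
        cfg = RegistrationConfig(max_iters_per_level=30)
        res = register(ref, ref, cfg)
        t = res.global_transform
        assert abs(t.rotation[0]) < 0.01
        assert np.all(np.abs(t.translation) < 0.2)
        assert res.field.magnitudes().max() < 0.1

    def test_deterministic_across_runs(self):
        pair = generate_phantom_pair(PhantomSpec(seed=3))
        cfg = RegistrationConfig(max_iters_per_level=25)
        res1 = register(pair.reference, pair.floating, cfg)
        res2 = register(pair.reference, pair.floating, cfg)
        assert np.array_equal(res1.field.vectors, res2.field.vectors)
        assert res1.mi_trace == res2.mi_trace
        assert res1.global_transform.to_dict() == res2.global_transform.to_dict()

    def test_multimodal_phantom_recovery(self):
        """Rigid offset + smooth deformation + non-monotone remap is
        recovered to sub-voxel mean endpoint error inside the body."""
        pair = generate_phantom_pair(PhantomSpec(seed=3))
        res = register(pair.reference, pair.floating)
        est = total_displacement(res.field, res.global_transform)
        truth = total_displacement(pair.truth_field, pair.truth_rigid)
        err = endpoint_error(est, truth, pair.body_mask)
        baseline = endpoint_error(
            DisplacementField.zeros(truth.grid_shape), truth, pair.body_mask
        )
        assert err.mean < 1.0
        assert err.mean < baseline.mean

    def test_mi_trace_not_below_level_start(self):
        pair = generate_phantom_pair(PhantomSpec(seed=3))
        res = register(pair.reference, pair.floating)
        for trace in res.mi_trace:
            assert max(trace) >= trace[0] - 1e-12
        assert [len(t) >= 1 for t in res.mi_trace]
        assert len(res.mi_trace) == len(res.iterations_used)

    def test_two_levels_not_worse_than_coarse_only(self):
        """Adding the fine level never lowers the full-resolution MI
        achieved by the coarse level alone."""
        pair = generate_phantom_pair(PhantomSpec(seed=4))
        ref = pair.reference.normalized()
        flo = pair.floating.normalized()
        cfg = RegistrationConfig(n_levels=2, skip_global=True, max_iters_per_level=60)

        def full_res_mi(field):
            w = warp_image(flo, field)
            return mutual_information(
                estimate_joint_density(ref, w, cfg.parzen_delta, cfg.lattice_size)
            )

        res2 = register(pair.reference, pair.floating, cfg)

        pyr = build_pyramid(ref, 2, 2)
        coarse_cfg = RegistrationConfig(
            n_levels=1, skip_global=True, max_iters_per_level=60
        )
        field = DisplacementField.zeros(pyr.levels[0].shape)
        coarse_ref = pyr.levels[0]
        coarse_flo = build_pyramid(flo, 2, 2).levels[0]
        field, _, _, _ = _run_level(coarse_ref, coarse_flo, field, coarse_cfg)
        coarse_up = upsample_field(field, ref.shape, 2)
        assert full_res_mi(res2.field) >= full_res_mi(coarse_up) - 1e-9

    def test_shape_mismatch_rejected(self, rng):
        a = ScalarImage(rng.random((16, 16)))
        b = ScalarImage(rng.random((18, 18)))
        with pytest.raises(ValueError):
            register(a, b)


class TestTotalDisplacement:
    def test_identity_transform_returns_field(self, rng):
        from gmidemons import RigidTransform

        vec = rng.standard_normal((6, 6, 2))
        field = DisplacementField(vec.copy())
        t = RigidTransform.identity(2, center=(2.5, 2.5))
        out = total_displacement(field, t)
        assert np.allclose(out.vectors, vec)

    def test_pure_translation_adds_offset(self):
        from gmidemons import RigidTransform

        field = DisplacementField.zeros((5, 5))
        t = RigidTransform(rotation=(0.0,), translation=(2.0, -1.0), center=(2, 2))
        out = total_displacement(field, t)
        assert np.allclose(out.vectors[..., 0], 2.0)
        assert np.allclose(out.vectors[..., 1], -1.0)
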