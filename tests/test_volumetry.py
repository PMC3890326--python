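import numpy as np
import pytest

from serialct.fields import identity_field, invert, jacobian_determinant
from serialct.phantom import NoduleSpec, PhantomSpec, make_phantom_pair, truth_jacobian
from serialct.volume import BinaryMask, ImageVolume
from serialct.volumetry import (jacobian_volume, percent_change, propagate_mask,
                                region_grow, volume_ml)


def sphere_volume(radius, shape=(40, 40, 40), center=None, inside=0.8, outside=0.05):
    center = center or tuple(s / 2.0 for s in shape)
    x = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
    d = np.sqrt(sum((x[i] - center[i]) ** 2 for i in range(3)))
    return ImageVolume(np.where(d <= radius, inside, outside), np.ones(3), np.zeros(3))


class TestRegionGrow:
    def test_recovers_exact_sphere(self):
        vol = sphere_volume(6.0)
        mask = region_grow(vol, (20, 20, 20))
        expected = vol.data > 0.5
        np.testing.assert_array_equal(mask.data, expected)

    def test_two_disjoint_spheres_only_seeded_one(self):
        vol = sphere_volume(5.0, center=(12, 12, 12))
        second = sphere_volume(5.0, center=(28, 28, 28)).data
        vol = ImageVolume(np.maximum(vol.data, second), vol.spacing, vol.origin)
        mask = region_grow(vol, (12, 12, 12))
        assert mask.data[12, 12, 12]
        assert not mask.data[28, 28, 28]

    def test_background_seed_rejected(self):
        with pytest.raises(ValueError, match="background"):
            region_grow(sphere_volume(5.0), (1, 1, 1))

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            region_grow(sphere_volume(5.0), (99, 0, 0))


class TestVolumeMeasures:
    def test_volume_ml_is_count_times_voxel_volume(self):
        data = np.zeros((20, 20, 20), dtype=bool)
        data[:10, :10, :10] = True  # 1000 voxels
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        assert volume_ml(mask) == pytest.approx(1.0)

    def test_empty_mask_zero(self):
        mask = BinaryMask(np.zeros((4, 4, 4), dtype=bool), np.ones(3), np.zeros(3))
        assert volume_ml(mask) == 0.0

    def test_anisotropic_voxels(self):
        data = np.ones((5, 5, 4), dtype=bool)
        mask = BinaryMask(data, np.array([1.0, 1.0, 2.5]), np.zeros(3))
        assert volume_ml(mask) == pytest.approx(100 * 2.5 / 1000.0)

    def test_digital_sphere_matches_analytic_volume(self):
        # r = 15.36 mm at 1 mm isotropic: the order of a sizeable lung mass
        r = 15.36
        vol = sphere_volume(r, shape=(40, 40, 40))
        mask = BinaryMask(vol.data > 0.5, vol.spacing, vol.origin)
        analytic_ml = 4.0 / 3.0 * np.pi * r**3 / 1000.0
        assert volume_ml(mask) == pytest.approx(analytic_ml, rel=0.02)
        assert analytic_ml == pytest.approx(15.2, abs=0.05)


class TestPercentChange:
    @pytest.mark.parametrize("v1,v2,expected", [(15.2, 17.6, 15.8), (10.0, 10.0, 0.0),
                                                (10.0, 12.5, 25.0), (8.0, 6.0, -25.0)])
    def test_worked_values(self, v1, v2, expected):
        assert round(percent_change(v1, v2), 1) == expected

    def test_exchange_relation(self):
        # p12 = -p21 / (1 + p21/100), not a plain sign flip
        p12 = percent_change(15.2, 17.6)
        p21 = percent_change(17.6, 15.2)
        assert p12 == pytest.approx(-p21 / (1 + p21 / 100.0))
        assert p12 != pytest.approx(-p21)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)

    from hypothesis import given, settings, strategies as st

    @given(st.floats(min_value=0.01, max_value=1e4),
           st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=100, deadline=None)
    def test_exchange_identity_holds_generally(self, v1, v2):
        p12 = percent_change(v1, v2)
        p21 = percent_change(v2, v1)
        assert p12 == pytest.approx(-p21 / (1 + p21 / 100.0), rel=1e-9)


class TestMaskPropagation:
    def test_identity_preserves_mask(self):
        data = np.zeros((16, 16, 16), dtype=bool)
        data[5:9, 5:9, 5:9] = True
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        out = propagate_mask(mask, identity_field(mask.shape))
        np.testing.assert_array_equal(out.data, mask.data)

    def test_translation_moves_mask(self):
        data = np.zeros((20, 20, 20), dtype=bool)
        data[5:9, 5:9, 5:9] = True
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        phi = identity_field(mask.shape)
        phi.u[0] += 3.0  # phi maps t1 frame +3 in x
        out = propagate_mask(mask, phi)
        assert out.data[8:12, 5:9, 5:9].all()
        assert out.count() == mask.count()

    def test_growth_warp_scales_volume(self):
        g = 1.25
        spec = PhantomSpec(shape=(48, 48, 48), warp_amplitude=0.0, noise_sd=0.0,
                           nodules=(NoduleSpec(radius=6, change="grow", factor=g,
                                               center=(24.0, 24.0, 24.0)),), seed=1)
        pair = make_phantom_pair(spec)
        out = propagate_mask(pair.masks_t1[0], pair.truth_phi)
        assert out.count() / pair.masks_t1[0].count() == pytest.approx(g, rel=0.03)


class TestJacobianVolume:
    def test_unity_jacobian_equals_volume(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[2:6, 2:6, 2:6] = True
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        J = jacobian_determinant(identity_field(mask.shape))
        assert jacobian_volume(mask, J) == pytest.approx(volume_ml(mask))

    def test_constant_jacobian_scales_volume(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[2:6, 2:6, 2:6] = True
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        J = jacobian_determinant(identity_field(mask.shape))
        J.data[:] = 1.331
        assert jacobian_volume(mask, J) == pytest.approx(1.331 * volume_ml(mask))

    def test_shape_mismatch_rejected(self):
        mask = BinaryMask(np.ones((4, 4, 4), dtype=bool), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            jacobian_volume(mask, jacobian_determinant(identity_field((6, 6, 6))))

    def test_conservation_against_propagated_mask(self):
        # ∫_mask J dV must match the voxel-counted volume of the propagated mask
        g = 1.3
        spec = PhantomSpec(shape=(48, 48, 48), warp_amplitude=2.0, noise_sd=0.0,
                           nodules=(NoduleSpec(radius=6, change="grow", factor=g,
                                               center=(24.0, 24.0, 24.0)),), seed=6)
        pair = make_phantom_pair(spec)
        mask = pair.masks_t1[0]
        v2_mask = volume_ml(propagate_mask(mask, pair.truth_phi))
        v2_jac = jacobian_volume(mask, truth_jacobian(spec))
        assert v2_jac == pytest.approx(v2_mask, rel=0.05)
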