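import numpy as np
import pytest

from serialct.fields import (DeformationField, InversionError, compose,
                             identity_field, invert, jacobian_determinant,
                             load_field, save_field, warp_image, warp_mask,
                             warp_points)
from serialct.volume import BinaryMask, ImageVolume, Landmark, LandmarkSet


def translation_field(shape, shift):
    phi = identity_field(shape)
    for c in range(3):
        phi.u[c] += shift[c]
    return phi


def smooth_random_field(rng, shape, amplitude=2.0, sigma=6.0):
    from scipy.ndimage import gaussian_filter

    u = rng.normal(size=(3, *shape))
    u = np.stack([gaussian_filter(c, sigma) for c in u])
    u *= amplitude / np.abs(u).max()
    return DeformationField(u.astype(np.float32), np.ones(3), np.zeros(3))


@pytest.fixture
def checker_volume(rng):
    data = rng.normal(size=(24, 24, 24))
    from scipy.ndimage import gaussian_filter

    return ImageVolume(gaussian_filter(data, 2.0), np.ones(3), np.zeros(3))


class TestWarpImage:
    def test_identity(self, checker_volume):
        out = warp_image(checker_volume, identity_field(checker_volume.shape))
        np.testing.assert_allclose(out.data, checker_volume.data, atol=1e-6)

    def test_pullback_shift_convention(self, checker_volume):
        # phi = +2-voxel x-shift samples vol(x+2): content moves -2 in output
        phi = translation_field(checker_volume.shape, (2.0, 0.0, 0.0))
        out = warp_image(checker_volume, phi)
        np.testing.assert_allclose(out.data[:-2], checker_volume.data[2:], atol=1e-5)

    def test_warp_then_inverse_recovers(self, rng, checker_volume):
        phi = smooth_random_field(rng, checker_volume.shape, amplitude=1.5)
        phi_inv = invert(phi, tol=1e-3)
        round_trip = warp_image(warp_image(checker_volume, phi), phi_inv)
        core = (slice(4, -4),) * 3
        err = np.abs(round_trip.data[core] - checker_volume.data[core])
        assert err.mean() < 1e-2

    def test_shape_mismatch_rejected(self, checker_volume):
        with pytest.raises(ValueError):
            warp_image(checker_volume, identity_field((8, 8, 8)))


class TestCompose:
    def test_identity_is_neutral(self, rng):
        phi = smooth_random_field(rng, (16, 16, 16))
        out = compose(identity_field(phi.shape), phi)
        np.testing.assert_allclose(out.u, phi.u, atol=1e-5)

    def test_translations_add(self):
        a = translation_field((12, 12, 12), (1.0, 2.0, -1.0))
        b = translation_field((12, 12, 12), (0.5, -1.0, 2.0))
        out = compose(a, b)
        np.testing.assert_allclose(out.u[0], 1.5, atol=1e-5)
        np.testing.assert_allclose(out.u[1], 1.0, atol=1e-5)
        np.testing.assert_allclose(out.u[2], 1.0, atol=1e-5)

    def test_jacobian_chain_rule(self, rng):
        # det D(a∘b) = (det Da)∘b · det Db on smooth fields
        shape = (24, 24, 24)
        a = smooth_random_field(rng, shape, amplitude=1.5, sigma=7.0)
        b = smooth_random_field(np.random.default_rng(7), shape, amplitude=1.5, sigma=7.0)
        lhs = jacobian_determinant(compose(a, b)).data
        ja_at_b = warp_image(
            ImageVolume(jacobian_determinant(a).data, np.ones(3), np.zeros(3)), b,
            fill=1.0).data
        rhs = ja_at_b * jacobian_determinant(b).data
        core = (slice(3, -3),) * 3
        rel = np.abs(lhs[core] - rhs[core]) / rhs[core]
        assert np.quantile(rel, 0.99) < 0.02


class TestJacobianDeterminant:
    def test_identity_is_one(self):
        j = jacobian_determinant(identity_field((10, 10, 10)))
        np.testing.assert_allclose(j.data, 1.0, atol=1e-12)

    def test_linear_scaling(self):
        # phi(x) = 1.1 x => u = 0.1 x => det = 1.331 in the interior
        shape = (12, 12, 12)
        x = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
        phi = DeformationField(0.1 * x, np.ones(3), np.zeros(3))
        j = jacobian_determinant(phi)
        np.testing.assert_allclose(j.data[1:-1, 1:-1, 1:-1], 1.1**3, rtol=1e-6)
        assert j.min_interior() == pytest.approx(1.331, rel=1e-6)

    def test_translation_volume_preserving(self):
        j = jacobian_determinant(translation_field((8, 8, 8), (3.0, -2.0, 1.0)))
        np.testing.assert_allclose(j.data, 1.0, atol=1e-6)

    def test_inverse_jacobian_reciprocal(self, rng):
        # det D(phi^-1) ≈ 1 / (det Dphi ∘ phi^-1)
        phi = smooth_random_field(rng, (24, 24, 24), amplitude=1.5)
        phi_inv = invert(phi, tol=1e-3)
        j_inv = jacobian_determinant(phi_inv).data
        j_at = warp_image(
            ImageVolume(jacobian_determinant(phi).data, np.ones(3), np.zeros(3)),
            phi_inv, fill=1.0).data
        core = (slice(3, -3),) * 3
        rel = np.abs(j_inv[core] * j_at[core] - 1.0)
        assert np.quantile(rel, 0.99) < 0.03


class TestWarpPoints:
    def make_points(self):
        return LandmarkSet([
            Landmark("a", "right", "proximal", (5.0, 6.0, 7.0)),
            Landmark("b", "left", "distal", (10.0, 4.0, 9.0)),
        ])

    def test_identity_keeps_points(self):
        pts = self.make_points()
        out = warp_points(pts, identity_field((16, 16, 16)))
        np.testing.assert_allclose(out.coordinates(), pts.coordinates())
        assert out.labels == pts.labels

    def test_uniform_shift_in_mm(self):
        pts = self.make_points()
        phi = translation_field((16, 16, 16), (1.0, 2.0, 3.0))
        phi.spacing = np.array([2.0, 2.0, 2.0])  # 1 voxel = 2 mm
        pts2 = LandmarkSet([Landmark(p.label, p.side, p.depth, p.xyz) for p in pts])
        out = warp_points(pts2, phi)
        np.testing.assert_allclose(out.coordinates() - pts.coordinates(),
                                   [[2.0, 4.0, 6.0]] * 2)

    def test_outside_grid_flagged(self):
        pts = LandmarkSet([Landmark("far", "right", "proximal", (100.0, 100.0, 100.0))])
        with pytest.warns(UserWarning, match="far"):
            warp_points(pts, identity_field((16, 16, 16)))


class TestInvert:
    def test_translation_inverse(self):
        phi = translation_field((12, 12, 12), (1.5, -0.5, 2.0))
        inv = invert(phi, tol=1e-4)
        core = (slice(3, -3),) * 3
        np.testing.assert_allclose(inv.u[0][core], -1.5, atol=1e-3)
        np.testing.assert_allclose(inv.u[1][core], 0.5, atol=1e-3)

    def test_identity_inverse(self):
        inv = invert(identity_field((8, 8, 8)))
        np.testing.assert_allclose(inv.u, 0.0, atol=1e-8)

    def test_self_consistency_on_smooth_field(self, rng):
        phi = smooth_random_field(rng, (24, 24, 24), amplitude=2.0)
        inv = invert(phi, tol=1e-3)
        resid = compose(phi, inv)
        core = (slice(4, -4),) * 3
        assert np.abs(resid.u[:, *core]).max() < 0.05

    def test_folding_field_raises(self):
        # a displacement with gradient << -1 folds space; inversion must fail
        shape = (16, 16, 16)
        x = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
        u = np.zeros((3, *shape))
        u[0] = -3.0 * np.sin(2 * np.pi * x[0] / 8.0)
        with pytest.raises(InversionError):
            invert(DeformationField(u, np.ones(3), np.zeros(3)), max_iter=20)


class TestWarpMaskAndIO:
    def test_mask_translation(self):
        data = np.zeros((16, 16, 16), dtype=bool)
        data[6:10, 6:10, 6:10] = True
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        out = warp_mask(mask, translation_field(mask.shape, (2.0, 0.0, 0.0)))
        np.testing.assert_array_equal(out.data[4:8, 6:10, 6:10],
                                      np.ones((4, 4, 4), dtype=bool))
        assert out.count() == mask.count()

    def test_field_round_trip(self, rng, tmp_path):
        phi = smooth_random_field(rng, (10, 10, 10))
        phi.spacing = np.array([1.0, 1.0, 2.0])
        phi.origin = np.array([0.0, -5.0, 3.0])
        save_field(phi, tmp_path / "phi.nii.gz")
        back = load_field(tmp_path / "phi.nii.gz")
        np.testing.assert_allclose(back.u, phi.u, atol=1e-6)
        np.testing.assert_allclose(back.spacing, phi.spacing)
        np.testing.assert_allclose(back.origin, phi.origin)

    def test_blob_and_landmark_move_together(self, rng):
        # warp_image and warp_points agree: a bright blob lands where its landmark does
        shape = (24, 24, 24)
        data = np.zeros(shape)
        data[12, 12, 12] = 1.0
        from scipy.ndimage import gaussian_filter

        vol = ImageVolume(gaussian_filter(data, 1.2), np.ones(3), np.zeros(3))
        phi = smooth_random_field(rng, shape, amplitude=2.0)
        phi_inv = invert(phi, tol=1e-3)
        moved = warp_image(vol, phi_inv, fill=0.0)
        peak = np.array(np.unravel_index(np.argmax(moved.data), shape), dtype=float)
        pts = LandmarkSet([Landmark("blob", "right", "proximal", (12.0, 12.0, 12.0))])
        target = warp_points(pts, phi).coordinates()[0]
        assert np.linalg.norm(peak - target) <= 1.0
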