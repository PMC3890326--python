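import numpy as np
import pytest

from serialct.fields import compose, jacobian_determinant, warp_points
from serialct.lddmm import (LDDMM, CascadeLDDMM, CascadeSchedule, VelocityField,
                            cascade_register, lddmm_register)
from serialct.evaluation import landmark_displacement
from serialct.phantom import NoduleSpec, PhantomSpec, make_phantom_pair
from serialct.volume import ImageVolume


def blob_volume(shape=(24, 24, 24), center=(12.0, 12.0, 12.0), sigma=3.0, peak=0.8):
    x = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
    d2 = sum((x[i] - center[i]) ** 2 for i in range(3))
    return ImageVolume(0.05 + peak * np.exp(-d2 / (2 * sigma**2)), np.ones(3), np.zeros(3))


class TestCascadeSchedule:
    def test_default_ratios(self):
        assert CascadeSchedule().ratios == (0.01, 0.005, 0.002)

    @pytest.mark.parametrize("ratios", [(), (0.01, 0.01), (0.002, 0.01), (0.01, -1.0)])
    def test_invalid_rejected(self, ratios):
        with pytest.raises(ValueError):
            CascadeSchedule(ratios)


class TestVelocityFieldType:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            VelocityField(np.zeros((0, 3, 4, 4, 4)))
        v = VelocityField(np.zeros((2, 3, 4, 4, 4)))
        assert v.timesteps == 2


class TestGreedyRegistration:
    def test_identical_images_zero_map(self):
        vol = blob_volume()
        _, phi, phi_inv = lddmm_register(vol, vol, ratio=0.01, iterations=20)
        assert np.abs(phi.u).max() < 0.05
        assert np.abs(phi_inv.u).max() < 0.05

    def test_blob_shift_recovered(self):
        fixed = blob_volume(center=(12.0, 12.0, 12.0))
        moving = blob_volume(center=(14.0, 12.0, 12.0))
        res = LDDMM(fixed, moving, ratio=0.002, iterations=60).fit()
        # phi(center of fixed blob) should land on the moving blob center
        assert res.phi.u[0][12, 12, 12] == pytest.approx(2.0, abs=0.5)
        assert res.final_cost < 0.1 * res.initial_cost

    def test_cost_monotone_and_jacobian_positive(self):
        fixed = blob_volume(center=(12.0, 12.0, 12.0))
        moving = blob_volume(center=(14.0, 13.0, 12.0))
        res = LDDMM(fixed, moving, ratio=0.005, iterations=40).fit()
        costs = res.log["cost"].to_numpy()
        assert np.all(np.diff(costs) <= 0)
        assert res.log["min_jacobian"].to_numpy()[1:].min() > 0
        assert res.min_jacobian > 0

    def test_inverse_consistency(self):
        fixed = blob_volume(center=(12.0, 12.0, 12.0))
        moving = blob_volume(center=(14.0, 12.0, 11.0))
        res = LDDMM(fixed, moving, ratio=0.005, iterations=40).fit()
        resid = compose(res.phi, res.phi_inv)
        core = (slice(4, -4),) * 3
        assert np.abs(resid.u[:, *core]).max() < 0.05

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LDDMM(blob_volume((24, 24, 24)), blob_volume((16, 16, 16)))


class TestVelocityModeRegistration:
    def test_flow_matches_blob_shift(self):
        fixed = blob_volume(shape=(20, 20, 20), center=(10.0, 10.0, 10.0))
        moving = blob_volume(shape=(20, 20, 20), center=(11.5, 10.0, 10.0))
        res = LDDMM(fixed, moving, ratio=0.002, method="velocity", timesteps=5,
                    iterations=30).fit()
        assert res.velocity is not None and res.velocity.timesteps == 5
        assert res.final_cost < res.initial_cost
        energies = res.log["cost"].to_numpy()
        assert np.all(np.diff(energies) <= 0)
        assert res.min_jacobian > 0
        # the flow moves the fixed-frame blob center onto the moving blob
        assert res.phi.u[0][10, 10, 10] == pytest.approx(1.5, abs=0.6)
        resid = compose(res.phi, res.phi_inv)
        assert np.abs(resid.u[:, 4:-4, 4:-4, 4:-4]).max() < 0.1


@pytest.fixture(scope="module")
def warped_pair():
    spec = PhantomSpec(shape=(48, 48, 48), warp_amplitude=3.0, noise_sd=0.02,
                       nodules=(), seed=5)
    return make_phantom_pair(spec)


class TestCascade:

    def test_single_stage_cascade_equals_lddmm(self, warped_pair):
        f, m = warped_pair.vol_t1, warped_pair.vol_t2
        res_c = CascadeLDDMM(f, m, [0.005], iterations=10).fit()
        _, phi, _ = lddmm_register(f, m, ratio=0.005, iterations=10)
        np.testing.assert_array_equal(res_c.phi.u, phi.u)

    def test_identical_images_identity_map(self):
        vol = blob_volume()
        res = cascade_register(vol, vol, iterations=10)
        assert np.abs(res.phi.u).max() < 0.05

    def test_stagewise_residual_nonincreasing(self, warped_pair):
        f, m = warped_pair.vol_t1, warped_pair.vol_t2
        res = CascadeLDDMM(f, m, iterations=25).fit()
        finals = [s.final_cost for s in res.stages]
        starts = [s.initial_cost for s in res.stages]
        for s0, f0 in zip(starts, finals):
            assert f0 <= s0
        # each stage starts from (approximately) the previous stage's residual
        assert finals[0] >= starts[1] * 0.5

    def test_cascade_improves_landmark_accuracy(self, warped_pair):
        f, m = warped_pair.vol_t1, warped_pair.vol_t2
        res = CascadeLDDMM(f, m, iterations=25).fit()
        before = landmark_displacement(warped_pair.landmarks_t2,
                                       warped_pair.landmarks_t1)["distance_mm"].mean()
        after = landmark_displacement(
            warped_pair.landmarks_t2,
            warp_points(warped_pair.landmarks_t1, res.phi))["distance_mm"].mean()
        assert after < 0.7 * before

    def test_elasticity_ordering_on_growth(self):
        # lower ratio admits more localized deformation: better final match
        spec = PhantomSpec(shape=(40, 40, 40), warp_amplitude=0.0, noise_sd=0.0,
                           nodules=(NoduleSpec(radius=5, change="grow", factor=1.5,
                                               center=(20.0, 20.0, 20.0)),), seed=2)
        pair = make_phantom_pair(spec)
        stiff = LDDMM(pair.vol_t1, pair.vol_t2, ratio=0.01, iterations=40).fit()
        elastic = LDDMM(pair.vol_t1, pair.vol_t2, ratio=0.002, iterations=40).fit()
        assert elastic.final_cost <= stiff.final_cost


class TestGrowthJacobian:
    def test_nodule_growth_detected_in_jacobian(self):
        # 6 -> 7 voxel radius growth: mean J over the nodule ≈ (7/6)^3
        factor = (7.0 / 6.0) ** 3
        spec = PhantomSpec(shape=(56, 56, 56), warp_amplitude=0.0, noise_sd=0.01,
                           nodules=(NoduleSpec(radius=6, change="grow", factor=factor,
                                               center=(28.0, 28.0, 28.0)),), seed=8)
        pair = make_phantom_pair(spec)
        res = CascadeLDDMM(pair.vol_t1, pair.vol_t2, iterations=50).fit()
        jac = res.jacobian()
        mean_j = jac.data[pair.masks_t1[0].data].mean()
        assert mean_j == pytest.approx(factor, rel=0.15)
        assert jac.min_interior() > 0
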