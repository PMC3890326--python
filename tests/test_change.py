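import numpy as np
import pytest

from serialct.change import (ChangePattern, ChangeThresholds, classify_change,
                             classify_regions, colorize_jacobian, hybrid_overlay,
                             propose_regions, subtraction_image)
from serialct.fields import JacobianMap, warp_image
from serialct.phantom import (NoduleSpec, PhantomSpec, make_phantom_pair,
                              truth_jacobian)
from serialct.volume import BinaryMask, ImageVolume


def vol(data):
    return ImageVolume(np.asarray(data, dtype=float), np.ones(3), np.zeros(3))


def jac(data):
    return JacobianMap(np.asarray(data, dtype=float), np.ones(3), np.zeros(3))


def region(shape=(8, 8, 8)):
    m = np.zeros(shape, dtype=bool)
    m[2:6, 2:6, 2:6] = True
    return BinaryMask(m, np.ones(3), np.zeros(3))


class TestSubtraction:
    def test_identical_inputs_zero(self, rng):
        a = vol(rng.normal(size=(8, 8, 8)))
        assert np.abs(subtraction_image(a, a).data).max() == 0.0

    def test_antisymmetry(self, rng):
        a, b = vol(rng.normal(size=(6, 6, 6))), vol(rng.normal(size=(6, 6, 6)))
        np.testing.assert_allclose(subtraction_image(a, b).data,
                                   -subtraction_image(b, a).data)

    def test_emerged_nodule_positive_blob(self):
        base = np.full((16, 16, 16), 0.05)
        withnod = base.copy()
        withnod[6:10, 6:10, 6:10] = 0.8
        s = subtraction_image(vol(base), vol(withnod))
        assert s.data[7, 7, 7] > 0.5
        assert np.abs(s.data[0:4]).max() == 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            subtraction_image(vol(np.zeros((4, 4, 4))), vol(np.zeros((5, 5, 5))))


class TestColorizeJacobian:
    def test_unity_is_yellow(self):
        rgb, n_bad = colorize_jacobian(jac(np.ones((4, 4, 4))))
        assert n_bad == 0
        np.testing.assert_allclose(rgb[..., 0], 1.0)  # red channel
        np.testing.assert_allclose(rgb[..., 1], 1.0)  # green channel
        np.testing.assert_allclose(rgb[..., 2], 0.0)

    def test_growth_reddens_shrinkage_greens(self):
        rgb, _ = colorize_jacobian(jac(np.full((2, 2, 2), 1.331)))
        assert rgb[0, 0, 0, 0] == 1.0 and rgb[0, 0, 0, 1] < 0.8
        rgb, _ = colorize_jacobian(jac(np.full((2, 2, 2), 0.75)))
        assert rgb[0, 0, 0, 1] == 1.0 and rgb[0, 0, 0, 0] < 0.7

    def test_monotone_on_each_side(self):
        vals = np.array([1.05, 1.2, 1.5, 2.0]).reshape(4, 1, 1)
        rgb, _ = colorize_jacobian(jac(vals))
        greens = rgb[:, 0, 0, 1]
        assert np.all(np.diff(greens) <= 0)  # redder and redder

    def test_nonpositive_counted_and_flagged(self):
        data = np.ones((3, 3, 3))
        data[0, 0, 0] = -0.2
        rgb, n_bad = colorize_jacobian(jac(data))
        assert n_bad == 1
        np.testing.assert_allclose(rgb[0, 0, 0], [1.0, 0.0, 1.0])

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            colorize_jacobian(jac(np.ones((2, 2, 2))), neutral_band=(1.1, 1.2))


class TestClassifyChange:
    @pytest.mark.parametrize(
        "mean_s,mean_j,expected",
        [
            (0.0, 1.0, "unchanged"),
            (0.02, 1.3, "growing"),
            (-0.03, 0.7, "shrinking"),
            (0.6, 1.0, "emerged"),
            (-0.6, 1.02, "vanished"),
            (0.6, 1.4, "ambiguous"),  # strong signal in both maps
            (-0.6, 0.6, "ambiguous"),
        ],
    )
    def test_decision_table(self, mean_s, mean_j, expected):
        r = region()
        S = vol(np.where(r.data, mean_s, 0.0))
        J = jac(np.where(r.data, mean_j, 1.0))
        pattern = classify_change(r, S, J)
        assert isinstance(pattern, ChangePattern)
        assert pattern.label == expected
        assert pattern.n_voxels == r.count()

    def test_empty_region_rejected(self):
        empty = BinaryMask(np.zeros((8, 8, 8), dtype=bool), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError, match="empty"):
            classify_change(empty, vol(np.zeros((8, 8, 8))), jac(np.ones((8, 8, 8))))

    def test_custom_thresholds(self):
        r = region()
        S = vol(np.zeros((8, 8, 8)))
        J = jac(np.where(r.data, 1.04, 1.0))
        assert classify_change(r, S, J).label == "unchanged"
        tight = ChangeThresholds(tau_s=0.1, tau_j=0.02)
        assert classify_change(r, S, J, tight).label == "growing"


class TestTaxonomyOnTruthEvidence:
    """Change calls from truth-warp evidence across phantoms: with S built
    from the exactly-registered pair and J from the analytic truth map, the
    signature table must recover ≥90% of the scripted labels, with ≥5
    regions per change class pooled over seeds."""

    def test_label_recovery(self, phantom_cache):
        hits, total = [], 0
        per_class = {k: 0 for k in ("none", "grow", "shrink", "appear", "vanish")}
        for seed in (0, 1, 2):
            pair = phantom_cache(PhantomSpec(seed=seed))
            registered = warp_image(pair.vol_t2, pair.truth_phi)
            S = subtraction_image(pair.vol_t1, registered)
            J = truth_jacobian(pair.spec)
            report = classify_regions(pair.regions, S, J)
            expected = {"none": "unchanged", "grow": "growing", "shrink": "shrinking",
                        "appear": "emerged", "vanish": "vanished"}
            for rid, label in zip(report["region"], report["label"]):
                truth = pair.labels[rid]
                per_class[truth] += 1
                hits.append(label == expected[truth])
                total += 1
        assert all(n >= 5 for n in per_class.values())
        assert np.mean(hits) >= 0.9


class TestRegionProposalsAndOverlay:
    def test_proposals_find_emerged_blob(self):
        base = np.full((24, 24, 24), 0.05)
        withnod = base.copy()
        withnod[10:16, 10:16, 10:16] = 0.8
        S = subtraction_image(vol(base), vol(withnod))
        J = jac(np.ones((24, 24, 24)))
        regions = propose_regions(S, J, min_voxels=20)
        assert len(regions) == 1
        assert regions[0].data[12, 12, 12]

    def test_hybrid_overlay_shapes_and_blend(self):
        S = vol(np.zeros((6, 6, 6)))
        data = np.ones((6, 6, 6))
        data[3, 3, 3] = 1.5
        out = hybrid_overlay(S, jac(data))
        assert out.shape == (6, 6, 6, 3)
        np.testing.assert_allclose(out[0, 0, 0], 0.5)  # neutral: plain gray
        assert out[3, 3, 3, 0] > out[3, 3, 3, 1]  # growth blended toward red
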