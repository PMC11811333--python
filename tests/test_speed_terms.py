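"""Edge/region/smoothing speed terms, weight rules and presets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorseg3d import (
    ImageVolume,
    LevelSetField,
    ParameterError,
    SpeedWeights,
    StatsError,
    check_weight_recommendations,
    edge_term,
    hybrid_speed,
    load_presets,
    region_stats,
    region_term,
    sphere_sdf,
)


class TestSpeedWeights:
    def test_normalized_to_unit_sum(self):
        w = SpeedWeights(2, 5, 3)
        assert w.as_tuple() == pytest.approx((0.2, 0.5, 0.3))

    @pytest.mark.parametrize("triple", [(0, 0, 0), (-1, 1, 1)])
    def test_invalid_weights_rejected(self, triple):
        with pytest.raises(ParameterError):
            SpeedWeights(*triple)

    @given(st.tuples(*(st.floats(0, 10),) * 3).filter(lambda t: sum(t) > 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_is_scale_invariant(self, triple):
        w1 = SpeedWeights(*triple)
        w2 = SpeedWeights(*(3.7 * v for v in triple))
        assert w1.as_tuple() == pytest.approx(w2.as_tuple())


class TestEdgeTerm:
    def test_constant_image_gives_unit_speed(self, unit_volume):
        se = edge_term(unit_volume, 0.0, 10.0)
        assert np.allclose(se, 1.0)

    def test_half_speed_where_gradient_equals_contrast_scale(self):
        # ramp with slope 5 everywhere: S_e = 1/(1 + (5/5)^2) = 0.5
        x = np.arange(12, dtype=float)
        vol = ImageVolume(np.broadcast_to(5 * x[:, None, None], (12, 12, 12)).copy(),
                          (1, 1, 1))
        se = edge_term(vol, 0.0, 5.0)
        assert np.allclose(se[1:-1], 0.5)

    def test_minimum_sits_on_blurred_step(self):
        # step blurred by sigma = 2 voxels: S_e argmin within 1 voxel of the
        # true step plane, against an exhaustive scan of the profile
        from scipy import ndimage

        n = 40
        img = np.zeros((n, 16, 16))
        img[20:] = 100.0
        img = ndimage.gaussian_filter(img, sigma=(2.0, 0, 0))
        vol = ImageVolume(img, (1, 1, 1))
        se = edge_term(vol, 0.0, 10.0)
        profile = se[:, 8, 8]
        assert abs(int(np.argmin(profile)) - 19.5) <= 1.0

    def test_invariant_to_intensity_shift(self, sphere_field):
        rng = np.random.default_rng(3)
        base = rng.normal(100, 10, (16, 16, 16))
        a = edge_term(ImageVolume(base, (1, 1, 1)), 1.0, 5.0)
        b = edge_term(ImageVolume(base + 500.0, (1, 1, 1)), 1.0, 5.0)
        assert np.allclose(a, b)

    def test_range_is_zero_one(self):
        rng = np.random.default_rng(4)
        vol = ImageVolume(rng.normal(0, 50, (16, 16, 16)), (1, 1, 1))
        se = edge_term(vol, 1.0, 3.0)
        assert se.min() > 0 and se.max() <= 1.0

    def test_nonpositive_contrast_scale_rejected(self, unit_volume):
        with pytest.raises(ParameterError):
            edge_term(unit_volume, 1.0, 0.0)


def _two_phase(c_in=200.0, c_out=50.0):
    """Sphere of intensity c_in on c_out background + matching SDF interior."""
    fld = sphere_sdf((24, 24, 24), (1, 1, 1), (11.5, 11.5, 11.5), 6.0)
    img = np.where(fld.phi < 0, c_in, c_out)
    return ImageVolume(img, (1, 1, 1)), fld


class TestRegionTerm:
    def test_interior_intensity_expands(self):
        vol, fld = _two_phase()
        sr = region_term(vol, fld)
        assert sr[fld.phi < 0].min() > 0.99  # I = c_in exactly -> +1 after scaling

    def test_midpoint_intensity_is_neutral(self):
        vol, fld = _two_phase()
        img = vol.data.copy()
        img[0, 0, 0] = 125.0  # (200 + 50) / 2
        vol2 = ImageVolume(img, (1, 1, 1))
        stats = region_stats(vol2, fld)
        sr = region_term(vol2, fld, stats)
        assert sr[0, 0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_detached_interior_like_distractor_is_positive(self):
        vol, fld = _two_phase()
        img = vol.data.copy()
        img[2:5, 2:5, 2:5] = 200.0  # far from the sphere, interior-like
        vol2 = ImageVolume(img, (1, 1, 1))
        sr = region_term(vol2, fld)
        assert sr[3, 3, 3] > 0.5

    def test_empty_interior_raises(self, unit_volume):
        fld = LevelSetField(np.ones((16, 16, 16)), (1, 1, 1))
        with pytest.raises(StatsError):
            region_stats(unit_volume, fld)

    def test_affine_intensity_invariance(self):
        vol, fld = _two_phase()
        sr1 = region_term(vol, fld)
        vol2 = ImageVolume(2.5 * vol.data + 40.0, (1, 1, 1))
        sr2 = region_term(vol2, fld)
        assert np.allclose(sr1, sr2)

    def test_range_bounded(self):
        rng = np.random.default_rng(5)
        vol, fld = _two_phase()
        vol2 = ImageVolume(vol.data + rng.normal(0, 30, vol.shape), (1, 1, 1))
        sr = region_term(vol2, fld)
        assert sr.min() >= -1.0 and sr.max() <= 1.0


class TestHybridSpeed:
    def test_degenerate_weights_return_single_term(self):
        rng = np.random.default_rng(6)
        se, sr, ss = (rng.normal(size=(6, 6, 6)) for _ in range(3))
        assert np.array_equal(hybrid_speed(se, sr, ss, SpeedWeights(1, 0, 0)), se)

    def test_acceptable_weights_arithmetic(self):
        one = np.ones((4, 4, 4))
        zero = np.zeros((4, 4, 4))
        f = hybrid_speed(one, one, zero, SpeedWeights(0.2, 0.5, 0.3))
        assert f[0, 0, 0] == pytest.approx(0.7)

    def test_null_terms_give_null_speed(self):
        zero = np.zeros((4, 4, 4))
        assert not hybrid_speed(zero, zero, zero, SpeedWeights(1, 1, 1)).any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linear_superposition(self, seed):
        rng = np.random.default_rng(seed)
        se1, se2, sr, ss = (rng.normal(size=(5, 5, 5)) for _ in range(4))
        w = SpeedWeights(*rng.uniform(0.1, 1, 3))
        lhs = hybrid_speed(se1 + se2, sr, ss, w)
        rhs = hybrid_speed(se1, sr, ss, w) + w.alpha * se2
        assert np.allclose(lhs, rhs)


class TestWeightRecommendations:
    def test_acceptable_set_for_edema_is_clean(self):
        assert check_weight_recommendations(SpeedWeights(0.2, 0.5, 0.3), "edema") == []

    def test_strong_smoothing_warns_for_any_component(self):
        warns = check_weight_recommendations(SpeedWeights(0.1, 0.1, 0.8), None)
        assert len(warns) == 1 and "gamma" in warns[0]

    def test_strong_edge_warns_low_beta_for_edema(self):
        warns = check_weight_recommendations(SpeedWeights(0.8, 0.1, 0.1), "edema")
        assert any("beta" in w for w in warns)


class TestPresets:
    def test_presets_obey_published_rules(self):
        presets = load_presets()
        assert set(presets) == {"contrast_enhancing", "necrotic", "edema"}
        for p in presets.values():
            assert p.weights.gamma <= 0.3 + 1e-12
        assert presets["edema"].weights.beta >= 0.5
        assert presets["edema"].weights.as_tuple() == pytest.approx((0.2, 0.5, 0.3))
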