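import numpy as np
import pytest
from scipy import ndimage

from octpre import dmaps


class TestRetinaAnchoredMap:
    def test_hand_values(self):
        m = dmaps.map_2netR(100, 300, 640, 1)
        assert m[100, 0] == pytest.approx(0.0, abs=1e-12)
        assert m[300, 0] == pytest.approx(1.0, abs=1e-12)
        assert m[50, 0] == pytest.approx(-0.25, abs=1e-12)

    def test_monotone_down_columns(self, rng):
        ilm = rng.uniform(50, 200, 32)
        rpe = ilm + rng.uniform(30, 100, 32)
        m = dmaps.map_2netR(ilm, rpe, 320)
        assert np.all(np.diff(m, axis=0) >= 0)

    def test_degenerate_column_clamped(self):
        # zero-height retina: denominator clamps to one pixel, no error
        m = dmaps.map_2netR(100, 100, 200, 1)
        assert np.all(np.isfinite(m))
        assert m[100, 0] == pytest.approx(0.0)


class TestPreretinalAnchoredMap:
    def test_hand_values(self):
        m = dmaps.map_2netPR(100, 200, 300, 640, 1)
        assert m[100, 0] == pytest.approx(0.0, abs=1e-12)   # PCV anchor
        assert m[200, 0] == pytest.approx(0.5, abs=1e-12)   # ILM anchor
        assert m[150, 0] == pytest.approx(0.25, abs=1e-12)  # preretinal branch
        assert m[350, 0] == pytest.approx(1.25, abs=1e-12)  # outside branch
        assert m[300, 0] == pytest.approx(1.0, abs=1e-12)   # RPE anchor

    def test_continuity_and_monotonicity_random_boundaries(self, rng):
        # branch limits agree at all three anchors; map non-decreasing
        for _ in range(1000):
            h = 160
            pcv = rng.uniform(5, 50)
            ilm = pcv + rng.integers(0, 40)
            rpe = ilm + rng.integers(1, 50)
            m = dmaps.map_2netPR(pcv, ilm, rpe, h, 1)[:, 0]
            assert np.all(np.diff(m) >= -1e-9)
            for anchor, val in ((pcv, 0.0), (ilm, 0.5), (rpe, 1.0)):
                lo, hi = int(np.floor(anchor)), int(np.ceil(anchor))
                # the map interpolates the anchor value between its rows
                assert m[lo] - 1e-9 <= val <= m[hi] + 1e-9

    def test_exact_continuity_at_integer_anchors(self):
        pcv, ilm, rpe = 40, 70, 110
        m = dmaps.map_2netPR(pcv, ilm, rpe, 160, 1)[:, 0]
        # evaluate adjacent-branch formulas at the anchor rows
        assert m[ilm] == pytest.approx(0.5, abs=1e-12)
        assert m[pcv] == pytest.approx(0.0, abs=1e-12)
        assert m[rpe] == pytest.approx(1.0, abs=1e-12)

    def test_adhesion_column_takes_retina_branch_value(self):
        m = dmaps.map_2netPR(100, 100, 150, 200, 1)
        assert m[100, 0] == pytest.approx(0.5)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            dmaps.map_2netPR(100, 90, 150, 200, 1)


class TestCumSumMap:
    def test_all_zero_image(self):
        assert np.all(dmaps.map_cumsum(np.zeros((8, 4))) == 0)

    def test_single_column_of_ones(self):
        np.testing.assert_allclose(dmaps.map_cumsum(np.ones((4, 1))).ravel(),
                                   [0.25, 0.5, 0.75, 1.0])

    def test_monotone_and_bounded(self, rng):
        img = rng.uniform(0, 1, (40, 30))
        m = dmaps.map_cumsum(img)
        assert np.all(np.diff(m, axis=0) >= 0)
        np.testing.assert_allclose(m.max(axis=0), 1.0)

    def test_scale_invariance(self, rng):
        img = rng.uniform(0, 1, (20, 10))
        np.testing.assert_allclose(dmaps.map_cumsum(img),
                                   dmaps.map_cumsum(7.3 * img))

    def test_anchors_on_retina_indicator(self):
        # clean indicator of the retina: the map approaches the
        # retina-anchored anchors (0 at ILM, 1 at RPE)
        img = np.zeros((200, 5))
        ilm, rpe = 80, 140
        img[ilm:rpe + 1] = 1.0
        m = dmaps.map_cumsum(img)
        assert np.all(m[ilm - 1] == 0)
        assert m[ilm, 0] <= 1.0 / (rpe - ilm)
        np.testing.assert_allclose(m[rpe], 1.0)


class TestBasicOrientMap:
    def test_uniform_image_vertical_ramp(self):
        m = dmaps.map_basic_orient(np.full((32, 16), 0.5))
        np.testing.assert_allclose(m[0], 0.0)
        np.testing.assert_allclose(m[-1], 1.0)
        assert np.all(np.diff(m, axis=0) > 0)

    @pytest.mark.parametrize("phi", [-18.0, -7.0, 0.0, 6.0, 14.0, 20.0])
    def test_orientation_recovery_on_tilted_edge(self, phi):
        # horizontal step edge tilted by a known angle: y = tan(phi) * x + c,
        # positive angle = edge descends toward the right
        h = w = 256
        y, x = np.mgrid[0:h, 0:w].astype(float)
        edge = h / 2 + np.tan(np.radians(phi)) * (x - w / 2)
        img = (y > edge).astype(float)
        assert dmaps.estimate_orientation(img) == pytest.approx(phi, abs=2.0)

    def test_map_range(self, rng):
        img = rng.uniform(0, 1, (64, 48))
        m = dmaps.map_basic_orient(img)
        assert m.min() == pytest.approx(0.0)
        assert m.max() == pytest.approx(1.0)

    def test_recovers_phantom_orientation_on_noiseless_scan(self):
        from octpre import phantom

        for seed in (1, 2, 3):
            cfg = phantom.PhantomConfig.for_size(
                256, 256, seed=seed, case_type="VMA", speckle_shape=None)
            img, _, b = phantom.generate_phantom(cfg)
            tilt = np.degrees(np.arctan((b.rpe[-1] - b.rpe[0]) / len(b.rpe)))
            est = dmaps.estimate_orientation(img)
            assert est == pytest.approx(tilt, abs=3.0)


class TestAttachMap:
    def test_two_channel_stack(self, rng):
        img = rng.uniform(0, 1, (64, 48))
        m = dmaps.map_cumsum(img)
        x = dmaps.attach_map(img, m)
        assert x.shape == (2, 64, 48)
        assert abs(x[0].mean()) < 1e-5 and abs(x[0].std() - 1) < 1e-4
        np.testing.assert_array_equal(x[1], m.astype(np.float32))

    def test_no_map_baseline(self, rng):
        x = dmaps.attach_map(rng.uniform(0, 1, (32, 32)), None)
        assert x.shape == (1, 32, 32)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dmaps.attach_map(rng.uniform(0, 1, (32, 32)), np.zeros((16, 16)))


def test_map_save_load_round_trip(tmp_path, rng):
    m = rng.uniform(-0.5, 1.5, (20, 10))
    dmaps.save_map(tmp_path / "m.npy", m, "2NetR", sigma=3)
    vals, meta = dmaps.load_map(tmp_path / "m.npy")
    np.testing.assert_allclose(vals, m.astype(np.float32))
    assert meta["variant"] == "2NetR" and meta["params"]["sigma"] == 3
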