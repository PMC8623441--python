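import numpy as np
import pytest

from octpre import phantom
from octpre.metrics import extract_boundaries, tii
from octpre.phantom import PhantomConfig, generate_boundaries, render_bscan


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"height": 100, "width": 128},   # not divisible by 16
        {"height": 16, "width": 128},    # too small
        {"pcv_visibility": 1.5},
        {"case_type": "PVD"},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            PhantomConfig(**kw)

    def test_impossible_geometry_rejected(self):
        # retina thicker than the image cannot fit
        cfg = PhantomConfig(height=64, width=64, retina_thickness_px=80,
                            retina_thickness_jitter=0, seed=0)
        with pytest.raises(ValueError):
            generate_boundaries(cfg)


class TestBoundaries:
    def test_vma_shallow_detachment_with_wide_adhesion(self):
        # VMA: wide central attachment (pcv == ilm) and shallow perifoveal
        # detachment; mean gap calibrated to clinical preretinal volumes
        gaps = []
        for seed in range(10):
            cfg = PhantomConfig(orientation_deg=0, case_type="VMA", seed=seed)
            b = generate_boundaries(cfg)
            assert np.any(b.pcv == b.ilm)
            gaps.append((b.ilm - b.pcv).mean())
        assert 5 < np.mean(gaps) < 45

    def test_vmt_has_adhesion_and_traction(self):
        cfg = PhantomConfig(case_type="VMT", seed=7)
        b = generate_boundaries(cfg)
        assert np.any(b.pcv == b.ilm)
        assert np.any(b.ilm - b.pcv > 20)

    def test_vmt_gaps_exceed_vma_gaps(self):
        mean_gap = {"VMA": [], "VMT": []}
        for seed in range(10):
            for case in mean_gap:
                b = generate_boundaries(PhantomConfig(case_type=case, seed=seed))
                mean_gap[case].append((b.ilm - b.pcv).mean())
        assert np.mean(mean_gap["VMT"]) > 2 * np.mean(mean_gap["VMA"])

    @pytest.mark.parametrize("case", ["VMA", "VMT"])
    def test_deterministic_given_seed(self, case):
        cfg = PhantomConfig(case_type=case, seed=42)
        b1 = generate_boundaries(cfg)
        b2 = generate_boundaries(cfg)
        for k in ("pcv", "ilm", "rpe"):
            np.testing.assert_array_equal(getattr(b1, k), getattr(b2, k))

    def test_ordering_invariant(self):
        for seed in range(10):
            for case in ("VMA", "VMT"):
                cfg = PhantomConfig.for_size(128, 128, case_type=case, seed=seed)
                generate_boundaries(cfg).validate(128)  # raises on violation


class TestRender:
    def test_noiseless_column_profile_piecewise_constant(self):
        cfg = PhantomConfig.for_size(128, 128, seed=3, case_type="VMT",
                                     pcv_visibility=1.0, speckle_shape=None)
        img, mask, b = phantom.generate_phantom(cfg)
        # every column takes only the few designed intensity levels
        assert np.unique(np.round(img, 6)).size <= 8
        # bright PCV run present in an elevated, visible column
        col = int(np.argmax(b.ilm - b.pcv))
        top = int(np.ceil(b.pcv[col] - 0.5))
        assert img[top, col] == pytest.approx(0.55)

    def test_mask_boundary_round_trip(self, small_phantoms):
        for s in small_phantoms:
            eb, flags = extract_boundaries(s.mask)
            assert not flags.any()
            for k in ("pcv", "ilm", "rpe"):
                err = np.abs(getattr(eb, k) - getattr(s.bounds, k))
                assert err.max() <= 0.5, k

    def test_ground_truth_masks_topologically_valid(self, small_phantoms):
        assert tii([s.mask for s in small_phantoms]) == 0.0

    def test_image_range_and_determinism(self):
        cfg = PhantomConfig.for_size(64, 64, seed=5, case_type="VMA")
        img1, m1, _ = phantom.generate_phantom(cfg)
        img2, m2, _ = phantom.generate_phantom(cfg)
        np.testing.assert_array_equal(img1, img2)
        np.testing.assert_array_equal(m1, m2)
        assert img1.min() >= 0 and img1.max() <= 1


class TestDataset:
    @pytest.mark.parametrize("n,expected", [(100, (80, 10, 10)), (10, (8, 1, 1))])
    def test_split_sizes(self, n, expected):
        assert phantom.split_sizes(n) == expected

    def test_split_ratio_matches_large_scale_bookkeeping(self):
        # the 80/10/10 rule reproduces the study-scale ratios
        train, val, test = phantom.split_sizes(7050)
        assert (train, val, test) == (5640, 705, 705)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            phantom.split_sizes(100, (0.8, 0.3, 0.1))

    def test_manifest_round_trip(self, tmp_path):
        manifest = phantom.generate_dataset(10, tmp_path, seed=3,
                                            height=64, width=64)
        assert len(manifest["samples"]) == 10
        tags = [e["subset"] for e in manifest["samples"]]
        assert tags.count("train") == 8 and tags.count("val") == 1
        s = phantom.load_sample(manifest["samples"][0], tmp_path)
        orig = phantom.generate_samples(10, height=64, width=64, seed=3)[0]
        assert np.abs(s.image - orig.image).max() < 1e-4  # 16-bit quantisation
        np.testing.assert_array_equal(s.mask, orig.mask)
        np.testing.assert_allclose(s.bounds.ilm, orig.bounds.ilm)

    def test_vmt_volumes_exceed_vma(self):
        from octpre.metrics import preretinal_volume

        samples = phantom.generate_samples(40, height=128, width=128, seed=17)
        vols = {"VMA": [], "VMT": []}
        for s in samples:
            vols[s.case_type].append(preretinal_volume([s.mask]))
        assert np.mean(vols["VMT"]) > np.mean(vols["VMA"])

    def test_volume_groups_never_straddle_subsets(self):
        samples = phantom.generate_samples(40, height=64, width=64, seed=9,
                                           scans_per_volume=3)
        by_group = {}
        for s in samples:
            by_group.setdefault(s.group, set()).add(s.subset)
        assert all(len(v) == 1 for v in by_group.values())
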