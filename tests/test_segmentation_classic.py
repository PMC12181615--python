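import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import helpers
from cmhq import segmentation_classic as sc
from cmhq.errors import ConfigurationError, DegenerateInputError
from cmhq.synthetic_slides import SlideSimConfig, generate_section


def _disk(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestBandpass:
    def test_flat_field_passes_through(self):
        out = sc.bandpass_filter(np.full((40, 40), 7.0), 50, 2)
        assert np.allclose(out, 7.0)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            sc.bandpass_filter(np.zeros((10, 10)), 2, 50)

    def test_small_structures_attenuated(self):
        # impulse and a 10 px blob in one image (shared rescaling), so
        # their responses stay comparable: the impulse responds <= 50%
        img = np.zeros((256, 256))
        img[64, 64] = 1.0
        img[_disk(img.shape, (192, 192), 5)] = 1.0
        out = sc.bandpass_filter(img, 50, 2)
        base = np.median(out)
        r_imp = out[60:69, 60:69].max() - base
        r_blob = out[188:197, 188:197].max() - base
        assert r_imp <= 0.5 * r_blob

    def test_large_structures_suppressed(self):
        # 200 px blob and 20 px blob in one image: the big blob's interior
        # is flattened to < 20% of the small blob's center response
        img = np.zeros((512, 768))
        img[_disk(img.shape, (256, 256), 100)] = 1.0
        img[_disk(img.shape, (256, 620), 10)] = 1.0
        out = sc.bandpass_filter(img, 50, 2)
        base = np.median(out)
        r_big_center = out[256, 256] - base
        r_small_center = out[256, 620] - base
        assert r_big_center < 0.2 * r_small_center


class TestOtsu:
    def test_two_level_image_split_exactly(self):
        vals = np.array([50.0] * 60 + [200.0] * 40)
        t = sc.otsu_threshold(vals.reshape(10, 10))
        assert 50.0 < t <= 200.0
        assert ((vals > t) == (vals == 200.0)).all()

    def test_binary_extremes(self):
        vals = np.array([0.0, 255.0] * 50)
        t = sc.otsu_threshold(vals)
        lo, hi = vals[vals <= t], vals[vals > t]
        assert lo.std() == 0 and hi.std() == 0

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sc.otsu_threshold(np.full((5, 5), 3.0))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 4
        if kind == 0:
            vals = rng.integers(0, 256, 500).astype(float)
        elif kind == 1:
            vals = np.concatenate([rng.normal(60, 5, 300),
                                   rng.normal(180, 20, 200)])
        elif kind == 2:  # adversarial: symmetric two-sided histogram
            vals = np.concatenate([rng.integers(0, 10, 250),
                                   255 - rng.integers(0, 10, 250)]).astype(float)
        else:
            vals = rng.uniform(-5, 5, 400)
        assert sc.otsu_threshold(vals) == helpers.otsu_brute_force(vals)


class TestBinarize:
    def test_threshold_above_max_empty(self):
        m = sc.binarize(np.arange(9.0).reshape(3, 3), 100.0, "bright")
        assert not m.mask.any()

    def test_threshold_below_min_full(self):
        m = sc.binarize(np.arange(9.0).reshape(3, 3), -1.0, "bright")
        assert m.mask.all()

    def test_complement_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 10, (20, 20)).astype(float)
        t = 4.0
        bright = sc.binarize(img, t, "bright").mask
        dark = sc.binarize(img, t, "dark").mask
        at_t = img == t
        assert np.array_equal(bright, ~dark & ~at_t)


class TestFillHoles:
    def test_enclosed_pixel_filled(self):
        ring = np.zeros((5, 5), bool)
        ring[1:4, 1:4] = True
        ring[2, 2] = False
        assert sc.fill_holes(ring).mask[2, 2]

    def test_no_holes_identity(self):
        solid = np.zeros((6, 6), bool)
        solid[2:4, 2:5] = True
        assert np.array_equal(sc.fill_holes(solid).mask, solid)

    @settings(deadline=None, max_examples=30)
    @given(mask=hnp.arrays(bool, (12, 12)))
    def test_matches_border_flood_fill_oracle(self, mask):
        got = sc.fill_holes(mask).mask
        want = helpers.fill_holes_flood(mask)
        assert np.array_equal(got, want)
        assert np.all(got[mask])  # foreground never removed


class TestAnalyzeParticles:
    def test_empty_mask_empty_table(self):
        df = sc.analyze_particles(np.zeros((8, 8), bool), 1.0)
        assert len(df) == 0

    def test_diagonal_connectivity_definition(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(sc.analyze_particles(mask, 10.0, connectivity=8)) == 1
        assert len(sc.analyze_particles(mask, 10.0, connectivity=4)) == 2

    def test_min_area_filter_in_physical_units(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True          # 1 px = 1 um^2 at 1 um/px
        mask[5:9, 5:9] = True      # 16 um^2
        df = sc.analyze_particles(mask, 1.0, min_area_um2=10.0)
        assert len(df) == 1
        assert df.iloc[0]["pixels"] == 16

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) < 0.35
        df = sc.analyze_particles(mask, 1.0, min_area_um2=0.0,
                                  connectivity=connectivity)
        _, sizes = helpers.label_flood_fill(mask, connectivity)
        assert len(df) == len(sizes)
        assert sorted(df["pixels"]) == sorted(sizes)
        assert df["pixels"].sum() == mask.sum()  # conservation


class TestSegmentHdab:
    def test_all_bleeds_found_on_clean_section(self, clean_stack):
        imgs, truth = clean_stack
        checked = 0
        for img, sec in zip(imgs, truth.sections):
            if not len(sec.objects):
                continue
            mask = sc.segment_hdab(img).mask
            rec = helpers.per_object_recall(sec.bleed_labels, mask,
                                            sec.objects)
            assert rec["small"][0] == rec["small"][1]
            assert rec["large"][0] == rec["large"][1]
            checked += len(sec.objects)
        assert checked > 0

    def test_artifacts_inflate_object_count(self):
        cfg = SlideSimConfig(n_sections=1, n_bleeds_total=3,
                             small_large_mix=1.0, artifact_rate=10.0,
                             rng_seed=5)
        img, truth = generate_section(cfg, 0)
        mask = sc.segment_hdab(img)
        n = len(sc.analyze_particles(mask, cfg.pixel_size_um))
        assert n > len(truth.objects)

    def test_blank_white_image_empty_mask(self):
        blank = np.full((32, 32, 3), 255, np.uint8)
        assert not sc.segment_hdab(blank).mask.any()

    def test_deterministic(self, default_stack):
        imgs, _ = default_stack
        a = sc.segment_hdab(imgs[0]).mask
        b = sc.segment_hdab(imgs[0]).mask
        assert np.array_equal(a, b)


class TestSegmentYiq:
    def test_all_bleeds_found_on_clean_section(self, clean_stack):
        imgs, truth = clean_stack
        for img, sec in zip(imgs, truth.sections):
            if not len(sec.objects):
                continue
            mask = sc.segment_yiq(img).mask
            rec = helpers.per_object_recall(sec.bleed_labels, mask,
                                            sec.objects)
            assert rec["small"][0] == rec["small"][1]
            assert rec["large"][0] == rec["large"][1]

    def test_bleed_free_section_near_empty(self):
        cfg = SlideSimConfig(n_bleeds_total=0, artifact_rate=0.0)
        img, truth = generate_section(cfg, 3)
        mask = sc.segment_yiq(img).mask
        assert mask.sum() < 0.001 * truth.tissue_mask.sum()

    def test_achromatic_image_degenerate(self):
        gray = np.full((16, 16, 3), 128, np.uint8)
        with pytest.raises(DegenerateInputError):
            sc.segment_yiq(gray)

    def test_counts_closer_to_truth_than_hdab(self, default_stack):
        imgs, truth = default_stack
        px = SlideSimConfig().pixel_size_um
        n_true = len(truth.objects)
        n_yiq = sum(len(sc.analyze_particles(sc.segment_yiq(i), px))
                    for i in imgs)
        n_hdab = sum(len(sc.analyze_particles(sc.segment_hdab(i), px))
                     for i in imgs)
        assert abs(n_yiq / n_true - 1) < abs(n_hdab / n_true - 1)

    def test_mask_serializes_as_0_255(self, default_stack):
        imgs, _ = default_stack
        u8 = sc.segment_yiq(imgs[0]).to_uint8()
        assert set(np.unique(u8)) <= {0, 255}
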