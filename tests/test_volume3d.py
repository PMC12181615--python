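import numpy as np
import pytest

from cmhq import registration as rg
from cmhq import volume3d as v3
from cmhq.errors import ConfigurationError, DataError, DegenerateInputError


def _stack(labels, px=1.725):
    return rg.SectionStack([np.asarray(l, np.uint8) for l in labels],
                           pixel_size_um=px)


@pytest.fixture(scope="module")
def aligned_truth_stack(clean_stack):
    _, truth = clean_stack
    return _stack(truth.label_stack())


class TestDownscale:
    def test_factor_one_identity(self, aligned_truth_stack):
        out = v3.downscale_stack(aligned_truth_stack, 1)
        assert np.array_equal(out.images[0], aligned_truth_stack.images[0])

    def test_uniform_block_stays_uniform(self):
        out = v3.downscale_stack(_stack([np.ones((10, 10))]), 5)
        assert np.all(np.asarray(out.images[0]) == 1)
        assert out.pixel_size_um == pytest.approx(5 * 1.725)

    def test_majority_vote_matches_oracle(self):
        rng = np.random.default_rng(0)
        lab = rng.integers(0, 3, (25, 25)).astype(np.uint8)
        out = np.asarray(v3.downscale_stack(_stack([lab]), 5).images[0])
        for bi in range(5):
            for bj in range(5):
                block = lab[bi * 5:(bi + 1) * 5, bj * 5:(bj + 1) * 5]
                counts = [(block == c).sum() for c in (0, 1, 2)]
                best = max(counts)
                # ties break toward the higher code
                want = max(c for c in (0, 1, 2) if counts[c] == best)
                assert out[bi, bj] == want

    def test_majority_bleed_block(self):
        lab = np.ones((5, 5), np.uint8)
        lab.flat[:13] = 2  # 13 of 25 bleed pixels
        out = v3.downscale_stack(_stack([lab]), 5)
        assert np.asarray(out.images[0])[0, 0] == 2

    def test_factor_larger_than_image_rejected(self):
        with pytest.raises(ConfigurationError):
            v3.downscale_stack(_stack([np.ones((4, 4))]), 5)


class TestBrainMask:
    def test_envelope_matches_solid_ellipse(self):
        yy, xx = np.mgrid[0:60, 0:80]
        ellipse = (((yy - 30) / 20.0) ** 2 + ((xx - 40) / 30.0) ** 2) <= 1
        stack = _stack([ellipse.astype(np.uint8)] * 8)
        mask = v3.build_brain_mask(stack)
        mid = mask[4]
        inter = (mid & ellipse).sum()
        dice = 2 * inter / (mid.sum() + ellipse.sum())
        assert dice >= 0.98

    def test_isolated_speck_excluded(self):
        yy, xx = np.mgrid[0:60, 0:80]
        ellipse = (((yy - 30) / 15.0) ** 2 + ((xx - 30) / 20.0) ** 2) <= 1
        lab = ellipse.astype(np.uint8)
        lab[2, 75] = 2  # far-away single-voxel noise
        mask = v3.build_brain_mask(_stack([lab] * 6))
        assert not mask[:, 2, 75].any()

    def test_single_connected_component(self, aligned_truth_stack):
        from scipy import ndimage

        mask = v3.build_brain_mask(aligned_truth_stack)
        _, n = ndimage.label(mask)
        assert n == 1


class TestMinimumOverlay:
    def test_true_mask_is_noop(self, aligned_truth_stack):
        mask = np.ones((len(aligned_truth_stack),)
                       + aligned_truth_stack.canvas_shape, bool)
        out = v3.minimum_overlay(aligned_truth_stack, mask)
        for a, b in zip(out.images, aligned_truth_stack.images):
            assert np.array_equal(a, b)

    def test_false_mask_zeroes_everything(self, aligned_truth_stack):
        mask = np.zeros((len(aligned_truth_stack),)
                        + aligned_truth_stack.canvas_shape, bool)
        out = v3.minimum_overlay(aligned_truth_stack, mask)
        assert all(np.asarray(i).max() == 0 for i in out.images)

    def test_pointwise_min_semantics(self):
        lab = np.array([[2, 2], [1, 0]], np.uint8)
        mask = np.array([[[True, False], [True, False]]])
        out = v3.minimum_overlay(_stack([lab]), mask)
        assert np.array_equal(np.asarray(out.images[0]),
                              [[2, 0], [1, 0]])

    def test_never_increases_bleed_count(self, aligned_truth_stack):
        mask = v3.build_brain_mask(aligned_truth_stack)
        out = v3.minimum_overlay(aligned_truth_stack, mask)
        before = sum(int((np.asarray(i) == 2).sum())
                     for i in aligned_truth_stack.images)
        after = sum(int((np.asarray(i) == 2).sum()) for i in out.images)
        assert after <= before

    def test_shape_mismatch_rejected(self, aligned_truth_stack):
        with pytest.raises(DataError):
            v3.minimum_overlay(aligned_truth_stack, np.ones((2, 3, 4), bool))


class TestAssemble:
    def test_depth_arithmetic(self, aligned_truth_stack):
        vol = v3.assemble_volume(aligned_truth_stack, z_spacing_um=20.0)
        assert vol.depth_mm == pytest.approx(
            len(aligned_truth_stack) * 20.0 / 1000.0)

    def test_voxel_counts_conserved_exactly(self, aligned_truth_stack):
        vol = v3.assemble_volume(aligned_truth_stack)
        for code in (0, 1, 2):
            per_section = sum(int((np.asarray(i) == code).sum())
                              for i in aligned_truth_stack.images)
            assert int((vol.codes == code).sum()) == per_section

    def test_3d_objects_not_more_than_2d(self, aligned_truth_stack):
        from cmhq.segmentation_classic import analyze_particles

        vol = v3.assemble_volume(aligned_truth_stack)
        n3d = v3.count_objects_3d(vol)
        n2d = sum(
            len(analyze_particles(np.asarray(i) == 2, 1.725,
                                  min_area_um2=0.0))
            for i in aligned_truth_stack.images)
        assert 0 < n3d <= n2d


class TestQuantify:
    def test_area_fraction_arithmetic(self):
        lab = np.zeros((40, 40), np.uint8)
        lab[:25, :40] = 1  # 1000 px total stained area after adding bleeds
        lab[0, :10] = 2    # 10 bleed px of the 1000
        df = v3.quantify(_stack([lab], px=1000.0), min_area_um2=0.0)
        agg = df.iloc[-1]
        assert agg["area_fraction_pct"] == pytest.approx(1.0)

    def test_density_arithmetic(self):
        # 5 isolated objects in 2 mm^2 of tissue -> 2.5 per mm^2
        lab = np.zeros((200, 100), np.uint8)
        lab[:, :] = 1
        for k in range(5):
            lab[10 + 20 * k, 50] = 2
        px = np.sqrt(2e6 / (200 * 100))  # tissue area = 2 mm^2
        df = v3.quantify(_stack([lab], px=px), min_area_um2=0.0)
        assert df.iloc[-1]["density_per_mm2"] == pytest.approx(2.5)

    def test_zero_tissue_degenerate(self):
        with pytest.raises(DegenerateInputError):
            v3.quantify(_stack([np.zeros((10, 10), np.uint8)]))

    def test_aggregate_is_area_weighted(self, aligned_truth_stack):
        df = v3.quantify(aligned_truth_stack)
        per = df[df["section"] != "aggregate"]
        agg = df.iloc[-1]
        assert agg["tissue_area_mm2"] == pytest.approx(
            per["tissue_area_mm2"].sum())
        assert agg["bleed_count"] == per["bleed_count"].sum()

    def test_downscale_preserves_area_within_tolerance(
            self, aligned_truth_stack):
        # total bleed area changes <= 20% for objects >= 3 output voxels
        small = v3.downscale_stack(aligned_truth_stack, 5)
        a0 = sum(int((np.asarray(i) == 2).sum())
                 for i in aligned_truth_stack.images) * 1.725 ** 2
        a1 = sum(int((np.asarray(i) == 2).sum())
                 for i in small.images) * (1.725 * 5) ** 2
        assert abs(a1 / a0 - 1.0) <= 0.20
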