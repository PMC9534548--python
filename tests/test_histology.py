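"""Tumor mask, k-SD GFP thresholding and cluster quantification."""

from collections import deque

import numpy as np
import pytest

from syncytia import synthetic
from syncytia.histology import (
    ClusterStats,
    Slide,
    count_clusters,
    gfp_background,
    gfp_threshold,
    group_ordering_concordance,
    quantify_slide,
    summarize_tumor,
    tumor_mask,
)

SLIDE_KW = dict(dilation_radius_px=3, min_region_px=1000)


def flood_fill_count(image, min_px=1, max_px=None):
    """Exhaustive BFS connected-component oracle (8-connectivity)."""
    fg = np.asarray(image) > 0
    seen = np.zeros_like(fg, dtype=bool)
    h, w = fg.shape
    count, total = 0, 0
    for sy in range(h):
        for sx in range(w):
            if not fg[sy, sx] or seen[sy, sx]:
                continue
            area = 0
            queue = deque([(sy, sx)])
            seen[sy, sx] = True
            while queue:
                y, x = queue.popleft()
                area += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
            if area >= min_px and (max_px is None or area <= max_px):
                count += 1
                total += area
    return count, total


@pytest.fixture(scope="module")
def slide_and_truth():
    return synthetic.generate_histology_slide(seed=7)


class TestTumorMask:
    def test_mask_area_within_5pct_of_generated_outline(self, slide_and_truth):
        slide, truth = slide_and_truth
        _, area = tumor_mask(slide.nuclear, **SLIDE_KW)
        assert area == pytest.approx(truth.params["tumor_area_px"], rel=0.05)

    def test_blank_nuclear_channel_rejected(self):
        with pytest.raises(ValueError):
            tumor_mask(np.zeros((64, 64)), dilation_radius_px=3, min_region_px=0)

    def test_zero_radius_mask_equals_raw_foreground(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 100.0
        mask, area = tumor_mask(img, dilation_radius_px=0, min_region_px=0, threshold=50.0)
        np.testing.assert_array_equal(mask, img > 50.0)
        assert area == 100


class TestBackground:
    def test_constant_gfp_inside_mask(self):
        gfp = np.full((32, 32), 7.0)
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:20, 4:20] = True
        mean, sd = gfp_background(gfp, mask)
        assert mean == 7.0 and sd == 0.0

    def test_background_estimate_matches_generator(self, slide_and_truth):
        slide, truth = slide_and_truth
        mask, _ = tumor_mask(slide.nuclear, **SLIDE_KW)
        mean, _ = gfp_background(slide.gfp, mask)
        assert mean == pytest.approx(truth.params["background_mean"], rel=0.02)

    def test_pixels_outside_mask_ignored(self):
        gfp = np.zeros((16, 16))
        mask = np.zeros((16, 16), dtype=bool)
        mask[:8] = True
        gfp[8:] = 1e6  # bright pixels outside the mask must not leak in
        mean, sd = gfp_background(gfp, mask)
        assert mean == 0.0 and sd == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            gfp_background(np.ones((8, 8)), np.zeros((8, 8), dtype=bool))


class TestThreshold:
    def test_strict_inequality_at_boundary(self):
        gfp = np.full((4, 4), 10.0)
        mask = np.ones((4, 4), dtype=bool)
        out = gfp_threshold(gfp, mask, mean=6.0, sd=1.0, k=4.0)  # 10 == 6 + 4*1
        assert not out.any()

    def test_huge_k_zeroes_everything(self, slide_and_truth):
        slide, _ = slide_and_truth
        mask, _ = tumor_mask(slide.nuclear, **SLIDE_KW)
        mean, sd = gfp_background(slide.gfp, mask)
        assert not gfp_threshold(slide.gfp, mask, mean, sd, k=1e6).any()

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            gfp_threshold(np.ones((4, 4)), np.ones((4, 4), dtype=bool), 1.0, 0.0, 4)


class TestClusters:
    def test_empty_image_gives_zero(self):
        assert count_clusters(np.zeros((16, 16))) == ClusterStats(0, 0)

    def test_oversized_cluster_excluded(self):
        img = np.zeros((64, 64))
        img[2:6, 2:6] = 1.0  # 16 px, kept
        img[20:52, 20:52] = 1.0  # 1024 px, filtered as noncellular
        stats = count_clusters(img, min_cluster_px=10, max_cluster_px=500)
        assert stats == ClusterStats(1, 16)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = (rng.random((64, 64)) < 0.25).astype(float)
        got = count_clusters(img, min_cluster_px=3, max_cluster_px=200)
        expect = flood_fill_count(img, min_px=3, max_px=200)
        assert (got.count, got.ensemble_area) == expect


class TestSlidePipeline:
    def test_planted_clusters_recovered_exactly_at_all_k(self, slide_and_truth):
        slide, truth = slide_and_truth
        q = quantify_slide(slide, **SLIDE_KW)
        for k in (4, 5, 6):
            assert q.per_k[k].count == truth.params["n_clusters"]
            assert q.per_k[k].ensemble_area == truth.params["ensemble_area_px"]

    def test_zero_cluster_slide_reports_zero_at_all_k(self):
        slide, _ = synthetic.generate_histology_slide(n_clusters=0, seed=8)
        q = quantify_slide(slide, **SLIDE_KW)
        assert all(s == ClusterStats(0, 0) for s in q.per_k.values())

    def test_count_and_area_non_increasing_in_k(self):
        # include marginal clusters near the threshold to exercise monotonicity
        slide, _ = synthetic.generate_histology_slide(
            cluster_height_sd=5.5, seed=9
        )
        q = quantify_slide(slide, **SLIDE_KW)
        counts = [q.per_k[k].count for k in (4, 5, 6)]
        areas = [q.per_k[k].ensemble_area for k in (4, 5, 6)]
        assert counts[0] >= counts[1] >= counts[2]
        assert areas[0] >= areas[1] >= areas[2]


class TestSummaries:
    def _quant(self, idx, count, area):
        return type(
            "Q",
            (),
            {
                "slide_index": idx,
                "tumor_area_px": 10_000,
                "tumor_area_mm2": 0.01,
                "per_k": {k: ClusterStats(count, area) for k in (4, 5, 6)},
            },
        )()

    def test_totals_are_additive(self):
        total = summarize_tumor([self._quant(0, 5, 2000), self._quant(1, 7, 3000)])
        for k in (4, 5, 6):
            assert total.per_k[k] == ClusterStats(12, 5000)
        assert total.tumor_area_px == 20_000

    def test_single_slide_summary_is_identity(self):
        q = self._quant(0, 3, 900)
        total = summarize_tumor([q])
        assert total.per_k[4] == ClusterStats(3, 900)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_tumor([])

    def test_group_ordering_concordant_across_k(self):
        """Distinct cluster loads (left > right flank) keep the same ordering
        at every thresholding level."""
        left_slide, _ = synthetic.generate_histology_slide(n_clusters=14, seed=21)
        right_slide, _ = synthetic.generate_histology_slide(n_clusters=3, seed=22)
        left = summarize_tumor([quantify_slide(left_slide, **SLIDE_KW)])
        right = summarize_tumor([quantify_slide(right_slide, **SLIDE_KW)])
        report = group_ordering_concordance({"left": left, "right": right})
        assert report["concordant"]
        assert all(o == ("left", "right") for o in report["orderings"].values())
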