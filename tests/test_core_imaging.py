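"""Shared imaging primitives: thresholding, labeling, skeletons, edges."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import draw as skdraw

from wormquant.core import (
    BinaryImage,
    GrayImage,
    Skeleton,
    adaptive_threshold,
    canny_edges,
    fill_gaps_and_holes,
    label_regions,
    skeletonize_mask,
)


def brute_force_local_mean_mask(pixels, window, offset):
    """Per-pixel local-mean threshold with edge-replicated windows."""
    h, w = pixels.shape
    r = window // 2
    padded = np.pad(pixels.astype(float), r, mode="edge")
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            m = padded[i:i + window, j:j + window].mean()
            out[i, j] = pixels[i, j] < m * (1 - offset)
    return out


class TestAdaptiveThreshold:
    def test_uniform_image_all_background(self):
        img = GrayImage(np.full((50, 50), 128, np.uint8))
        assert not adaptive_threshold(img, window=11).mask.any()

    def test_dark_square_matches_brute_force_oracle(self):
        px = np.full((60, 60), 200, np.uint8)
        px[25:35, 25:35] = 40
        img = GrayImage(px)
        got = adaptive_threshold(img, window=31, offset_fraction=0.15).mask
        expected = brute_force_local_mean_mask(px, 31, 0.15)
        assert np.array_equal(got, expected)
        assert got.sum() == 100
        assert got[25:35, 25:35].all()

    def test_illumination_ramp_yields_almost_no_foreground(self):
        ramp = np.tile(np.linspace(60, 220, 200), (100, 1))
        img = GrayImage(np.round(ramp).astype(np.uint8))
        mask = adaptive_threshold(img, window=31, offset_fraction=0.15).mask
        assert mask.mean() < 0.01
        oracle = brute_force_local_mean_mask(img.pixels, 31, 0.15)
        assert np.array_equal(mask, oracle)

    @pytest.mark.parametrize("window, offset, err", [
        (4, 0.1, "odd"), (1, 0.1, "odd"), (501, 0.1, "exceeds"),
        (11, 1.0, "offset"), (11, -0.1, "offset"),
    ])
    def test_invalid_parameters_rejected(self, window, offset, err):
        img = GrayImage(np.full((40, 40), 100, np.uint8))
        with pytest.raises(ValueError, match=err):
            adaptive_threshold(img, window=window, offset_fraction=offset)

    def test_raising_offset_never_adds_foreground(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.integers(0, 256, (64, 64)).astype(np.uint8))
        prev = None
        for offset in (0.0, 0.1, 0.2, 0.4, 0.8):
            mask = adaptive_threshold(img, window=15, offset_fraction=offset).mask
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask


def union_find_label_count_and_areas(mask, connectivity):
    """Independent connected-component oracle via union-find."""
    h, w = mask.shape
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    offs = [(-1, 0), (0, -1)] if connectivity == 4 else \
           [(-1, -1), (-1, 0), (-1, 1), (0, -1)]
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            parent.setdefault((i, j), (i, j))
            for di, dj in offs:
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and mask[ni, nj]:
                    union((i, j), (ni, nj))
    comps = {}
    for p in parent:
        comps.setdefault(find(p), []).append(p)
    return sorted(len(v) for v in comps.values())


class TestLabelRegions:
    def test_empty_mask_gives_no_regions(self):
        assert label_regions(BinaryImage(np.zeros((10, 10), bool))) == []

    def test_two_disjoint_squares(self):
        m = np.zeros((20, 20), bool)
        m[2:5, 2:5] = True
        m[10:13, 10:13] = True
        regions = label_regions(BinaryImage(m))
        assert sorted(r.area for r in regions) == [9, 9]

    def test_corner_touching_squares_connectivity(self):
        m = np.zeros((10, 10), bool)
        m[2:4, 2:4] = True
        m[4:6, 4:6] = True  # touch only at corner (3,3)-(4,4)
        assert len(label_regions(BinaryImage(m), connectivity=4)) == 2
        assert len(label_regions(BinaryImage(m), connectivity=8)) == 1

    @given(st.integers(0, 2**32 - 1), st.sampled_from([4, 8]))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_union_find_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((rng.integers(1, 33), rng.integers(1, 33))) < 0.4
        regions = label_regions(BinaryImage(mask), connectivity=connectivity)
        assert sorted(r.area for r in regions) == \
            union_find_label_count_and_areas(mask, connectivity)

    def test_areas_partition_foreground(self):
        rng = np.random.default_rng(3)
        mask = rng.random((80, 80)) < 0.3
        regions = label_regions(BinaryImage(mask))
        assert sum(r.area for r in regions) == int(mask.sum())


class TestSkeletonize:
    def test_bar_gives_branch_free_two_endpoint_curve(self):
        m = np.zeros((20, 120), bool)
        m[8:13, 5:106] = True
        sk = skeletonize_mask(BinaryImage(m))
        assert sk.branch_count == 0
        assert len(sk.endpoints) == 2
        assert sk.path[:, 1].max() - sk.path[:, 1].min() >= 90

    def test_plus_sign_has_branches(self):
        m = np.zeros((41, 41), bool)
        m[18:23, 5:36] = True
        m[5:36, 18:23] = True
        assert skeletonize_mask(BinaryImage(m)).branch_count >= 1

    def test_disk_gives_degenerate_skeleton(self):
        m = np.zeros((30, 30), bool)
        rr, cc = skdraw.disk((15, 15), 10)
        m[rr, cc] = True
        sk = skeletonize_mask(BinaryImage(m))
        assert sk.n_pixels < 5
        assert not sk.is_worm_like

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            skeletonize_mask(BinaryImage(np.zeros((5, 5), bool)))

    def test_skeleton_contained_in_mask_and_idempotent(self):
        m = np.zeros((30, 80), bool)
        m[10:17, 5:75] = True
        sk = skeletonize_mask(BinaryImage(m))
        assert m[sk.path[:, 0], sk.path[:, 1]].all()
        as_mask = np.zeros_like(m)
        as_mask[sk.path[:, 0], sk.path[:, 1]] = True
        sk2 = skeletonize_mask(BinaryImage(as_mask))
        assert {tuple(p) for p in sk2.path} == {tuple(p) for p in sk.path}


class TestCannyAndFill:
    def test_uniform_image_no_edges(self):
        img = GrayImage(np.full((40, 40), 150, np.uint8))
        assert not canny_edges(img, 10, 30).mask.any()

    def test_dark_disk_yields_ring_that_fills_to_disk(self):
        px = np.full((60, 60), 200, np.uint8)
        rr, cc = skdraw.disk((30, 30), 10)
        px[rr, cc] = 60
        edges = canny_edges(GrayImage(px), 10, 30)
        assert edges.mask.any()
        filled = fill_gaps_and_holes(edges, max_gap=3)
        area = filled.mask.sum()
        assert abs(area - np.pi * 100) < 0.25 * np.pi * 100

    def test_two_disks_give_two_separate_rings(self):
        px = np.full((60, 120), 200, np.uint8)
        for c in (30, 90):
            rr, cc = skdraw.disk((30, c), 10)
            px[rr, cc] = 60
        filled = fill_gaps_and_holes(canny_edges(GrayImage(px), 10, 30), 3)
        assert len(label_regions(filled)) == 2

    def test_inverted_thresholds_rejected(self):
        img = GrayImage(np.full((20, 20), 100, np.uint8))
        with pytest.raises(ValueError):
            canny_edges(img, 30, 10)

    def _square_outline(self, break_cols=()):
        m = np.zeros((30, 30), bool)
        m[5, 5:25] = True
        m[24, 5:25] = True
        m[5:25, 5] = True
        m[5:25, 24] = True
        for c in break_cols:
            m[5, c] = False
        return m

    def test_closed_contour_fills_solid(self):
        filled = fill_gaps_and_holes(BinaryImage(self._square_outline()), 0)
        assert filled.mask.sum() == 20 * 20

    def test_small_break_bridged_and_filled(self):
        outline = self._square_outline(break_cols=(14, 15))
        filled = fill_gaps_and_holes(BinaryImage(outline), max_gap=3)
        assert filled.mask.sum() > 300  # solid interior recovered

    def test_large_break_stays_open(self):
        outline = self._square_outline(break_cols=tuple(range(10, 20)))
        filled = fill_gaps_and_holes(BinaryImage(outline), max_gap=3)
        assert filled.mask.sum() < 200  # no interior fill


class TestTypes:
    def test_gray_image_validates_range_and_scale(self):
        with pytest.raises(ValueError):
            GrayImage(np.full((4, 4), 300))
        with pytest.raises(ValueError):
            GrayImage(np.zeros((4, 4), np.uint8), scale=0)

    def test_binary_image_requires_boolean_values(self):
        with pytest.raises(ValueError):
            BinaryImage(np.full((3, 3), 2))

    def test_region_bbox_contains_centroid(self):
        m = np.zeros((12, 12), bool)
        m[3:7, 4:9] = True
        (r,) = label_regions(BinaryImage(m))
        r0, c0, r1, c1 = r.bbox
        assert r0 <= r.centroid[0] < r1 and c0 <= r.centroid[1] < c1
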