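"""Skeletonization, tagging/labelling and branch-graph dissection."""

import math

import numpy as np
import pytest

from mitonetquant import BinaryMask
from mitonetquant.skeleton import (
    ContractViolation,
    Tag,
    build_graph,
    skeletonize,
    tag_and_label,
)

from _oracles import graph_counts_oracle, random_stroke_mask, tag_oracle
from conftest import mask

SQRT2 = math.sqrt(2.0)


def analyze(px, pixel_size_um=1.0):
    sk = skeletonize(mask(px, pixel_size_um))
    tagged = tag_and_label(sk)
    return tagged, build_graph(tagged)


class TestSkeletonize:
    def test_ribbon_reduces_to_centerline(self):
        m = np.zeros((9, 27), dtype=bool)
        m[3:6, 3:24] = True  # 3x21 horizontal bar
        sk = skeletonize(mask(m)).pixels
        assert sk.sum() <= 21
        rows = np.unique(np.argwhere(sk)[:, 0])
        assert len(rows) == 1  # a single 1-px line

    def test_annulus_keeps_one_loop(self, annulus):
        tagged, graph = analyze(annulus)
        assert tagged.n_objects == 1
        assert graph.endpoint_count == 0
        assert graph.junction_count == 0
        assert len(graph.branches) == 1
        (branch,) = graph.branches
        assert branch.node_a == branch.node_b  # a self-edge: one closed loop

    def test_idempotent_on_thin_curve(self, diagonal_11):
        once = skeletonize(mask(diagonal_11)).pixels
        assert (once == diagonal_11).all()

    def test_empty_mask_gives_empty_skeleton(self):
        sk = skeletonize(mask(np.zeros((10, 10), dtype=bool)))
        assert not sk.pixels.any()

    def test_output_has_no_reducible_thick_block(self):
        # a fully foreground 2x2 block may only survive when all four pixels
        # are topologically essential (an irreducible crossing)
        from mitonetquant.skeleton import _has_reducible_block

        rng = np.random.default_rng(42)
        for _ in range(25):
            sk = skeletonize(mask(random_stroke_mask(rng))).pixels
            assert not _has_reducible_block(sk)

    def test_preserves_component_count(self):
        from scipy import ndimage

        rng = np.random.default_rng(7)
        s8 = np.ones((3, 3), dtype=bool)
        for _ in range(25):
            m = random_stroke_mask(rng)
            sk = skeletonize(mask(m)).pixels
            assert ndimage.label(m, structure=s8)[1] == ndimage.label(sk, structure=s8)[1]


class TestTagAndLabel:
    def test_plus_cross_tags(self, plus_cross):
        tagged = tag_and_label(skeletonize(mask(plus_cross)))
        assert tagged.n_objects == 1
        assert (tagged.tags == Tag.ENDPOINT).sum() == 4
        assert tagged.tags[10, 10] == Tag.JUNCTION

    def test_two_disjoint_segments(self):
        m = np.zeros((20, 20), dtype=bool)
        m[3, 2:13] = True
        m[10, 2:13] = True
        tagged = tag_and_label(mask(m))
        assert tagged.n_objects == 2
        assert (tagged.tags == Tag.ENDPOINT).sum() == 4
        assert (tagged.tags == Tag.JUNCTION).sum() == 0

    def test_tags_match_brute_force_neighbor_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            sk = skeletonize(mask(random_stroke_mask(rng)))
            tagged = tag_and_label(sk)
            assert (tagged.tags == tag_oracle(sk.pixels)).all()

    def test_labels_follow_raster_order(self):
        m = np.zeros((20, 20), dtype=bool)
        m[15, 1:6] = True  # later in raster order
        m[2, 10:15] = True  # first pixel encountered first
        tagged = tag_and_label(mask(m))
        assert tagged.labels[2, 10] == 1
        assert tagged.labels[15, 1] == 2

    def test_non_thin_input_rejected(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ContractViolation):
            tag_and_label(mask(m))


class TestBuildGraph:
    def test_plus_cross_geometry(self, plus_cross):
        tagged, graph = analyze(plus_cross, pixel_size_um=2.0)
        assert graph.junction_count == 1
        assert graph.endpoint_count == 4
        assert len(graph.branches) == 4
        for b in graph.branches:
            assert b.length_um == pytest.approx(10 * 2.0)

    def test_h_shape_topology(self, h_shape):
        tagged, graph = analyze(h_shape)
        assert tagged.n_objects == 1
        assert graph.junction_count == 2
        assert graph.endpoint_count == 4
        assert len(graph.branches) == 5

    def test_diagonal_metric(self, diagonal_11):
        _, graph = analyze(diagonal_11, pixel_size_um=0.5)
        (branch,) = graph.branches
        assert branch.length_um == pytest.approx(10 * SQRT2 * 0.5)

    def test_isolated_pixel_is_degenerate_object(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 5] = True
        tagged, graph = analyze(m)
        assert tagged.n_objects == 1
        assert len(graph.nodes) == 1
        assert len(graph.branches) == 0

    def test_counts_match_brute_force_graph_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            sk = skeletonize(mask(random_stroke_mask(rng)))
            tagged = tag_and_label(sk)
            graph = build_graph(tagged)
            n_obj, n_junc, n_end, n_branch = graph_counts_oracle(sk.pixels)
            assert tagged.n_objects == n_obj
            assert graph.junction_count == n_junc
            assert graph.endpoint_count == n_end
            assert len(graph.branches) == n_branch

    def test_branch_paths_cover_slab_pixels_once(self, h_shape):
        tagged, graph = analyze(h_shape)
        slab_pixels = set(map(tuple, np.argwhere(tagged.tags == Tag.SLAB)))
        seen = []
        node_px = {p for n in graph.nodes for p in n.pixels}
        for b in graph.branches:
            seen.extend(p for p in b.path if tuple(p) in slab_pixels and p not in node_px)
        assert sorted(seen) == sorted(slab_pixels - node_px)
        assert len(seen) == len(set(seen))

    def test_total_length_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sk = skeletonize(mask(random_stroke_mask(rng)))
            graph = build_graph(tag_and_label(sk))
            n_px = int(sk.pixels.sum())
            # isotropy bound on the step metric: interior path pixels are
            # distinct, termini may be shared (at most twice per branch)
            step_total = sum(
                np.hypot(r1 - r0, c1 - c0)
                for b in graph.branches
                for (r0, c0), (r1, c1) in zip(b.path, b.path[1:])
            )
            assert step_total <= (n_px + 2 * len(graph.branches)) * SQRT2


class TestInvariances:
    def test_counts_invariant_under_dihedral_transforms(self):
        rng = np.random.default_rng(13)
        m = random_stroke_mask(rng, size=28)
        ref = None
        for transform in (
            lambda a: a,
            np.rot90,
            lambda a: np.rot90(a, 2),
            lambda a: np.rot90(a, 3),
            np.flipud,
            np.fliplr,
        ):
            tagged, graph = analyze(np.ascontiguousarray(transform(m)))
            counts = (
                tagged.n_objects,
                graph.junction_count,
                graph.endpoint_count,
                len(graph.branches),
                round(graph.total_length_um, 9),
            )
            if ref is None:
                ref = counts
            assert counts == ref
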