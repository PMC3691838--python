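import math

import numpy as np
import pytest

from snpquant import build_graph, skeletonize
from snpquant.segmentation import FiberMask, SegmentationConfig
from snpquant.skeleton_graph import BORDER_BAND_PX

from conftest import make_y_skeleton


def test_empty_mask_empty_skeleton():
    skel = skeletonize(np.zeros((32, 32), dtype=bool))
    assert not skel.any()
    g = build_graph(skel)
    assert g.n_components == 0
    assert g.n_edges == 0


def test_wide_bar_thins_to_line():
    mask = np.zeros((21, 60), dtype=bool)
    mask[9:12, :] = True  # 3-px-wide bar spanning the image
    skel = skeletonize(mask)
    rows = {int(r) for r, c in np.argwhere(skel)}
    assert rows == {10}
    # one pixel wide: no 2x2 block fully set
    s = skel.astype(int)
    assert (s[:-1, :-1] + s[1:, :-1] + s[:-1, 1:] + s[1:, 1:]).max() < 4


def test_skeleton_preserves_component_count(default_truth_mask):
    from skimage.measure import label

    skel = skeletonize(default_truth_mask)
    assert label(skel, connectivity=2).max() == label(default_truth_mask, connectivity=2).max()


def test_straight_line_length():
    skel = np.zeros((21, 120), dtype=bool)
    skel[10, 10:110] = True  # 100 px => 99 orthogonal steps
    g = build_graph(skel, pixel_size_um=1.0)
    assert g.n_edges == 1
    assert g.count_kind("endpoint") == 2
    assert g.total_length_um == pytest.approx(99.0)


def test_diagonal_line_length():
    skel = np.zeros((120, 120), dtype=bool)
    for i in range(100):
        skel[10 + i, 10 + i] = True
    g = build_graph(skel, pixel_size_um=1.0)
    assert g.n_edges == 1
    assert g.total_length_um == pytest.approx(99.0 * math.sqrt(2.0))


def test_y_topology():
    g = build_graph(make_y_skeleton(), pixel_size_um=1.0)
    assert g.n_branch == 1
    assert g.count_kind("endpoint") == 3
    assert g.n_edges == 3
    assert g.n_components == 1


def test_border_nodes_classified():
    skel = np.zeros((40, 40), dtype=bool)
    skel[20, :] = True  # spans the image left to right
    g = build_graph(skel, pixel_size_um=1.0)
    assert g.n_border == 2
    assert g.count_kind("endpoint") == 0


def test_border_band_width():
    skel = np.zeros((40, 40), dtype=bool)
    skel[20, BORDER_BAND_PX - 1 : 30] = True  # tip retracted but inside the band
    g = build_graph(skel, pixel_size_um=1.0)
    kinds = sorted(n.kind for n in g.nodes.values())
    assert kinds == ["border", "endpoint"]


def test_isolated_ring_gets_anchor():
    skel = np.zeros((32, 32), dtype=bool)
    # an 8-pixel diamond ring (all degree 2)
    for dr, dc in [(-2, 0), (-1, 1), (0, 2), (1, 1), (2, 0), (1, -1), (0, -2), (-1, -1)]:
        skel[16 + dr, 16 + dc] = True
    g = build_graph(skel, pixel_size_um=1.0)
    assert g.count_kind("anchor") == 1
    assert g.n_edges == 1
    (e,) = g.edges
    assert e.u == e.v  # closed loop


def test_pixel_conservation(default_truth_mask):
    skel = skeletonize(default_truth_mask)
    g = build_graph(skel, pixel_size_um=400.0 / 384.0, prune_um=0.0)
    assert g.node_pixel_count() + g.chain_pixel_count() == int(skel.sum())


def test_handshake(default_truth_mask):
    skel = skeletonize(default_truth_mask)
    g = build_graph(skel, pixel_size_um=400.0 / 384.0, prune_um=0.0)
    nxg = g.to_networkx()
    assert sum(d for _, d in nxg.degree()) == 2 * g.n_edges


def test_edge_length_bounds(default_truth_mask):
    px = 400.0 / 384.0
    skel = skeletonize(default_truth_mask)
    g = build_graph(skel, pixel_size_um=px, prune_um=0.0)
    for e in g.edges:
        steps = len(e.chain) + 1  # chain pixels exclude node pixels
        assert e.length_um <= math.sqrt(2.0) * px * (steps + 1) + 1e-9


def test_spur_pruning():
    skel = np.zeros((50, 50), dtype=bool)
    c = 25
    skel[c : c + 15, c] = True          # stem, 15 px down
    for i in range(15):
        skel[c - i, c - i] = True       # long arm up-left
    for i in range(1, 4):
        skel[c - i, c + i] = True       # 3-px spur up-right
    g_keep = build_graph(skel, pixel_size_um=1.0, prune_um=0.0)
    g_pruned = build_graph(skel, pixel_size_um=1.0, prune_um=5.0)
    assert g_keep.n_branch == 1 and g_keep.n_edges == 3
    assert g_pruned.n_branch == 0 and g_pruned.n_edges == 1


def test_skeleton_within_dilated_mask(default_truth_mask):
    from scipy.ndimage import binary_dilation

    skel = skeletonize(default_truth_mask)
    assert not (skel & ~binary_dilation(default_truth_mask, iterations=1)).any()
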