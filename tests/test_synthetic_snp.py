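import numpy as np
import pytest

from snpquant import generate_scene, render_image, truth_metrics
from snpquant.synthetic_snp import NoiseParams, truth_mask


def test_empty_scene_all_zero_metrics():
    scene = generate_scene(n_trees=0, seed=0)
    m = truth_metrics(scene)
    assert all(v == 0 for k, v in m.as_dict().items() if k != "area_mm2")


def test_single_straight_fibre_topology():
    scene = generate_scene(n_trees=1, branch_prob=0.0, tortuosity=0.0, seed=3)
    g = scene.truth_graph
    assert len(g.edges) == 1
    assert g.n_branch == 0
    kinds = sorted(n.kind for n in g.nodes.values())
    assert all(k in ("border", "endpoint") for k in kinds)
    assert len(kinds) == 2


def test_truth_length_equals_polyline_sum(default_scene):
    by_hand = sum(
        float(np.linalg.norm(np.diff(f.centerline, axis=0), axis=1).sum())
        for f in default_scene.fibers
    )
    assert default_scene.total_length_um == pytest.approx(by_hand, rel=1e-12)


def test_truth_nfd_identity(default_scene):
    m = truth_metrics(default_scene)
    assert m.nerve_fibre_density_mm_per_mm2 * m.area_mm2 == pytest.approx(
        m.total_fibre_length_um / 1000.0, rel=1e-12
    )


def test_fibers_match_truth_edges(default_scene):
    assert len(default_scene.fibers) == len(default_scene.truth_graph.edges)


def test_centerlines_inside_extent(default_scene):
    for f in default_scene.fibers:
        assert f.centerline.min() >= 0.0
        assert f.centerline.max() <= default_scene.extent_um


def test_centerline_point_spacing_below_one_pixel(default_scene):
    pixel_um = default_scene.extent_um / 384.0
    for f in default_scene.fibers:
        steps = np.linalg.norm(np.diff(f.centerline, axis=0), axis=1)
        assert steps.max() <= 1.0 + 1e-9  # 1 um step < 1.0417 um pixel


def test_scene_determinism():
    a = generate_scene(seed=11)
    b = generate_scene(seed=11)
    assert len(a.fibers) == len(b.fibers)
    for fa, fb in zip(a.fibers, b.fibers):
        assert np.array_equal(fa.centerline, fb.centerline)
    assert np.array_equal(render_image(a).intensities, render_image(b).intensities)


def test_different_seeds_differ():
    a = generate_scene(seed=1)
    b = generate_scene(seed=2)
    assert a.total_length_um != b.total_length_um


def test_render_determinism(default_scene):
    r1 = render_image(default_scene)
    r2 = render_image(default_scene)
    assert np.array_equal(r1.intensities, r2.intensities)


def test_empty_scene_zero_noise_uniform_background():
    scene = generate_scene(n_trees=0, seed=0, noise=NoiseParams(
        background=0.2, additive_sigma=0.0, speckle_sigma=0.0, blur_sigma_px=0.0))
    img = render_image(scene)
    assert np.allclose(img.intensities, 0.2)


def test_bright_pixels_near_centerline():
    scene = generate_scene(n_trees=1, branch_prob=0.0, tortuosity=0.0, seed=3,
                           noise=NoiseParams(background=0.0, additive_sigma=0.0,
                                             speckle_sigma=0.0, blur_sigma_px=0.0))
    img = render_image(scene)
    (f,) = scene.fibers
    px = scene.extent_um / img.shape[0]
    bright = np.argwhere(img.intensities > 0.5 * f.peak_intensity)
    pts = (bright + 0.5) * px
    d = np.min(
        np.linalg.norm(pts[:, None, :] - f.centerline[None, :, :], axis=2), axis=1
    )
    assert d.max() <= f.width_um / 2.0 + px


def test_truth_mask_covers_skeleton(default_scene, default_truth_mask):
    m = truth_metrics(default_scene)
    assert m.skeleton_pixels <= m.component_pixels
    assert m.component_pixels == int(default_truth_mask.sum())


@pytest.mark.parametrize("kwargs", [
    {"branch_prob": -0.1},
    {"branch_prob": 1.5},
    {"extent_um": -1.0},
    {"n_trees": -1},
])
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        generate_scene(seed=0, **kwargs)


def test_no_close_approach_between_distinct_fibres(default_scene):
    """Separation rule: distinct fibres never run closer than one fibre width,
    except where they meet at a shared graph node."""
    from scipy.spatial import cKDTree

    g = default_scene.truth_graph
    fibres = default_scene.fibers
    edges = g.edges
    for i in range(len(fibres)):
        tree = cKDTree(fibres[i].centerline)
        for j in range(i + 1, len(fibres)):
            d, idx = tree.query(fibres[j].centerline)
            shared = {edges[i].u, edges[i].v} & {edges[j].u, edges[j].v}
            if not shared:
                assert d.min() > 2.2  # > one fibre width apart
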