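import numpy as np
import pytest

from snpquant import (
    ConfocalImage,
    QuantifyConfig,
    SegmentationConfig,
    build_graph,
    compute_metrics,
    normalize_per_mm2,
    quantify_image,
    skeletonize,
)
from snpquant.segmentation import FiberMask
from snpquant.snp_metrics import METRIC_COLUMNS, SNPMetrics, nerve_fibre_density

from conftest import make_y_skeleton


def test_worked_example_nfd():
    # 1578 um of fibre in a 400 x 400 um field.
    nfd = nerve_fibre_density(1578.0, 0.16)
    assert round(nfd, 3) == 9.863


def test_empty_inputs_zero_metrics():
    mask = FiberMask(np.zeros((64, 64), dtype=bool), 64.0, 64.0)
    g = build_graph(np.zeros((64, 64), dtype=bool))
    m = compute_metrics(mask, g)
    assert all(v == 0 for k, v in m.as_dict().items() if k != "area_mm2")


def test_y_scene_counts():
    skel = make_y_skeleton()
    mask = FiberMask(skel, float(skel.shape[1]), float(skel.shape[0]))
    g = build_graph(skel, pixel_size_um=1.0)
    m = compute_metrics(mask, g)
    assert m.single_nerve_fibres == 3
    assert m.branches == 1
    assert m.nerve_fibre_components == 1


def test_normalize_scales_counts():
    m = SNPMetrics(single_nerve_fibres=19.0, total_fibre_length_um=1578.0,
                   nerve_fibre_density_mm_per_mm2=9.8625, area_mm2=0.16)
    n = normalize_per_mm2(m)
    assert n.single_nerve_fibres == pytest.approx(118.75)
    assert n.normalised
    # intensive quantities unchanged
    assert n.nerve_fibre_density_mm_per_mm2 == m.nerve_fibre_density_mm_per_mm2
    assert n.average_single_fibre_length_um == m.average_single_fibre_length_um


def test_normalize_unit_area_identity():
    m = SNPMetrics(single_nerve_fibres=10.0, area_mm2=1.0)
    n = normalize_per_mm2(m)
    assert n.single_nerve_fibres == 10.0


def test_double_normalization_rejected():
    m = normalize_per_mm2(SNPMetrics(area_mm2=0.16))
    with pytest.raises(ValueError):
        normalize_per_mm2(m)


def test_normalization_linear_in_area():
    a = SNPMetrics(component_pixels=800.0, total_fibre_length_um=400.0, area_mm2=0.2)
    b = SNPMetrics(component_pixels=800.0, total_fibre_length_um=400.0, area_mm2=0.4)
    na, nb = normalize_per_mm2(a), normalize_per_mm2(b)
    assert na.component_pixels == pytest.approx(2 * nb.component_pixels)


def test_nfd_identity_exact(default_truth_mask):
    mask = FiberMask(default_truth_mask, 400.0, 400.0)
    skel = skeletonize(default_truth_mask)
    g = build_graph(skel, pixel_size_um=mask.pixel_size_um)
    m = compute_metrics(mask, g)
    assert m.nerve_fibre_density_mm_per_mm2 == pytest.approx(
        (m.total_fibre_length_um / 1000.0) / m.area_mm2, rel=1e-12
    )


def test_length_per_skeleton_pixel_bounds(default_truth_mask):
    mask = FiberMask(default_truth_mask, 400.0, 400.0)
    skel = skeletonize(default_truth_mask)
    g = build_graph(skel, pixel_size_um=mask.pixel_size_um, prune_um=0.0)
    m = compute_metrics(mask, g)
    ratio = m.total_fibre_length_um / m.skeleton_pixels
    px = mask.pixel_size_um
    assert px * (1 - 1e-9) <= ratio <= np.sqrt(2.0) * px * (1 + 1e-9)


def test_skeleton_not_larger_than_mask(default_truth_mask):
    mask = FiberMask(default_truth_mask, 400.0, 400.0)
    skel = skeletonize(default_truth_mask)
    g = build_graph(skel, pixel_size_um=mask.pixel_size_um)
    m = compute_metrics(mask, g)
    assert m.skeleton_pixels <= m.component_pixels


def test_quantify_blank_image():
    img = ConfocalImage(np.zeros((64, 64)), 64.0, 64.0)
    with pytest.warns(UserWarning):
        m = quantify_image(img, QuantifyConfig())
    assert m.total_fibre_length_um == 0.0


def test_quantify_accepts_mask_input(default_truth_mask):
    fm = FiberMask(default_truth_mask, 400.0, 400.0)
    m = quantify_image(fm, QuantifyConfig(prune_um=0.0))
    assert m.component_pixels == int(default_truth_mask.sum())


def test_rounded_three_decimals():
    m = SNPMetrics(total_fibre_length_um=1234.56789, area_mm2=0.16,
                   nerve_fibre_density_mm_per_mm2=9.8625)
    r = m.rounded()
    assert r.total_fibre_length_um == 1234.568
    assert r.nerve_fibre_density_mm_per_mm2 == 9.863


def test_metric_columns_cover_nine_parameters():
    assert len(METRIC_COLUMNS) == 9
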