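"""The nine morphometric parameters of the subbasal nerve plexus.

Raw per-image values are computed from the fibre mask and the medial-axis
graph; an optional normalisation scales the extensive quantities (counts and
total length) to a reference area of 1 mm².  Nerve fibre density is defined
as total fibre length per area (mm/mm²) and therefore holds the identity
``density = (total_length_um / 1000) / area_mm2`` exactly on every output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict, field

import numpy as np

from ._round import round_half_away
from .image import ConfocalImage
from .segmentation import FiberMask, SegmentationConfig, segment
from .skeleton_graph import SkeletonGraph, skeletonize, build_graph

__all__ = [
    "SNPMetrics",
    "METRIC_COLUMNS",
    "nerve_fibre_density",
    "compute_metrics",
    "normalize_per_mm2",
    "QuantifyConfig",
    "quantify_image",
]

#: Canonical column order for delimited-text output.
METRIC_COLUMNS = (
    "component_pixels",
    "nerve_fibre_components",
    "skeleton_pixels",
    "single_nerve_fibres",
    "total_fibre_length_um",
    "average_single_fibre_length_um",
    "nerve_fibre_density_mm_per_mm2",
    "connectivity_points",
    "branches",
)


@dataclass(frozen=True)
class SNPMetrics:
    """Morphometric parameters of one image (raw) or per 1 mm² (normalised).

    Counts are stored as floats so that area normalisation keeps exact
    fractional values; ``rounded`` renders the reporting convention
    (lengths and densities to 3 decimals, half away from zero).
    """

    component_pixels: float = 0.0
    nerve_fibre_components: float = 0.0
    skeleton_pixels: float = 0.0
    single_nerve_fibres: float = 0.0
    total_fibre_length_um: float = 0.0
    average_single_fibre_length_um: float = 0.0
    nerve_fibre_density_mm_per_mm2: float = 0.0
    connectivity_points: float = 0.0
    branches: float = 0.0
    area_mm2: float = 0.16
    normalised: bool = False

    def rounded(self) -> "SNPMetrics":
        """Lengths/densities rounded to 3 decimals (half away from zero)."""
        return replace(
            self,
            total_fibre_length_um=round_half_away(self.total_fibre_length_um, 3),
            average_single_fibre_length_um=round_half_away(self.average_single_fibre_length_um, 3),
            nerve_fibre_density_mm_per_mm2=round_half_away(self.nerve_fibre_density_mm_per_mm2, 3),
        )

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        return d


def nerve_fibre_density(total_length_um: float, area_mm2: float) -> float:
    """Nerve fibre density in mm/mm²: total fibre length per image area."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return (total_length_um / 1000.0) / area_mm2


def compute_metrics(mask: FiberMask, graph: SkeletonGraph) -> SNPMetrics:
    """Assemble the nine parameters from a fibre mask and its medial-axis graph.

    - component pixels: true pixels of the mask;
    - nerve fibre components: connected subnetworks of the graph;
    - skeleton pixels: medial-axis pixels (node pixels plus chain pixels);
    - single nerve fibres: graph edges, i.e. nerve segments between
      topological events (branch points and fibre ends);
    - total/average fibre length: chain-code edge lengths;
    - nerve fibre density: total length per area;
    - connectivity points: fibres entering or leaving the image area
      (border nodes);
    - branches: branch nodes (merged junction clusters).
    """
    total_len = graph.total_length_um
    n_fibres = graph.n_edges
    return SNPMetrics(
        component_pixels=float(mask.component_pixel_count),
        nerve_fibre_components=float(graph.n_components),
        skeleton_pixels=float(graph.node_pixel_count() + graph.chain_pixel_count()),
        single_nerve_fibres=float(n_fibres),
        total_fibre_length_um=total_len,
        average_single_fibre_length_um=total_len / n_fibres if n_fibres else 0.0,
        nerve_fibre_density_mm_per_mm2=nerve_fibre_density(total_len, mask.area_mm2),
        connectivity_points=float(graph.n_border),
        branches=float(graph.n_branch),
        area_mm2=mask.area_mm2,
        normalised=False,
    )


def normalize_per_mm2(metrics: SNPMetrics) -> SNPMetrics:
    """Scale extensive quantities to a reference area of 1 mm².

    Counts and total length are multiplied by ``1 / area_mm2``; density and
    average single-fibre length are intensive and stay unchanged.
    """
    if metrics.normalised:
        raise ValueError("metrics are already normalised")
    if metrics.area_mm2 <= 0:
        raise ValueError("area must be positive")
    f = 1.0 / metrics.area_mm2
    return replace(
        metrics,
        component_pixels=metrics.component_pixels * f,
        nerve_fibre_components=metrics.nerve_fibre_components * f,
        skeleton_pixels=metrics.skeleton_pixels * f,
        single_nerve_fibres=metrics.single_nerve_fibres * f,
        total_fibre_length_um=metrics.total_fibre_length_um * f,
        connectivity_points=metrics.connectivity_points * f,
        branches=metrics.branches * f,
        normalised=True,
    )


@dataclass(frozen=True)
class QuantifyConfig:
    """End-to-end pipeline parameters.

    ``prune_um`` removes skeleton spurs shorter than that physical length
    (set 0 to disable); ``normalise`` reports per-mm² values.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    prune_um: float = 5.0
    normalise: bool = False


def quantify_image(
    source: ConfocalImage | FiberMask,
    config: QuantifyConfig | None = None,
) -> SNPMetrics:
    """Full quantification pipeline for one frame.

    ``source`` may be a grayscale frame (segmented first) or an existing
    binary :class:`FiberMask` (segmentation skipped).  The mask is thinned
    to its medial axis, the axis converted into the topological graph, and
    the nine parameters assembled; deterministic for fixed input and config.
    """
    config = config or QuantifyConfig()
    if isinstance(source, FiberMask):
        mask = source
    else:
        mask = segment(source, config.segmentation)
    skel = skeletonize(mask.mask)
    graph = build_graph(skel, pixel_size_um=mask.pixel_size_um, prune_um=config.prune_um)
    metrics = compute_metrics(mask, graph)
    if config.normalise:
        metrics = normalize_per_mm2(metrics)
    return metrics
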