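"""Synthetic subbasal-nerve scenes with exact ground-truth geometry.

The generator grows each nerve "tree" as a smoothed random walk that enters
the field at one border and propagates with bounded curvature, spawning
side branches stochastically — emulating the hyperreflective, regularly
tortuous, branching fibres seen in confocal frames of the subbasal plexus.
Every scene stores its generative topology as a ground-truth medial-axis
graph, so segmentation and graph extraction can be validated against exact
component, branch, fibre and border-crossing counts and analytic lengths.

Coordinates are micrometres in (y, x) order, matching (row, col) pixel
order; the pixel centre of (r, c) is ((r + 0.5) * s, (c + 0.5) * s) for
pixel size s.  Fibres of distinct trees never approach each other closer
than a separation margin (unless ``allow_overlap``), because overlapping
trees make component and branch counts ill-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import ConfocalImage, DEFAULT_EXTENT_UM, DEFAULT_PIXELS
from .skeleton_graph import SkeletonGraph, SkeletonNode, SkeletonEdge, skeletonize
from .snp_metrics import SNPMetrics, nerve_fibre_density

__all__ = [
    "NoiseParams",
    "FiberTruth",
    "SceneTruth",
    "generate_scene",
    "render_image",
    "truth_mask",
    "truth_metrics",
]

# Geometry guards (um): walkers may not terminate inside this distance of
# the border (a truth endpoint there would be indistinguishable from a
# border crossing), and truth spurs shorter than _MIN_EDGE_UM are dissolved.
_BORDER_MARGIN_UM = 10.0
_MIN_EDGE_UM = 12.0
_BRANCH_REFRACTORY_STEPS = 15
# Walkers leave a junction (or the border) on a straight course for this many
# steps so that sibling fibres diverge cleanly before curvature resumes.
_STRAIGHT_STEPS = 12
# The junction-vicinity exclusion from the self-separation test only applies
# while the walker is still departing its spawn point; afterwards any return
# toward laid fibres terminates the walker like elsewhere in the field.  The
# exclusion covers only the parent's points laid contiguously around the
# junction (an index window in the laid-point buffer), never unrelated fibre
# points that merely lie near the junction geometrically.
_SPAWN_BALL_STEPS = 25
_SPAWN_WINDOW = 13
_RENDER_OVERSHOOT_UM = 3.0


@dataclass(frozen=True)
class NoiseParams:
    """Rendering noise model: I = clip(blur(bg + fibres) * speckle + additive)."""

    background: float = 0.15
    additive_sigma: float = 0.05
    speckle_sigma: float = 0.2
    blur_sigma_px: float = 0.8


@dataclass(frozen=True)
class FiberTruth:
    """One single nerve fibre: the centerline between two topological events.

    ``centerline`` is an (n, 2) array of (y, x) points in um, sub-pixel
    spaced; ``render_centerline`` may extend a few um beyond the field
    border so that rasterised border crossings reach the outermost pixel
    row/column.
    """

    centerline: np.ndarray
    width_um: float = 2.0
    peak_intensity: float = 0.8
    render_centerline: np.ndarray | None = None

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 2 or cl.shape[1] != 2:
            raise ValueError("centerline must be an (n>=2, 2) array")
        if self.width_um <= 0:
            raise ValueError("width must be positive")
        object.__setattr__(self, "centerline", cl)
        rc = self.render_centerline
        object.__setattr__(
            self, "render_centerline", cl if rc is None else np.asarray(rc, dtype=float)
        )

    @property
    def length_um(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))


@dataclass(frozen=True)
class SceneTruth:
    """A generated scene: fibres, their exact topology, and rendering params.

    ``truth_graph`` edges correspond 1:1 (same order) to ``fibers``.
    """

    fibers: tuple[FiberTruth, ...]
    truth_graph: SkeletonGraph
    extent_um: float
    seed: int
    noise: NoiseParams = field(default_factory=NoiseParams)

    @property
    def total_length_um(self) -> float:
        return float(sum(f.length_um for f in self.fibers))

    @property
    def area_mm2(self) -> float:
        return (self.extent_um / 1000.0) ** 2


# ---------------------------------------------------------------------------
# generation


class _Walker:
    __slots__ = ("pos", "heading", "start_node", "segment", "steps_since_event")

    def __init__(self, pos, heading, start_node):
        self.pos = np.asarray(pos, dtype=float)
        self.heading = float(heading)
        self.start_node = start_node
        self.segment = [self.pos.copy()]
        self.steps_since_event = 0


def generate_scene(
    n_trees: int = 8,
    branch_prob: float = 0.02,
    tortuosity: float = 0.12,
    extent_um: float = DEFAULT_EXTENT_UM,
    seed: int = 0,
    *,
    width_um: float = 2.1,
    peak_range: tuple[float, float] = (0.6, 1.0),
    step_um: float = 1.0,
    stop_prob: float = 0.003,
    max_walkers_per_tree: int = 4,
    noise: NoiseParams | None = None,
    allow_overlap: bool = False,
    min_separation_um: float = 8.0,
) -> SceneTruth:
    """Grow a random scene of branching nerve trees with exact topology.

    Each tree enters at a uniformly chosen border point heading inward and
    performs a smoothed random walk (per-step heading jitter of standard
    deviation ``tortuosity`` radians, clamped to bounded curvature).  At
    each step a side branch spawns with probability ``branch_prob`` (up to
    ``max_walkers_per_tree`` walkers per tree, with a refractory distance
    after every junction).  Walkers end by leaving the field (a border
    crossing), by random termination, or on approaching another fibre
    closer than ``min_separation_um``.  Deterministic for a fixed seed.
    """
    if not 0.0 <= branch_prob <= 1.0:
        raise ValueError("branch_prob must lie in [0, 1]")
    if extent_um <= 0:
        raise ValueError("extent must be positive")
    if n_trees < 0:
        raise ValueError("n_trees must be >= 0")
    rng = np.random.default_rng(seed)
    noise = noise or NoiseParams()

    nodes: list[dict] = []  # {"pos": (y,x), "kind": str}
    edges: list[dict] = []  # {"u","v","points","tree"}
    tree_arrays: list[np.ndarray] = []  # laid points per completed tree

    def new_node(pos, kind) -> int:
        nodes.append({"pos": np.asarray(pos, dtype=float), "kind": kind})
        return len(nodes) - 1

    sep2_other = min_separation_um**2
    sep2_own = (0.75 * min_separation_um) ** 2

    own_buf = np.empty((256, 2))
    n_own = 0

    def push_own(pt: np.ndarray) -> None:
        nonlocal own_buf, n_own
        if n_own == len(own_buf):
            own_buf = np.vstack([own_buf, np.empty_like(own_buf)])
        own_buf[n_own] = pt
        n_own += 1

    def too_close(
        pt: np.ndarray,
        spawn_idx: int | None,
        walker_start: int,
        walker_steps: int,
        ignore_recent: int = 15,
    ) -> bool:
        if allow_overlap:
            return False
        if other_arr is not None and np.min(np.sum((other_arr - pt) ** 2, axis=1)) < sep2_other:
            return True
        # Own tree: ignore only the current walker's recent trail (never the
        # tail of a previously finished sibling walker).
        n_older = max(walker_start, n_own - ignore_recent)
        if n_older == 0:
            return False
        d2 = np.sum((own_buf[:n_older] - pt) ** 2, axis=1)
        if spawn_idx is not None and walker_steps <= _SPAWN_BALL_STEPS:
            # While departing its junction, the walker ignores the parent's
            # points laid contiguously around the spawn (and only those).
            lo = max(0, spawn_idx - _SPAWN_WINDOW)
            hi = min(n_older, spawn_idx + _SPAWN_WINDOW + 1)
            if hi > lo:
                d2[lo:hi] = np.inf
        return bool(len(d2)) and float(d2.min()) < sep2_own

    for current_tree in range(n_trees):
        other_arr = np.vstack(tree_arrays) if tree_arrays else None
        entry = _sample_entry(rng, extent_um, other_arr, min_separation_um, allow_overlap)
        if entry is None:
            continue
        pos, heading = entry
        root_node = new_node(pos, "border")
        queue = [_Walker(pos, heading, root_node)]
        walkers_spawned = 1
        n_own = 0
        push_own(np.asarray(pos, dtype=float))
        spawn_of_walker = {0: 0}  # buffer index of each walker's spawn point
        w_idx = 0
        while w_idx < len(queue):
            w = queue[w_idx]
            spawn_idx = spawn_of_walker.get(w_idx)
            walker_start = n_own
            walker_steps = 0
            for _ in range(2000):
                if w.steps_since_event < _STRAIGHT_STEPS:
                    turn = 0.0
                else:
                    turn = float(np.clip(rng.normal(0.0, tortuosity), -0.35, 0.35))
                w.heading += turn
                step = np.array([math.sin(w.heading), math.cos(w.heading)]) * step_um
                nxt = w.pos + step
                if not _inside(nxt, extent_um):
                    border_pt = _clip_to_border(w.pos, nxt, extent_um)
                    w.segment.append(border_pt)
                    end = new_node(border_pt, "border")
                    edges.append(
                        {"u": w.start_node, "v": end, "points": list(w.segment), "tree": current_tree}
                    )
                    break
                if too_close(nxt, spawn_idx, walker_start, walker_steps):
                    stopped = _retract_from_border(w.segment, extent_um)
                    if stopped is not None:
                        end = new_node(stopped[-1], "endpoint")
                        edges.append({"u": w.start_node, "v": end, "points": stopped, "tree": current_tree})
                    break
                w.pos = nxt
                w.segment.append(nxt.copy())
                push_own(nxt)
                w.steps_since_event += 1
                walker_steps += 1
                dist_border = _dist_to_border(nxt, extent_um)
                if (
                    rng.random() < stop_prob
                    and dist_border > _BORDER_MARGIN_UM
                    and w.steps_since_event * step_um > _MIN_EDGE_UM
                ):
                    end = new_node(nxt, "endpoint")
                    edges.append({"u": w.start_node, "v": end, "points": list(w.segment), "tree": current_tree})
                    break
                if (
                    rng.random() < branch_prob
                    and walkers_spawned < max_walkers_per_tree
                    and w.steps_since_event > _BRANCH_REFRACTORY_STEPS
                    and dist_border > 1.5 * _BORDER_MARGIN_UM
                ):
                    jnode = new_node(nxt, "branch")
                    edges.append({"u": w.start_node, "v": jnode, "points": list(w.segment), "tree": current_tree})
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    child_heading = w.heading + side * rng.uniform(0.6, 1.1)
                    child = _Walker(nxt, child_heading, jnode)
                    spawn_of_walker[len(queue)] = n_own - 1
                    queue.append(child)
                    walkers_spawned += 1
                    w.start_node = jnode
                    w.segment = [nxt.copy()]
                    w.steps_since_event = 0
            else:  # step budget exhausted: close as endpoint
                end = new_node(w.pos, "endpoint")
                edges.append({"u": w.start_node, "v": end, "points": list(w.segment), "tree": current_tree})
            w_idx += 1
        tree_arrays.append(own_buf[:n_own].copy())

    nodes, edges = _canonicalize(nodes, edges)
    fibers = []
    for e in edges:
        pts = np.asarray(e["points"], dtype=float)
        render = pts
        # Extend border-crossing ends a little beyond the field so that the
        # rasterised stroke solidly reaches the outermost pixel row/column.
        if nodes[e["v"]]["kind"] == "border":
            fwd = pts[-1] - pts[-2]
            fwd = fwd / max(np.linalg.norm(fwd), 1e-9) * _RENDER_OVERSHOOT_UM
            render = np.vstack([render, pts[-1] + fwd])
        if nodes[e["u"]]["kind"] == "border":
            back = pts[0] - pts[1]
            back = back / max(np.linalg.norm(back), 1e-9) * _RENDER_OVERSHOOT_UM
            render = np.vstack([pts[0] + back, render])
        fibers.append(
            FiberTruth(
                centerline=pts,
                width_um=width_um,
                peak_intensity=float(rng.uniform(*peak_range)),
                render_centerline=render,
            )
        )

    graph_nodes = [
        SkeletonNode(id=i, position=tuple(n["pos"]), kind=n["kind"]) for i, n in enumerate(nodes)
    ]
    graph_edges = [
        SkeletonEdge(u=e["u"], v=e["v"], length_um=f.length_um) for e, f in zip(edges, fibers)
    ]
    return SceneTruth(
        fibers=tuple(fibers),
        truth_graph=SkeletonGraph(graph_nodes, graph_edges),
        extent_um=extent_um,
        seed=seed,
        noise=noise,
    )




def _inside(pt: np.ndarray, extent: float) -> bool:
    return 0.0 < pt[0] < extent and 0.0 < pt[1] < extent


def _dist_to_border(pt: np.ndarray, extent: float) -> float:
    return float(min(pt[0], pt[1], extent - pt[0], extent - pt[1]))


def _clip_to_border(p: np.ndarray, q: np.ndarray, extent: float):
    """Intersect segment p->q (p inside, q outside) with the field border."""
    ts = []
    for dim in (0, 1):
        for bound in (0.0, extent):
            denom = q[dim] - p[dim]
            if denom != 0:
                t = (bound - p[dim]) / denom
                if 0.0 <= t <= 1.0:
                    ts.append(t)
    t = min(ts) if ts else 1.0
    return p + t * (q - p)


def _retract_from_border(segment: list[np.ndarray], extent: float):
    """Trim trailing points inside the border margin; None if too little remains."""
    pts = list(segment)
    while pts and _dist_to_border(pts[-1], extent) < _BORDER_MARGIN_UM:
        pts.pop()
    if len(pts) < 2 or _seg_len(pts) < _MIN_EDGE_UM:
        return None
    return pts


def _seg_len(pts) -> float:
    arr = np.asarray(pts)
    return float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)))


def _sample_entry(rng, extent, other_arr, min_sep, allow_overlap):
    """Pick a border entry point clear of existing trees; inward heading."""
    for _ in range(40):
        side = rng.integers(0, 4)
        along = rng.uniform(0.1 * extent, 0.9 * extent)
        # heading convention: step = (sin h, cos h) = (dy, dx)
        if side == 0:
            pos, base = (0.0, along), math.pi / 2  # top row, heading +y
        elif side == 1:
            pos, base = (extent, along), -math.pi / 2  # bottom row, heading -y
        elif side == 2:
            pos, base = (along, 0.0), 0.0  # left column, heading +x
        else:
            pos, base = (along, extent), math.pi  # right column, heading -x
        pt = np.asarray(pos)
        clear = (
            allow_overlap
            or other_arr is None
            or float(np.min(np.sum((other_arr - pt) ** 2, axis=1))) > (2.5 * min_sep) ** 2
        )
        if clear:
            heading = base + rng.uniform(-0.5, 0.5)
            return pt, heading
    return None


def _canonicalize(nodes: list[dict], edges: list[dict]):
    """Remove sub-threshold terminal spurs and dissolve degree-2 junctions.

    The raw walk can leave endpoint edges shorter than the minimum
    resolvable fibre segment (e.g. a child halted immediately by the
    separation rule); such spurs are dropped and any branch node left with
    exactly two incident edges is merged into a single through fibre, so
    the stored topology is the one a perfect medial-axis analysis would
    recover.
    """
    changed = True
    while changed:
        changed = False
        # drop short terminal spurs
        deg: dict[int, int] = {}
        for e in edges:
            deg[e["u"]] = deg.get(e["u"], 0) + 1
            deg[e["v"]] = deg.get(e["v"], 0) + 1
        for i, e in enumerate(edges):
            if _seg_len(e["points"]) >= _MIN_EDGE_UM:
                continue
            u_term = nodes[e["u"]]["kind"] == "endpoint" and deg.get(e["u"], 0) == 1
            v_term = nodes[e["v"]]["kind"] == "endpoint" and deg.get(e["v"], 0) == 1
            if u_term or v_term:
                del edges[i]
                changed = True
                break
        if changed:
            continue
        # dissolve branch nodes of degree 2; demote degree-1 branch nodes
        # (their side fibre died before laying an edge) to endpoints
        incidence: dict[int, list[int]] = {}
        for i, e in enumerate(edges):
            incidence.setdefault(e["u"], []).append(i)
            incidence.setdefault(e["v"], []).append(i)
        for nid, inc in incidence.items():
            if nodes[nid]["kind"] == "branch" and len(inc) == 1:
                nodes[nid]["kind"] = "endpoint"
                changed = True
                break
            if nodes[nid]["kind"] != "branch" or len(inc) != 2 or inc[0] == inc[1]:
                continue
            i1, i2 = inc
            e1, e2 = edges[i1], edges[i2]
            p1 = e1["points"] if e1["v"] == nid else list(reversed(e1["points"]))
            p2 = e2["points"] if e2["u"] == nid else list(reversed(e2["points"]))
            far_u = e1["u"] if e1["v"] == nid else e1["v"]
            far_v = e2["v"] if e2["u"] == nid else e2["u"]
            merged = {"u": far_u, "v": far_v, "points": p1 + p2[1:], "tree": e1["tree"]}
            for i in sorted((i1, i2), reverse=True):
                del edges[i]
            edges.append(merged)
            nodes[nid]["kind"] = "_removed"
            changed = True
            break
    # compact node ids, keeping only referenced nodes
    used = sorted({e["u"] for e in edges} | {e["v"] for e in edges})
    remap = {old: new for new, old in enumerate(used)}
    new_nodes = [nodes[old] for old in used]
    for e in edges:
        e["u"], e["v"] = remap[e["u"]], remap[e["v"]]
    return new_nodes, edges


# ---------------------------------------------------------------------------
# rasterisation


def _distance_fields(scene: SceneTruth, pixels_per_side: int):
    """Per-pixel minimum distance to any fibre centerline, plus max intensity.

    Centerlines are resampled at quarter-pixel spacing and stamped into a
    window of 3 sigma around each sample; taking the per-pixel minimum over
    stamps recovers the distance to the curve to sub-sample accuracy.
    Returns (norm_dist, intensity): ``norm_dist`` is distance divided by the
    local fibre half-width (<= 1 inside a fibre), ``intensity`` the maximal
    Gaussian-profile brightness over fibres.
    """
    n = pixels_per_side
    px = scene.extent_um / n
    norm_dist = np.full((n, n), np.inf)
    intensity = np.zeros((n, n))
    fine = 0.25 * px
    for fib in scene.fibers:
        half = fib.width_um / 2.0
        sigma = half  # Gaussian profile scale of the stroke
        r_px = max(2, int(math.ceil(3.0 * sigma / px)))
        pts = _resample(fib.render_centerline, fine)
        for (y, x) in pts:
            r0 = int(y / px - 0.5)
            c0 = int(x / px - 0.5)
            rr = np.arange(max(0, r0 - r_px), min(n, r0 + r_px + 2))
            cc = np.arange(max(0, c0 - r_px), min(n, c0 + r_px + 2))
            if rr.size == 0 or cc.size == 0:
                continue
            cy = (rr + 0.5) * px
            cx = (cc + 0.5) * px
            d = np.sqrt((cy[:, None] - y) ** 2 + (cx[None, :] - x) ** 2)
            sub = (slice(rr[0], rr[-1] + 1), slice(cc[0], cc[-1] + 1))
            np.minimum(norm_dist[sub], d / half, out=norm_dist[sub])
            np.maximum(
                intensity[sub],
                fib.peak_intensity * np.exp(-0.5 * (d / sigma) ** 2),
                out=intensity[sub],
            )
    return norm_dist, intensity


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at a fixed arc-length spacing (endpoints kept)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1]
    si = np.arange(0.0, total, spacing)
    si = np.append(si, total)
    y = np.interp(si, s, pts[:, 0])
    x = np.interp(si, s, pts[:, 1])
    return np.column_stack([y, x])


def truth_mask(scene: SceneTruth, pixels_per_side: int = DEFAULT_PIXELS) -> np.ndarray:
    """Noiseless binary rasterisation: pixels within half a width of a centerline."""
    norm_dist, _ = _distance_fields(scene, pixels_per_side)
    return norm_dist <= 1.0


def render_image(scene: SceneTruth, pixels_per_side: int = DEFAULT_PIXELS) -> ConfocalImage:
    """Render a scene to a noisy confocal-like frame.

    Fibres are drawn as Gaussian-profile strokes of their width and peak
    intensity over a uniform background; the frame is then blurred and
    corrupted by multiplicative speckle and additive Gaussian noise per the
    scene's noise parameters.  Deterministic for a fixed scene seed.
    """
    if pixels_per_side < 32:
        raise ValueError("pixels_per_side must be >= 32")
    _, intensity = _distance_fields(scene, pixels_per_side)
    p = scene.noise
    img = np.clip(p.background + intensity, 0.0, 1.0)
    if p.blur_sigma_px > 0:
        img = gaussian_filter(img, p.blur_sigma_px)
    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed), 0x5EED]))
    if p.speckle_sigma > 0:
        img = img * (1.0 + p.speckle_sigma * rng.standard_normal(img.shape))
    if p.additive_sigma > 0:
        img = img + p.additive_sigma * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0)
    return ConfocalImage(img, width_um=scene.extent_um, height_um=scene.extent_um)


def truth_metrics(scene: SceneTruth, pixels_per_side: int = DEFAULT_PIXELS) -> SNPMetrics:
    """The nine parameters computed analytically from the ground truth.

    Counts and lengths come from the generative graph (exact); the two
    pixel-count parameters are rasterised counts of the noiseless mask and
    of its thinned medial axis, since "number of pixels" is only defined on
    a grid.
    """
    g = scene.truth_graph
    area = scene.area_mm2
    if not scene.fibers:
        return SNPMetrics(area_mm2=area)
    mask = truth_mask(scene, pixels_per_side)
    skel = skeletonize(mask)
    total = scene.total_length_um
    n_fib = g.n_edges
    return SNPMetrics(
        component_pixels=float(mask.sum()),
        nerve_fibre_components=float(g.n_components),
        skeleton_pixels=float(skel.sum()),
        single_nerve_fibres=float(n_fib),
        total_fibre_length_um=total,
        average_single_fibre_length_um=total / n_fib if n_fib else 0.0,
        nerve_fibre_density_mm_per_mm2=nerve_fibre_density(total, area),
        connectivity_points=float(g.n_border),
        branches=float(g.n_branch),
        area_mm2=area,
        normalised=False,
    )
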