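"""Shared fixtures: cached synthetic scenes and small handmade rasters."""

from __future__ import annotations

import numpy as np
import pytest

from snpquant import generate_scene, render_image
from snpquant.synthetic_snp import truth_mask


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene reused across read-only tests."""
    return generate_scene(seed=7)


@pytest.fixture(scope="session")
def default_render(default_scene):
    return render_image(default_scene)


@pytest.fixture(scope="session")
def default_truth_mask(default_scene):
    return truth_mask(default_scene)


@pytest.fixture
def straight_fiber_scene():
    """One straight border-to-border fibre (no branching, no curvature)."""
    return generate_scene(n_trees=1, branch_prob=0.0, tortuosity=0.0, seed=3)


def make_y_skeleton(size: int = 41, margin: int = 10) -> np.ndarray:
    """A Y: three straight arms meeting at one centre pixel, away from borders."""
    skel = np.zeros((size, size), dtype=bool)
    c = size // 2
    for i in range(c + 1):
        skel[c + i, c] = True        # stem straight down
        skel[c - i, c - i] = True    # arm up-left
        skel[c - i, c + i] = True    # arm up-right
    return np.pad(skel, margin)
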