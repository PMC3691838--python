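"""In-memory containers for confocal images and volume stacks.

The reference acquisition geometry is a 384 x 384 pixel frame covering
400 x 400 um of corneal surface (pixel size ~1.0417 um), acquired either as
single frames or as 30-slice volume scans with 2 um interslice spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Default physical field of view (um) of the reference confocal geometry.
DEFAULT_EXTENT_UM = 400.0
#: Default frame size in pixels of the reference confocal geometry.
DEFAULT_PIXELS = 384

_SQUARE_RTOL = 1e-9


@dataclass(frozen=True)
class ConfocalImage:
    """A 2-D grayscale confocal frame with physical extent.

    Parameters
    ----------
    intensities
        2-D float array, values in [0, 1] (readers normalise on ingest).
    width_um, height_um
        Physical extent of the field of view in micrometres.
    rescaled
        True if the reader rescaled the stored integer range to [0, 1].
    """

    intensities: np.ndarray
    width_um: float = DEFAULT_EXTENT_UM
    height_um: float = DEFAULT_EXTENT_UM
    rescaled: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 2-D array")
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("physical extent must be positive")
        px_w = self.width_um / arr.shape[1]
        px_h = self.height_um / arr.shape[0]
        if abs(px_w - px_h) > _SQUARE_RTOL * max(px_w, px_h):
            raise ValueError(
                f"non-square pixels: {px_w:.6g} x {px_h:.6g} um; square pixels are assumed"
            )
        lo, hi = float(arr.min()), float(arr.max())
        if not np.isfinite([lo, hi]).all() or lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo:.4g}, {hi:.4g}]")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def pixel_size_um(self) -> float:
        """Pixel edge length in um (width_um / columns; pixels are square)."""
        return self.width_um / self.intensities.shape[1]

    @property
    def area_mm2(self) -> float:
        """Field-of-view area in mm²."""
        return (self.width_um / 1000.0) * (self.height_um / 1000.0)

    def with_intensities(self, intensities: np.ndarray) -> "ConfocalImage":
        """Return a copy carrying ``intensities`` with the same geometry."""
        return ConfocalImage(
            intensities=intensities,
            width_um=self.width_um,
            height_um=self.height_um,
            rescaled=self.rescaled,
        )


@dataclass(frozen=True)
class VolumeStack:
    """An ordered z-stack of confocal frames with constant interslice spacing."""

    slices: Sequence[ConfocalImage]
    interslice_um: float = 2.0
    depth_offset_um: float = 0.0

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise ValueError("stack must contain at least one slice")
        if self.interslice_um <= 0:
            raise ValueError("interslice spacing must be positive")
        first = slices[0]
        for s in slices[1:]:
            if s.shape != first.shape or s.width_um != first.width_um or s.height_um != first.height_um:
                raise ValueError("all slices must share identical geometry")
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, k: int) -> ConfocalImage:
        return self.slices[k]

    @property
    def depth_um(self) -> float:
        """Total depth spanned by the stack (slice count - 1 spacings)."""
        return (len(self.slices) - 1) * self.interslice_um
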