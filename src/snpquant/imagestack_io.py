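"""Reading and writing confocal frames and z-stacks.

Vendor headers of clinical confocal systems are proprietary, so physical
extent is supplied by the caller (or a plain-text sidecar config), with the
reference geometry of 400 x 400 um as default.  Intensities are normalised
to [0, 1] on ingest so that all downstream thresholds are scale-free.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Callable, Union

import numpy as np
import imageio.v3 as iio
import tifffile

from .image import ConfocalImage, VolumeStack, DEFAULT_EXTENT_UM

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "read_sidecar",
    "write_sidecar",
    "select_snp_slice",
]


def _to_float01(arr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Luminance-convert and normalise a raster to [0, 1] floats."""
    arr = np.asarray(arr)
    int_max = float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else None
    if arr.ndim == 3:
        # Drop alpha, then ITU-R 601 luminance for colour inputs.
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ np.array([0.299, 0.587, 0.114])
        else:
            arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"expected a single-plane raster, got shape {arr.shape}")
    arr = arr.astype(float)
    rescaled = False
    if int_max is not None:
        arr = arr / int_max
        rescaled = True
    elif arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
        rescaled = True
    return np.clip(arr, 0.0, 1.0), rescaled


def read_image(
    path: Union[str, os.PathLike],
    width_um: float = DEFAULT_EXTENT_UM,
    height_um: float = DEFAULT_EXTENT_UM,
) -> ConfocalImage:
    """Read a single-plane grayscale raster (TIFF/PNG) as a :class:`ConfocalImage`.

    Multi-channel inputs are converted to luminance; integer ranges are
    rescaled to [0, 1] (recorded in ``rescaled``).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    data, rescaled = _to_float01(arr)
    return ConfocalImage(data, width_um=width_um, height_um=height_um, rescaled=rescaled)


def write_image(path: Union[str, os.PathLike], image: ConfocalImage) -> None:
    """Write an image as an 8-bit grayscale raster (format from extension)."""
    path = Path(path)
    data = np.clip(image.intensities, 0.0, 1.0)
    u8 = np.rint(data * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, u8)
    else:
        iio.imwrite(path, u8)


def read_stack(
    path: Union[str, os.PathLike],
    width_um: float = DEFAULT_EXTENT_UM,
    height_um: float = DEFAULT_EXTENT_UM,
    interslice_um: float = 2.0,
) -> VolumeStack:
    """Read a multi-page TIFF as a :class:`VolumeStack`."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    slices = []
    for plane in pages:
        data, rescaled = _to_float01(plane)
        slices.append(ConfocalImage(data, width_um=width_um, height_um=height_um, rescaled=rescaled))
    return VolumeStack(slices, interslice_um=interslice_um)


def read_sidecar(path: Union[str, os.PathLike]) -> dict[str, float]:
    """Read a ``key=value`` sidecar config (width_um, height_um, interslice_um)."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = float(value.strip())
    return out


def write_sidecar(path: Union[str, os.PathLike], values: dict[str, float]) -> None:
    Path(path).write_text("".join(f"{k}={v}\n" for k, v in values.items()))


def select_snp_slice(
    stack: VolumeStack,
    strategy: Union[str, int] = "max_ridge_response",
) -> ConfocalImage:
    """Pick the frame of a volume scan that best shows the nerve plexus.

    ``strategy`` is either an integer slice index or ``"max_ridge_response"``,
    which picks the slice maximising the mean multi-scale ridge-enhancement
    response (ties broken by lowest index).  The acquisition protocol scans a
    60 um deep volume through the subbasal layer, and the plexus plane is the
    one where curvilinear structures respond most strongly.
    """
    if isinstance(strategy, (int, np.integer)):
        k = int(strategy)
        if not 0 <= k < len(stack):
            raise IndexError(f"slice index {k} out of range for stack of {len(stack)}")
        return stack[k]
    if strategy != "max_ridge_response":
        raise ValueError(f"unknown strategy: {strategy!r}")
    from .segmentation import enhance_ridges  # deferred: avoids import cycle

    best_k, best_score = 0, -np.inf
    for k, img in enumerate(stack.slices):
        score = float(enhance_ridges(img).intensities.mean())
        if score > best_score:  # strict: ties keep the lowest index
            best_k, best_score = k, score
    return stack[best_k]
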