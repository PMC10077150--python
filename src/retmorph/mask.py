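"""Binary raster masks with physical scale.

A :class:`BinaryMask` is the carrier for vessel and optic-disc segmentations:
a 2-D boolean grid in row-major (row, col) order plus a micron-per-pixel
scale. The default scale of 12.2 µm/px corresponds to wide-field pediatric
fundus frames of 1,600 × 1,200 px.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

#: Physical scale of the emulated fundus camera frame, µm per pixel.
DEFAULT_SCALE_UM_PER_PX = 12.2

#: Native frame size of the emulated camera (rows, cols).
DEFAULT_FRAME_SHAPE = (1200, 1600)


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean raster with a physical scale.

    Parameters
    ----------
    grid
        Boolean array, shape (rows, cols). Any array-like is coerced;
        nonzero means foreground.
    scale_um_per_px
        Physical size of one pixel in microns. Must be positive.
    """

    grid: np.ndarray
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("mask grid must be a non-empty 2-D array")
        if not (self.scale_um_per_px > 0):
            raise ValueError("scale_um_per_px must be positive")
        object.__setattr__(self, "grid", g.astype(bool, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def count(self) -> int:
        """Number of foreground pixels."""
        return int(self.grid.sum())

    def with_scale(self, scale_um_per_px: float) -> "BinaryMask":
        return BinaryMask(self.grid, scale_um_per_px)


def load_mask(path: str | Path, scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX) -> BinaryMask:
    """Read a PNG/TIFF image as a binary mask; any nonzero pixel is foreground."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim == 3:  # collapse channels
        arr = arr.max(axis=-1)
    return BinaryMask(arr != 0, scale_um_per_px)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit 0/255 PNG or TIFF, chosen by extension."""
    path = Path(path)
    arr = (mask.grid.astype(np.uint8)) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)
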