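"""Image container and TIFF input/output.

A :class:`PixelGrid` is one channel's 2D intensity raster together with the
physical pixel size; it is the common currency between the simulator and the
detector.  Multi-channel TIFF stacks are read with the channel axis first;
interleaved RGB images are refused because their channel semantics are
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["PixelGrid", "ImageFormatError", "read_tiff", "write_tiff"]


class ImageFormatError(ValueError):
    """Unsupported or ambiguous image layout."""


@dataclass
class PixelGrid:
    """One channel's 2D intensity raster plus physical pixel size.

    ``data`` is indexed ``[row, column]`` (= ``[y, x]``); coordinates used
    elsewhere in the package are ``(x, y)`` with the origin at the centre of
    the top-left pixel.
    """

    data: np.ndarray
    pixel_size_nm: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ImageFormatError(f"expected a 2D image, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data.astype(float))):
            raise ImageFormatError("image contains non-finite values")
        if np.any(self.data < 0):
            raise ImageFormatError("image contains negative intensities")
        if not (self.pixel_size_nm > 0):
            raise ImageFormatError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_tiff(
    path: str | Path,
    pixel_size_nm: float,
    channel: int | None = None,
    channel_label: str = "",
) -> PixelGrid:
    """Read a single channel from an 8/16-bit TIFF.

    2D files are read directly.  For a 3D stack the *first* axis is taken as
    the channel axis and ``channel`` selects a plane.  A trailing axis of
    length 3 or 4 (interleaved RGB/RGBA) is refused: convert to a
    channel-first stack or separate files instead.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        if channel not in (None, 0):
            raise ImageFormatError(f"{path} is single-channel; cannot select channel {channel}")
        plane = arr
    elif arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            raise ImageFormatError(
                f"{path} looks like interleaved RGB (shape {arr.shape}); "
                "supply a channel-first stack or one file per channel"
            )
        if channel is None:
            raise ImageFormatError(
                f"{path} is a {arr.shape[0]}-channel stack; a channel index is required"
            )
        if not (0 <= channel < arr.shape[0]):
            raise ImageFormatError(
                f"channel {channel} out of range for stack with {arr.shape[0]} planes"
            )
        plane = arr[channel]
    else:
        raise ImageFormatError(f"unsupported TIFF dimensionality: shape {arr.shape}")
    return PixelGrid(data=plane, pixel_size_nm=pixel_size_nm, channel=channel_label)


def write_tiff(path: str | Path, grid: PixelGrid) -> None:
    """Write one channel as a plain single-plane TIFF."""
    tifffile.imwrite(str(path), grid.data)
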