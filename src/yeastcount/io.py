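"""Image reading/writing and channel handling.

The counting pipeline works on one field of view captured three times:
a bright-field image (cells dark on a bright background), a green-fluorescence
image (GF; fluorescein from FDA hydrolysis marks live cells) and a
red-fluorescence image (RF; propidium iodide marks dead cells). All processing
is done on 8-bit single-channel images; colour inputs are reduced on load.

Pixel indexing is (row, col), 0-based, row-major.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Tuple

import numpy as np
from PIL import Image
import tifffile

ChannelTag = Literal["brightfield", "green", "red"]

#: ITU-R BT.601 luminance weights used for grayscale conversion.
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ChannelImage:
    """A single 8-bit image plane.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (height, width)
        Intensities on the 0-255 scale.
    channel_tag : {"brightfield", "green", "red"}
        Which acquisition channel the plane came from.
    """

    pixels: np.ndarray
    channel_tag: ChannelTag

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValueError("pixel intensities must be 8-bit (0-255)")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class MultiChannelFrame:
    """Co-registered bright-field / green / red triple for one field of view."""

    brightfield: ChannelImage
    green: ChannelImage
    red: ChannelImage

    def __post_init__(self) -> None:
        shapes = {
            "brightfield": self.brightfield.shape,
            "green": self.green.shape,
            "red": self.red.shape,
        }
        ref = shapes["brightfield"]
        for name, shp in shapes.items():
            if shp != ref:
                raise ValueError(
                    f"channel dimension mismatch: brightfield is {ref} but {name} is {shp}"
                )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.brightfield.shape


def _read_raw(path: str | os.PathLike) -> np.ndarray:
    """Read PNG/TIFF to an array, rescaling 16-bit data to the 8-bit range."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    # drop an alpha plane if present
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def _as_plane(arr: np.ndarray, tag: ChannelTag) -> ChannelImage:
    """Reduce a decoded array to the single plane named by ``tag``."""
    if arr.ndim == 2:
        return ChannelImage(arr, tag)
    if arr.ndim == 3 and arr.shape[2] == 3:
        if tag == "brightfield":
            return to_gray(arr)
        green, red = split_channels(arr)
        return green if tag == "green" else red
    raise ValueError(f"unsupported image shape {arr.shape} for channel {tag}")


def load_frame(
    bf_path: str | os.PathLike,
    gf_path: str | os.PathLike,
    rf_path: str | os.PathLike,
) -> MultiChannelFrame:
    """Load one field of view from three image files.

    Colour bright-field input is converted to grayscale; colour fluorescence
    inputs are reduced to their named channel plane. All three images must
    decode to identical dimensions (the channels are assumed co-registered by
    the instrument).
    """
    bf = _as_plane(_read_raw(bf_path), "brightfield")
    gf = _as_plane(_read_raw(gf_path), "green")
    rf = _as_plane(_read_raw(rf_path), "red")
    return MultiChannelFrame(bf, gf, rf)


def split_channels(color_image: np.ndarray) -> Tuple[ChannelImage, ChannelImage]:
    """Split an RGB image into its green and red planes.

    Working on single 8-bit planes instead of a 24-bit colour image is what
    lets the rest of the pipeline stay cheap; the planes are returned
    unchanged (no re-weighting).
    """
    arr = np.asarray(color_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected a 3-channel color image, got shape {arr.shape}")
    return (
        ChannelImage(arr[:, :, 1].copy(), "green"),
        ChannelImage(arr[:, :, 0].copy(), "red"),
    )


def merge_channels(green: ChannelImage, red: ChannelImage, blue: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`split_channels` (blue plane zero unless given)."""
    if green.shape != red.shape:
        raise ValueError("green and red planes differ in shape")
    b = np.zeros(green.shape, dtype=np.uint8) if blue is None else np.asarray(blue, dtype=np.uint8)
    return np.stack([red.pixels, green.pixels, b], axis=-1)


def to_gray(color_image: np.ndarray) -> ChannelImage:
    """Convert an RGB image to 8-bit grayscale with BT.601 luminance weights."""
    arr = np.asarray(color_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected a 3-channel color image, got shape {arr.shape}")
    gray = np.rint(arr.astype(np.float64) @ _BT601).clip(0, 255).astype(np.uint8)
    return ChannelImage(gray, "brightfield")


def save_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale or RGB array as PNG/TIFF."""
    path = Path(path)
    arr = np.asarray(pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Export a boolean mask as a 0/255 8-bit PNG for inspection."""
    save_image(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))
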