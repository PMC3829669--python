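"""Global Gaussian thresholding, binarization and object detection.

The intensity histogram of a yeast micrograph is well modelled by a single
Gaussian background mode plus a small foreground tail, so a global threshold
is placed a fixed number of standard deviations from the image mean:

    T = mu - alpha * sigma      (dark objects, bright-field)
    T = mu + alpha * sigma      (bright objects, fluorescence)

with ``alpha = 3`` by default. Unlike Otsu's method this stays correct when
the foreground occupies a vanishing fraction of pixels, which is exactly the
regime of sparse yeast fields (Otsu is kept here only as a comparison
baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Literal, Set, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .io import ChannelImage

Polarity = Literal["dark_objects", "bright_objects"]

#: Default confidence-interval constant for the global threshold.
DEFAULT_ALPHA = 3.0


@dataclass(frozen=True)
class ThresholdParams:
    """Threshold configuration: ``alpha`` and which side of the mean is foreground."""

    alpha: float = DEFAULT_ALPHA
    polarity: Polarity = "dark_objects"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground map with the dimensions of its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
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
class DetectedObject:
    """One 8-connected foreground component and its geometry.

    ``roundness`` is the circularity 4*pi*area/perimeter^2, capped at 1.0
    (rasterized disks can overshoot slightly); a single-pixel object is taken
    as perfectly round.
    """

    object_id: int
    coords: np.ndarray  # (n, 2) array of (row, col)
    area_px: int
    perimeter_px: float
    centroid: Tuple[float, float]
    bounding_box: Tuple[int, int, int, int]  # min_row, min_col, max_row, max_col
    equivalent_diameter_px: float
    roundness: float

    @property
    def pixel_set(self) -> Set[Tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}


def _pixels(image: ChannelImage | np.ndarray) -> np.ndarray:
    return image.pixels if isinstance(image, ChannelImage) else np.asarray(image)


def image_stats(image: ChannelImage | np.ndarray) -> Tuple[float, float]:
    """Mean and population standard deviation of the image intensities.

    sigma uses the divide-by-MN (population) form, matching the defining
    sums over all M*N pixels.
    """
    px = _pixels(image).astype(np.float64)
    if px.size == 0:
        raise ValueError("empty image")
    return float(px.mean()), float(px.std(ddof=0))


def gaussian_threshold(
    image: ChannelImage | np.ndarray, params: ThresholdParams = ThresholdParams()
) -> float:
    """Global threshold T = mu -/+ alpha*sigma, clamped to [0, 255].

    ``dark_objects`` subtracts (bright-field: cells are darker than the
    background); ``bright_objects`` adds (fluorescence: cells are brighter).
    """
    mu, sigma = image_stats(image)
    if params.polarity == "dark_objects":
        t = mu - params.alpha * sigma
    else:
        t = mu + params.alpha * sigma
    return float(min(255.0, max(0.0, t)))


def denoise(image: ChannelImage) -> ChannelImage:
    """3x3 median filter with edge replication; removes salt noise, keeps edges."""
    out = ndimage.median_filter(image.pixels, size=3, mode="nearest")
    return ChannelImage(out, image.channel_tag)


def binarize(
    image: ChannelImage | np.ndarray, threshold: float, polarity: Polarity
) -> BinaryMask:
    """Foreground = I < T (dark objects) or I > T (bright objects); strict at T."""
    px = _pixels(image)
    if polarity == "dark_objects":
        return BinaryMask(px < threshold)
    if polarity == "bright_objects":
        return BinaryMask(px > threshold)
    raise ValueError(f"unknown polarity {polarity!r}")


def candidate_mask(gf_mask: BinaryMask, rf_mask: BinaryMask) -> BinaryMask:
    """Yeast-candidate mask: union of the GF and RF binaries.

    Live cells carry green signal only and dead cells mostly red, so the two
    binaries must be OR-ed for every stained cell to appear in the candidate
    map.
    """
    if gf_mask.shape != rf_mask.shape:
        raise ValueError(
            f"mask dimension mismatch: GF {gf_mask.shape} vs RF {rf_mask.shape}"
        )
    return BinaryMask(gf_mask.pixels | rf_mask.pixels)


def find_objects(mask: BinaryMask) -> List[DetectedObject]:
    """Extract all 8-connected foreground components with their geometry."""
    labels = measure.label(mask.pixels, connectivity=2)
    objects: List[DetectedObject] = []
    for region in measure.regionprops(labels):
        area = int(region.area)
        perim = float(region.perimeter)
        if perim > 0:
            roundness = min(1.0, 4.0 * np.pi * area / perim**2)
        else:
            roundness = 1.0  # single pixel / degenerate boundary: maximally compact
        minr, minc, maxr, maxc = region.bbox
        objects.append(
            DetectedObject(
                object_id=int(region.label),
                coords=region.coords.copy(),
                area_px=area,
                perimeter_px=perim,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                bounding_box=(int(minr), int(minc), int(maxr) - 1, int(maxc) - 1),
                equivalent_diameter_px=float(2.0 * np.sqrt(area / np.pi)),
                roundness=float(roundness),
            )
        )
    return objects


def otsu_threshold(image: ChannelImage | np.ndarray) -> float:
    """Classic Otsu threshold over the 256-bin histogram (comparison baseline).

    On sparse foregrounds Otsu's between-class criterion places T inside the
    background mode — the failure mode that motivates the Gaussian threshold.
    A constant image is degenerate: its own value is returned with a warning.
    """
    px = _pixels(image)
    if px.min() == px.max():
        warnings.warn("degenerate (constant) image: Otsu threshold undefined", stacklevel=2)
        return float(px.flat[0])
    return float(filters.threshold_otsu(px, nbins=256))
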