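"""Per-object intensity and geometry measurements.

Intensities are read from the denoised original channels under the object's
pixels (not from the binary masks), so the live/dead decision sees the true
signal levels. Cell size can additionally be refined from the bright-field
channel, which is insensitive to fluorescence exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List

import numpy as np
from skimage import measure

from .io import MultiChannelFrame
from .segmentation import DetectedObject, ThresholdParams, gaussian_threshold, image_stats

#: Bounding-box padding (px) for bright-field size refinement; captures the
#: dark cell-wall ring that extends slightly past the fluorescent body.
BBOX_PAD = 2


@dataclass(frozen=True)
class ObjectFeatures:
    object_id: int
    area_px: int
    equivalent_diameter_px: float
    roundness: float
    mean_gf: float
    mean_rf: float
    mean_gray: float
    background_gray: float

    def as_dict(self) -> dict:
        return asdict(self)


def measure_object(obj: DetectedObject, frame: MultiChannelFrame) -> ObjectFeatures:
    """Mean per-channel intensity over the object's pixels plus its geometry.

    ``frame`` should be the denoised frame the masks were derived from.
    ``background_gray`` is the frame-wide bright-field mean, the reference
    level against which dark (bright-field-visible) objects are judged.
    """
    rows, cols = obj.coords[:, 0], obj.coords[:, 1]
    h, w = frame.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise ValueError(f"object {obj.object_id} has pixels outside the {h}x{w} frame")
    mu_bf, _ = image_stats(frame.brightfield)
    return ObjectFeatures(
        object_id=obj.object_id,
        area_px=obj.area_px,
        equivalent_diameter_px=obj.equivalent_diameter_px,
        roundness=obj.roundness,
        mean_gf=float(frame.green.pixels[rows, cols].mean()),
        mean_rf=float(frame.red.pixels[rows, cols].mean()),
        mean_gray=float(frame.brightfield.pixels[rows, cols].mean()),
        background_gray=float(mu_bf),
    )


def measure_frame(objects: List[DetectedObject], frame: MultiChannelFrame) -> List[ObjectFeatures]:
    return [measure_object(obj, frame) for obj in objects]


def size_from_brightfield(
    obj: DetectedObject,
    frame: MultiChannelFrame,
    params: ThresholdParams = ThresholdParams(alpha=3.0, polarity="dark_objects"),
    bf_threshold: float | None = None,
) -> int:
    """Refine an object's area from the bright-field channel.

    Fluorescence footprints depend on camera exposure and staining intensity;
    the dark cell body in bright-field does not. Within the object's bounding
    box (padded by ``BBOX_PAD``), the bright-field channel is re-thresholded
    with the frame-wide dark-objects Gaussian threshold and the area of the
    dark 8-connected component under the object's centroid is returned. The
    frame-global threshold is used (not a per-box one) to avoid histogram
    instability on tiny crops. Falls back to the fluorescence-mask area when
    no dark component overlaps the object.
    """
    if params.polarity != "dark_objects":
        raise ValueError("bright-field refinement requires dark_objects polarity")
    if bf_threshold is None:
        bf_threshold = gaussian_threshold(frame.brightfield, params)

    h, w = frame.shape
    minr, minc, maxr, maxc = obj.bounding_box
    r0, c0 = max(0, minr - BBOX_PAD), max(0, minc - BBOX_PAD)
    r1, c1 = min(h, maxr + 1 + BBOX_PAD), min(w, maxc + 1 + BBOX_PAD)

    crop = frame.brightfield.pixels[r0:r1, c0:c1]
    dark = crop < bf_threshold
    if not dark.any():
        return obj.area_px
    labels = measure.label(dark, connectivity=2)

    cr = int(round(obj.centroid[0])) - r0
    cc = int(round(obj.centroid[1])) - c0
    target = 0
    if 0 <= cr < labels.shape[0] and 0 <= cc < labels.shape[1]:
        target = int(labels[cr, cc])
    if target == 0:
        # centroid not on a dark pixel: take the dark component with the
        # largest overlap with the object's own pixels
        rows = obj.coords[:, 0] - r0
        cols = obj.coords[:, 1] - c0
        inside = (rows >= 0) & (rows < labels.shape[0]) & (cols >= 0) & (cols < labels.shape[1])
        hit = labels[rows[inside], cols[inside]]
        hit = hit[hit > 0]
        if hit.size == 0:
            return obj.area_px
        target = int(np.bincount(hit).argmax())
    return int((labels == target).sum())
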