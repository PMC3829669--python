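"""Annotated overlay rendering: circle each counted object on a colour
composite, green for live, red for dead, yellow for debris."""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw

from .pipeline import FrameAnalysis

_COLORS = {"live": (0, 255, 0), "dead": (255, 0, 0), "debris": (255, 255, 0)}


def render_overlay(analysis: FrameAnalysis) -> np.ndarray:
    """RGB composite (red=RF, green=GF, blue=dimmed bright-field) with one
    outline per classified object at its equivalent radius."""
    den = analysis.denoised
    base = np.stack(
        [den.red.pixels, den.green.pixels, den.brightfield.pixels // 3], axis=-1
    )
    img = Image.fromarray(base.astype(np.uint8))
    drawer = ImageDraw.Draw(img)

    geometry = list(analysis.objects) + list(analysis.bf_only_objects)
    for obj, cls in zip(geometry, analysis.classified):
        r = max(3.0, obj.equivalent_diameter_px / 2.0 + 2.0)
        cy, cx = obj.centroid
        drawer.ellipse(
            [cx - r, cy - r, cx + r, cy + r], outline=_COLORS[cls.label], width=1
        )
    return np.asarray(img)
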