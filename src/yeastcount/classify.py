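"""Live / dead / debris classification of detected objects.

The assay makes the decision simple: FDA-derived fluorescein (green) is
retained only by membrane-intact live cells, while propidium iodide (red)
enters only membrane-compromised dead cells. An object that is the right
size and shape for a yeast cell is therefore live if its green signal
exceeds its red signal and dead otherwise; objects that carry neither
fluorescent signal but are visible in bright-field — hop, grape or rice-flour
particles in a messy culture — are debris.

Decision cascade (first matching rule wins):

1. geometry  — too small, too large or too irregular for a yeast cell;
2. unstained — both fluorescence means below the channel signal floors;
3. live      — mean GF > mean RF;
4. dead      — otherwise (ties count as dead: PI positivity means a
               compromised membrane, the conservative call for viability).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import List, Literal, Optional

from .features import ObjectFeatures

Label = Literal["live", "dead", "debris"]

#: Default image scale. At 0.6 um/px a typical S. cerevisiae cell
#: (3-8 um diameter) spans 5-13 px.
DEFAULT_UM_PER_PX = 0.6


def _disk_area_px(diameter_um: float, um_per_px: float) -> int:
    r_px = diameter_um / (2.0 * um_per_px)
    return max(1, int(round(math.pi * r_px * r_px)))


@dataclass(frozen=True)
class ClassifierConfig:
    """Gates and signal floors for the classification cascade.

    Size gates default to the pixel areas of 2 um and 10 um diameter disks at
    ``DEFAULT_UM_PER_PX`` (yeast are 3-8 um, so the gates bracket generously).
    ``gf_min_signal`` / ``rf_min_signal`` are the intensities above which a
    channel counts as stained; when ``None`` the pipeline fills them with the
    channel's own mu + alpha*sigma background statistic, reusing the
    thresholding constant rather than introducing a new one.
    ``bf_dark_contrast`` is the gray deficit versus the frame background that
    marks a bright-field-visible object (used for the bright-field debris
    scan).
    """

    min_area_px: int = _disk_area_px(2.0, DEFAULT_UM_PER_PX)
    max_area_px: int = _disk_area_px(10.0, DEFAULT_UM_PER_PX)
    min_roundness: float = 0.5
    gf_min_signal: Optional[float] = None
    rf_min_signal: Optional[float] = None
    bf_dark_contrast: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area_px < self.max_area_px):
            raise ValueError("require 0 < min_area_px < max_area_px")
        if not (0.0 <= self.min_roundness <= 1.0):
            raise ValueError("min_roundness must be in [0, 1]")

    @classmethod
    def from_scale(
        cls,
        um_per_px: float,
        min_diameter_um: float = 2.0,
        max_diameter_um: float = 10.0,
        **kwargs,
    ) -> "ClassifierConfig":
        return cls(
            min_area_px=_disk_area_px(min_diameter_um, um_per_px),
            max_area_px=_disk_area_px(max_diameter_um, um_per_px),
            **kwargs,
        )

    def with_floors(self, gf_floor: float, rf_floor: float) -> "ClassifierConfig":
        """Fill unset signal floors with frame-derived values."""
        return replace(
            self,
            gf_min_signal=self.gf_min_signal if self.gf_min_signal is not None else gf_floor,
            rf_min_signal=self.rf_min_signal if self.rf_min_signal is not None else rf_floor,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ClassifiedObject:
    features: ObjectFeatures
    label: Label
    rule_fired: str


def classify_object(features: ObjectFeatures, config: ClassifierConfig) -> ClassifiedObject:
    """Apply the four-rule cascade to one object."""
    if config.gf_min_signal is None or config.rf_min_signal is None:
        raise ValueError(
            "signal floors unresolved; use config.with_floors(...) or set them explicitly"
        )
    f = features
    if (
        f.area_px < config.min_area_px
        or f.area_px > config.max_area_px
        or f.roundness < config.min_roundness
    ):
        return ClassifiedObject(f, "debris", "geometry")
    if f.mean_gf < config.gf_min_signal and f.mean_rf < config.rf_min_signal:
        return ClassifiedObject(f, "debris", "unstained")
    if f.mean_gf > f.mean_rf:
        return ClassifiedObject(f, "live", "gf_over_rf")
    return ClassifiedObject(f, "dead", "rf_ge_gf")


def classify_frame(
    objects: List[ObjectFeatures], config: ClassifierConfig
) -> List[ClassifiedObject]:
    """Classify every object; order and length preserved."""
    return [classify_object(f, config) for f in objects]
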