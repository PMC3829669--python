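"""The full counting pipeline for one frame.

Order of operations: denoise each channel -> Gaussian-threshold the two
fluorescence channels (bright objects) -> combine binaries into the yeast
candidate mask -> extract connected components -> measure per-object
intensities on the denoised originals -> classify live/dead/debris ->
tally counts, viability and concentration.

Additionally, dark bright-field components that overlap no fluorescent
candidate are reported as debris when their gray deficit versus the frame
background exceeds the configured contrast: messy-culture particles are
visible in bright-field only, so a fluorescence-driven candidate mask alone
would never surface them. This bright-field scan is logged on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

from .io import MultiChannelFrame
from .segmentation import (
    BinaryMask,
    DetectedObject,
    ThresholdParams,
    binarize,
    candidate_mask,
    denoise,
    find_objects,
    gaussian_threshold,
    image_stats,
)
from .features import ObjectFeatures, measure_frame, measure_object
from .classify import ClassifiedObject, ClassifierConfig, classify_frame
from .quantify import CountResult, DEFAULT_VOLUME_FACTOR, summarize

logger = logging.getLogger("yeastcount")


@dataclass
class ChannelStats:
    mu: float
    sigma: float
    threshold: float


@dataclass
class FrameAnalysis:
    """Everything computed for one frame, for auditing and rendering."""

    stats: Dict[str, ChannelStats]
    gf_mask: BinaryMask
    rf_mask: BinaryMask
    candidates: BinaryMask
    objects: List[DetectedObject]
    features: List[ObjectFeatures]
    classified: List[ClassifiedObject]
    bf_only_objects: List[DetectedObject]
    result: CountResult
    denoised: MultiChannelFrame


def analyze_frame(
    frame: MultiChannelFrame,
    alpha: float = 3.0,
    config: Optional[ClassifierConfig] = None,
    volume_factor: float = DEFAULT_VOLUME_FACTOR,
    scan_brightfield_debris: bool = True,
) -> FrameAnalysis:
    """Run the complete segment-classify-summarize pipeline on one frame."""
    config = config or ClassifierConfig()

    den = MultiChannelFrame(
        denoise(frame.brightfield), denoise(frame.green), denoise(frame.red)
    )

    bright = ThresholdParams(alpha=alpha, polarity="bright_objects")
    dark = ThresholdParams(alpha=alpha, polarity="dark_objects")
    stats: Dict[str, ChannelStats] = {}
    for name, chan, params in (
        ("brightfield", den.brightfield, dark),
        ("green", den.green, bright),
        ("red", den.red, bright),
    ):
        mu, sigma = image_stats(chan)
        stats[name] = ChannelStats(mu, sigma, gaussian_threshold(chan, params))
        logger.info(
            "channel %-11s mu=%.2f sigma=%.2f T=%.2f", name, mu, sigma,
            stats[name].threshold,
        )

    gf_mask = binarize(den.green, stats["green"].threshold, "bright_objects")
    rf_mask = binarize(den.red, stats["red"].threshold, "bright_objects")
    candidates = candidate_mask(gf_mask, rf_mask)

    objects = find_objects(candidates)
    feats = measure_frame(objects, den)

    # signal floors default to each fluorescence channel's own mu + alpha*sigma
    cfg = config.with_floors(stats["green"].threshold, stats["red"].threshold)
    classified = classify_frame(feats, cfg)
    logger.info(
        "candidate objects: %d (%d below/above geometry gates)",
        len(classified),
        sum(1 for c in classified if c.rule_fired == "geometry"),
    )

    bf_only: List[DetectedObject] = []
    if scan_brightfield_debris:
        bf_dark = binarize(den.brightfield, stats["brightfield"].threshold, "dark_objects")
        for obj in find_objects(bf_dark):
            if obj.area_px < cfg.min_area_px:
                continue
            rows, cols = obj.coords[:, 0], obj.coords[:, 1]
            if candidates.pixels[rows, cols].any():
                continue  # belongs to a fluorescent candidate, already handled
            f = measure_object(obj, den)
            if f.background_gray - f.mean_gray > cfg.bf_dark_contrast:
                bf_only.append(obj)
                classified.append(ClassifiedObject(f, "debris", "bf_only"))
        logger.info(
            "bright-field-only debris scan (extension beyond the fluorescence "
            "candidate mask): %d objects flagged", len(bf_only),
        )

    result = summarize(classified, volume_factor=volume_factor)
    logger.info(
        "counts: live=%d dead=%d debris=%d viability=%s",
        result.n_live, result.n_dead, result.n_debris,
        "NA" if result.viability_pct is None else f"{result.viability_pct:.1f}%",
    )
    return FrameAnalysis(
        stats=stats,
        gf_mask=gf_mask,
        rf_mask=rf_mask,
        candidates=candidates,
        objects=objects,
        features=feats,
        classified=classified,
        bf_only_objects=bf_only,
        result=result,
        denoised=den,
    )


def count_frame(
    frame: MultiChannelFrame,
    alpha: float = 3.0,
    config: Optional[ClassifierConfig] = None,
    volume_factor: float = DEFAULT_VOLUME_FACTOR,
) -> CountResult:
    """Convenience wrapper returning only the :class:`CountResult`."""
    return analyze_frame(
        frame, alpha=alpha, config=config, volume_factor=volume_factor
    ).result
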