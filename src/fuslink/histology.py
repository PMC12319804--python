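"""Myelin immunofluorescence quantification on 8-bit grayscale sections.

Two complementary measurements per region and hemisphere: the
background-subtracted mean gray intensity (a linear surrogate for myelin
basic protein content when all sections are stained and scanned
identically) and the percentage of the region area whose intensity reaches
a common threshold (default 64 on the 0-255 scale).  Per-animal values are
the mean over left/right sides within a section, then over sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SectionQuant",
    "mean_gray_intensity",
    "area_fraction",
    "quantify_section",
    "aggregate_animal",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 64


@dataclass
class SectionQuant:
    """Quantification of one region on one side of one section."""

    section_id: str
    region: str
    side: str  # "left" | "right"
    mean_gray: float  # background-subtracted
    area_fraction_pct: float

    def __post_init__(self) -> None:
        if self.mean_gray < -5:
            # a blank region can dip slightly below background by noise,
            # but a strongly negative value means the masks are wrong
            logger.warning(
                "section %s, %s/%s: background-subtracted mean %.1f < -5",
                self.section_id, self.region, self.side, self.mean_gray,
            )


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        # colour input: standard luminance conversion, then 8-bit
        weights = np.array([0.2126, 0.7152, 0.0722])
        image = np.clip(np.rint(image[..., :3].astype(float) @ weights), 0, 255).astype(np.uint8)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return image


def mean_gray_intensity(image: np.ndarray, region_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean gray level over the region minus the mean over the background zone.

    Negative values are retained (clipping would bias group means) but the
    caller is warned when they fall below what mask noise explains.
    """
    image = _check_image(image)
    region_mask = np.asarray(region_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if region_mask.shape != image.shape or background_mask.shape != image.shape:
        raise ValueError("mask shape mismatch")
    if not region_mask.any() or not background_mask.any():
        raise ValueError("region and background masks must be non-empty")
    if np.any(region_mask & background_mask):
        raise ValueError("region and background masks must be disjoint")
    return float(image[region_mask].mean() - image[background_mask].mean())


def area_fraction(image: np.ndarray, region_mask: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> float:
    """Percent of region pixels at or above the staining threshold."""
    image = _check_image(image)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != image.shape:
        raise ValueError("mask shape mismatch")
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    vals = image[region_mask]
    if vals.size == 0:
        raise ValueError("region mask is empty")
    return float(100.0 * np.count_nonzero(vals >= threshold) / vals.size)


def quantify_section(
    image: np.ndarray,
    region_masks: np.ndarray,
    region_labels: dict[str, int],
    section_id: str,
    threshold: int = DEFAULT_THRESHOLD,
    background_region: str = "background",
    side_split: bool = True,
) -> list[SectionQuant]:
    """Quantify every labelled tissue region of one section.

    When ``side_split`` is true the image midline (vertical) separates the
    left and right halves of each region, mirroring bilateral
    quantification; otherwise a single "both" entry per region is emitted.
    """
    image = _check_image(image)
    region_masks = np.asarray(region_masks)
    if background_region not in region_labels:
        raise ValueError(f"no {background_region!r} label for background subtraction")
    bg = region_masks == region_labels[background_region]
    mid = image.shape[1] // 2
    out = []
    for region, label in region_labels.items():
        if region == background_region:
            continue
        full = region_masks == label
        if not full.any():
            continue
        halves = (("left", slice(None, mid)), ("right", slice(mid, None))) if side_split else (("both", slice(None)),)
        for side, cols in halves:
            mask = np.zeros_like(full)
            mask[:, cols] = full[:, cols]
            if not mask.any():
                logger.warning("section %s: region %s missing on %s side", section_id, region, side)
                continue
            out.append(
                SectionQuant(
                    section_id=section_id,
                    region=region,
                    side=side,
                    mean_gray=mean_gray_intensity(image, mask, bg),
                    area_fraction_pct=area_fraction(image, mask, threshold),
                )
            )
    return out


def aggregate_animal(quants: list[SectionQuant] | pd.DataFrame) -> pd.DataFrame:
    """Per-region animal values: mean over sides within section, then over sections.

    Returns a frame indexed by region with columns ``mean_gray`` and
    ``area_fraction_pct``.  A section missing one side contributes its
    available side, with a warning.
    """
    if isinstance(quants, pd.DataFrame):
        df = quants.copy()
    else:
        if not quants:
            raise ValueError("no section quantifications to aggregate")
        df = pd.DataFrame([q.__dict__ for q in quants])
    required = {"section_id", "region", "side", "mean_gray", "area_fraction_pct"}
    if not required <= set(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    sides_per = df.groupby(["region", "section_id"])["side"].nunique()
    incomplete = sides_per[sides_per < 2]
    for (region, section), _ in incomplete.items():
        logger.warning("region %s, section %s: only one side available", region, section)
    per_section = df.groupby(["region", "section_id"])[["mean_gray", "area_fraction_pct"]].mean()
    return per_section.groupby("region").mean()
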