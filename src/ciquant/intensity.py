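"""Marker densitometry: mean gray values per segmented region class.

Quantifies background-corrected marker intensity (typically vimentin and
pan-cytokeratin) inside supplied region masks — normal luminal duct
epithelium, multicellular tumor groups in the marginal adipose tissue, and
spindle-shaped stromal cells.  Region masks are supplied (manually drawn or
generator ground truth); identifying stromal cells by morphology is not
automated here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import MultiChannelImage
from .errors import EmptyRegionError

logger = logging.getLogger(__name__)

REGION_CLASSES = ("normal_luminal_epithelium", "tumor_group_adipose",
                  "stromal_cell")


@dataclass
class RegionProfile:
    """Mean background-corrected intensity of each channel in one region."""

    region_class: str
    mean_gray: dict[str, float]
    pixel_count: int


def max_projection(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (planes, h, w) stack."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3:
        raise ValueError("expected a 2D image or a (planes, h, w) stack")
    return stack.max(axis=0)


def mean_gray(channel: np.ndarray, region_mask: np.ndarray) -> float:
    """Arithmetic mean of the channel over the mask pixels."""
    channel = np.asarray(channel, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if channel.shape != region_mask.shape:
        raise ValueError("channel and mask shapes differ")
    n = int(region_mask.sum())
    if n == 0:
        raise EmptyRegionError("region mask is empty")
    return float(channel[region_mask].mean())


def region_marker_table(image: MultiChannelImage,
                        regions: list[tuple[str, np.ndarray]]
                        ) -> list[RegionProfile]:
    """Mean gray value of every channel inside each named region.

    Overlapping regions are allowed (a pixel then contributes to several
    profiles) but logged, since overlaps usually indicate sloppy manual
    segmentation.
    """
    masks = [np.asarray(m, dtype=bool) for _, m in regions]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                logger.warning("region masks %r and %r overlap",
                               regions[i][0], regions[j][0])
    profiles = []
    for (name, _), mask in zip(regions, masks):
        profiles.append(RegionProfile(
            region_class=name,
            mean_gray={ch: mean_gray(image[ch], mask)
                       for ch in image.channels},
            pixel_count=int(mask.sum()),
        ))
    return profiles
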