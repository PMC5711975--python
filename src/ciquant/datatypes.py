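"""Core in-memory containers shared across the pipeline.

Images are plain numpy arrays wrapped with the physical metadata the
measurements need (pixel size in micrometers).  Per-cell and per-group
results are lightweight dataclasses convertible to pandas DataFrames for
downstream tabular work.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CHANNEL_NAMES = ("nuclear", "ecadherin", "keratin", "vimentin", "cd44")

#: group_id given to cells without a multicellular neighborhood
INDIVIDUAL = 0


@dataclass
class MultiChannelImage:
    """A multiplexed fluorescence-style image of one tissue section.

    Parameters
    ----------
    channels
        Mapping of channel name -> 2D float array.  Any subset of
        ``CHANNEL_NAMES`` may be present; all must share one shape.
    pixel_size
        Physical edge length of one pixel in micrometers.
    slide_id
        Identifier used in output tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class RegionMasks:
    """Co-registered binary region masks for one slide.

    ``tissue`` is the reference area ("whole section"); ``adipose`` the
    adipocyte-rich marginal region; ``tumor`` the thresholded (or ground
    truth) epithelial tumor area; ``exclusion`` marks normal ducts and other
    regions to remove from the tumor mask.  ``core`` optionally marks the
    central tumor mass, used only for compartment assignment.
    """

    tissue: np.ndarray
    adipose: np.ndarray
    tumor: np.ndarray
    exclusion: Optional[np.ndarray] = None
    core: Optional[np.ndarray] = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        masks = {"tissue": self.tissue, "adipose": self.adipose, "tumor": self.tumor}
        if self.exclusion is not None:
            masks["exclusion"] = self.exclusion
        if self.core is not None:
            masks["core"] = self.core
        shapes = {m.shape for m in masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"masks disagree on shape: {shapes}")
        for name, m in masks.items():
            if m.dtype != bool:
                masks[name] = m.astype(bool)
        self.tissue = masks["tissue"]
        self.adipose = masks["adipose"]
        self.tumor = masks["tumor"]
        if self.exclusion is not None:
            self.exclusion = masks["exclusion"]
        if self.core is not None:
            self.core = masks["core"]


@dataclass
class CellRecord:
    """One detected nucleus with its group assignment.

    ``group_id`` is ``INDIVIDUAL`` (0) when the cell's epithelial component
    holds exactly one nucleus and has no epithelial neighbor within the
    neighbor radius.
    """

    centroid: tuple[float, float]
    group_id: int
    keratin_positive: bool
    compartment: str = "fibrous"


@dataclass
class GroupRecord:
    """One multicellular tumor group (connected epithelial component)."""

    group_id: int
    area_um2: float
    cell_count: int
    compartment: str
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.cell_count < 2:
            raise ValueError("a group holds at least 2 cells")
        if self.area_um2 <= 0:
            raise ValueError("group area must be positive")


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    """Tabulate CellRecords (one row per detected cell)."""
    return pd.DataFrame(
        {
            "row": [c.centroid[0] for c in cells],
            "col": [c.centroid[1] for c in cells],
            "group_id": [c.group_id for c in cells],
            "keratin_positive": [c.keratin_positive for c in cells],
            "compartment": [c.compartment for c in cells],
        }
    )


def groups_to_frame(groups: list[GroupRecord]) -> pd.DataFrame:
    """Tabulate GroupRecords (one row per multicellular group)."""
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "area_um2": [g.area_um2 for g in groups],
            "cell_count": [g.cell_count for g in groups],
            "compartment": [g.compartment for g in groups],
        }
    )


@dataclass
class SlideQuant:
    """Per-slide quantification summary.

    ``ci_score`` is the ratio of the percentage of total tumor area lying in
    adipose tissue to the percentage of adipose tissue in the whole section;
    ``None`` when the slide is excluded (no adipose tissue).
    """

    slide_id: str
    pct_adipose: float
    pct_tumor_in_adipose: float
    ci_score: Optional[float]
    individualized_pct: Optional[float] = None
    collective_positive: Optional[bool] = None
    subtype: Optional[str] = None
    excluded: bool = False
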