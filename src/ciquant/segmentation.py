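"""Image-cytometry stage: background correction, thresholding, nucleus
detection, and grouped-vs-individual cell labeling.

The stage mirrors a semi-automated workflow on multiplexed tissue sections:
marker channels are background-corrected and thresholded into an epithelial
(tumor) mask, manually drawn exclusion regions (normal ducts) are removed,
nuclei are detected on the nuclear channel, and each nucleus is assigned to
its connected epithelial component.  Components holding two or more nuclei
are multicellular groups; a component with exactly one nucleus and no
epithelial neighbor within a small radius is an individualized cell.
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.restoration import rolling_ball

from .datatypes import INDIVIDUAL, CellRecord, GroupRecord, RegionMasks
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: default minimal center-to-center distance of distinct nuclei (um)
NUCLEUS_MIN_DISTANCE_UM = 3.0
#: an isolated 1-nucleus component is "individual" only if no other
#: epithelial pixel lies within this radius (um)
NEIGHBOR_RADIUS_UM = 5.0


def correct_background(channel: np.ndarray, method: str = "rolling_ball",
                       radius: float = 50.0) -> np.ndarray:
    """Remove slowly varying background from one channel.

    ``rolling_ball`` subtracts a morphological rolling-ball background
    (radius in pixels); ``mode_subtract`` subtracts the histogram mode,
    which for tissue images is the empty-background level.  The output is
    clipped at zero, so a constant image maps to zero everywhere.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    if not channel.any():
        return channel.copy()
    if method == "rolling_ball":
        bg = rolling_ball(channel, radius=radius)
    elif method == "mode_subtract":
        # histogram mode on a coarse binning; robust to continuous values
        hist, edges = np.histogram(channel, bins=256)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        bg = np.full_like(channel, mode)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.clip(channel - bg, 0.0, None)


def threshold_channel(channel: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binarize a background-corrected channel.

    ``method`` is ``"otsu"`` or ``"fixed:<value>"``; fixed thresholds cut
    at ``intensity > value``.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if method == "otsu":
        if np.ptp(channel) == 0:
            raise DegenerateInputError(
                "constant channel has no threshold (Otsu undefined)")
        return channel > threshold_otsu(channel)
    if method.startswith("fixed:"):
        value = float(method.split(":", 1)[1])
        return channel > value
    raise ValueError(f"unknown threshold method {method!r}")


def apply_exclusions(tumor_mask: np.ndarray,
                     exclusion_mask: np.ndarray) -> np.ndarray:
    """Remove manually excluded regions (normal ducts) from the tumor mask."""
    if tumor_mask.shape != exclusion_mask.shape:
        raise ValueError(
            f"shape mismatch: tumor {tumor_mask.shape} vs "
            f"exclusion {exclusion_mask.shape}")
    return tumor_mask.astype(bool) & ~exclusion_mask.astype(bool)


def detect_nuclei(nuclear_channel: np.ndarray, pixel_size: float = 0.5,
                  min_distance_um: float = NUCLEUS_MIN_DISTANCE_UM,
                  threshold_rel: float = 0.25,
                  smoothing_sigma_um: float = 1.0) -> np.ndarray:
    """Detect nucleus centroids as local maxima of the smoothed channel.

    Returns an (n, 2) array of (row, col) coordinates.  Maxima closer than
    ``min_distance_um`` are merged (the brighter wins), which suppresses
    duplicate seeds inside one nucleus.
    """
    channel = np.asarray(nuclear_channel, dtype=np.float64)
    if not channel.any():
        return np.empty((0, 2), dtype=float)
    smoothed = ndimage.gaussian_filter(channel, sigma=smoothing_sigma_um / pixel_size)
    min_dist = max(int(round(min_distance_um / pixel_size)), 1)
    coords = peak_local_max(
        smoothed,
        footprint=disk(min_dist),  # Euclidean suppression radius
        threshold_abs=threshold_rel * float(smoothed.max()),
        exclude_border=False,
    )
    return coords.astype(float)


def label_groups(tumor_mask: np.ndarray, nuclei: np.ndarray,
                 pixel_size: float = 0.5, min_cells_group: int = 2,
                 neighbor_radius_um: float = NEIGHBOR_RADIUS_UM
                 ) -> tuple[list[GroupRecord], list[CellRecord]]:
    """Assign nuclei to connected epithelial components.

    Components of ``tumor_mask`` (8-connectivity, so diagonal contacts in
    single-file chains do not split a file) holding at least
    ``min_cells_group`` nuclei become :class:`GroupRecord` entries; a
    component with exactly one nucleus whose nearest other epithelial pixel
    is farther than ``neighbor_radius_um`` yields an individualized cell
    (``group_id`` 0).  A single-nucleus component *with* a close epithelial
    neighbor is attributed to the nearest group.  Nuclei outside the tumor
    mask are recorded as keratin-negative cells and take no part in group
    accounting.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    nuclei = np.asarray(nuclei, dtype=float).reshape(-1, 2)
    labels, n_comp = ndimage.label(tumor_mask, structure=np.ones((3, 3), int))

    if nuclei.size == 0:
        return [], []

    ij = np.clip(np.round(nuclei).astype(int), 0,
                 np.array(tumor_mask.shape) - 1)
    comp_of_nucleus = labels[ij[:, 0], ij[:, 1]]

    counts = np.bincount(comp_of_nucleus, minlength=n_comp + 1)
    # map raw component label -> emitted group id (stable order)
    group_id_of_comp = np.zeros(n_comp + 1, dtype=int)
    next_gid = 1
    singles: list[int] = []
    for comp in range(1, n_comp + 1):
        if counts[comp] >= min_cells_group:
            group_id_of_comp[comp] = next_gid
            next_gid += 1
        elif counts[comp] == 1:
            singles.append(comp)

    # resolve single-nucleus components: truly isolated -> individual;
    # within the neighbor radius of other epithelium -> merge into that group
    merged_into: dict[int, int] = {}
    objects = ndimage.find_objects(labels)
    if singles:
        r_px = neighbor_radius_um / pixel_size
        pad = int(math.ceil(r_px)) + 2
        h, w = labels.shape
        for comp in singles:
            sl = objects[comp - 1]
            win = (slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, h)),
                   slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, w)))
            lab_win = labels[win]
            own = lab_win == comp
            others = (lab_win > 0) & ~own
            if not others.any():
                continue
            dist, (iy, ix) = ndimage.distance_transform_edt(
                ~others, return_indices=True)
            dmin_idx = np.unravel_index(
                np.argmin(np.where(own, dist, np.inf)), dist.shape)
            if dist[dmin_idx] <= r_px:
                target = lab_win[iy[dmin_idx], ix[dmin_idx]]
                if group_id_of_comp[target] > 0:
                    merged_into[comp] = int(group_id_of_comp[target])

    areas = np.bincount(labels.ravel(), minlength=n_comp + 1)

    cells: list[CellRecord] = []
    for (y, x), comp in zip(nuclei, comp_of_nucleus):
        if comp == 0:
            cells.append(CellRecord(centroid=(y, x), group_id=INDIVIDUAL,
                                    keratin_positive=False))
        elif group_id_of_comp[comp] > 0:
            cells.append(CellRecord(centroid=(y, x),
                                    group_id=int(group_id_of_comp[comp]),
                                    keratin_positive=True))
        elif comp in merged_into:
            cells.append(CellRecord(centroid=(y, x),
                                    group_id=merged_into[comp],
                                    keratin_positive=True))
        else:
            cells.append(CellRecord(centroid=(y, x), group_id=INDIVIDUAL,
                                    keratin_positive=True))

    groups: list[GroupRecord] = []
    for comp in range(1, n_comp + 1):
        gid = group_id_of_comp[comp]
        if gid == 0:
            continue
        n_cells = int(counts[comp]) + sum(1 for c, g in merged_into.items()
                                          if g == gid)
        sl = objects[comp - 1]
        groups.append(GroupRecord(
            group_id=int(gid),
            area_um2=float(areas[comp]) * pixel_size ** 2,
            cell_count=n_cells,
            compartment="fibrous",
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
        ))
    return groups, cells


def assign_compartments(cells: list[CellRecord], masks: RegionMasks
                        ) -> list[CellRecord]:
    """Label each cell by the compartment its centroid falls in.

    Adipose membership wins over core (invading cells inside the adipose
    band stay adipose); anything else is fibrous.  Centroids outside the
    tissue mask are labeled fibrous with a warning.
    """
    shape = np.array(masks.tissue.shape)
    for cell in cells:
        i, j = np.clip(np.round(cell.centroid).astype(int), 0, shape - 1)
        if not masks.tissue[i, j]:
            logger.warning("cell centroid (%.0f, %.0f) outside tissue mask",
                           *cell.centroid)
            cell.compartment = "fibrous"
        elif masks.adipose[i, j]:
            cell.compartment = "adipose"
        elif masks.core is not None and masks.core[i, j]:
            cell.compartment = "core"
        else:
            cell.compartment = "fibrous"
    return cells


def majority_group_compartments(groups: list[GroupRecord],
                                cells: list[CellRecord]) -> list[GroupRecord]:
    """Set each group's compartment to the majority vote of its cells."""
    from collections import Counter

    by_gid: dict[int, Counter] = {}
    for c in cells:
        if c.group_id != INDIVIDUAL:
            by_gid.setdefault(c.group_id, Counter())[c.compartment] += 1
    for g in groups:
        if g.group_id in by_gid:
            g.compartment = by_gid[g.group_id].most_common(1)[0][0]
    return groups
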