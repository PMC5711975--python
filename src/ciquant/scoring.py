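"""Collective-invasion scoring: area fractions, the CI score, the
individualized-cell percentage, and positivity calls.

The CI score of a section is

    CI = (% of total tumor area lying in adipose tissue)
         / (% of adipose tissue in the whole section)

so a score of 1 means the tumor occupies adipose tissue exactly in
proportion to its availability; scores above 1 indicate preferential
invasion of the fat.  Sections without adipose tissue cannot be scored and
are excluded.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .datatypes import INDIVIDUAL, CellRecord, RegionMasks
from .errors import EmptyRegionError, ExcludedSlideError

logger = logging.getLogger(__name__)

#: minimal grouped-cell percentages for a collective-invasion-positive call,
#: per subtype, as (fibrous, adipose); comparisons are inclusive
POSITIVITY_THRESHOLDS = {"IDC": (95.0, 95.0), "ILC": (75.0, 90.0)}


def area_fractions(masks: RegionMasks) -> tuple[float, float]:
    """Percent adipose of the whole section, and percent tumor in adipose.

    Returns ``(pct_adipose, pct_tumor_in_adipose)`` where the first is
    100*|adipose|/|tissue| and the second 100*|tumor & adipose|/|tumor|.
    An empty tumor mask yields 0 for the second with a warning; an empty
    tissue mask is an error.
    """
    n_tissue = int(masks.tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    pct_adipose = 100.0 * masks.adipose.sum() / n_tissue
    n_tumor = int(masks.tumor.sum())
    if n_tumor == 0:
        logger.warning("empty tumor mask: pct_tumor_in_adipose set to 0")
        return float(pct_adipose), 0.0
    pct_tia = 100.0 * (masks.tumor & masks.adipose).sum() / n_tumor
    return float(pct_adipose), float(pct_tia)


def ci_score(pct_tumor_in_adipose: float, pct_adipose: float) -> float:
    """CI score = pct_tumor_in_adipose / pct_adipose.

    Raises
    ------
    ExcludedSlideError
        When ``pct_adipose`` is 0; such sections cannot be scored and are
        excluded from the analysis rather than given a numeric score.
    """
    if pct_adipose <= 0:
        raise ExcludedSlideError(
            "section contains no adipose tissue; CI score undefined")
    if not 0 <= pct_tumor_in_adipose <= 100:
        raise ValueError("pct_tumor_in_adipose must lie in [0, 100]")
    if pct_adipose > 100:
        raise ValueError("pct_adipose must lie in (0, 100]")
    return pct_tumor_in_adipose / pct_adipose


def individualized_percentage(cells: list[CellRecord],
                              compartments: set[str] | None = None) -> float:
    """Percent of keratin-positive cells that are individualized.

    ``compartments`` restricts the count to a region (e.g. the peritumor
    invasion zone ``{"fibrous", "adipose"}``); ``None`` uses all cells.
    """
    pool = [c for c in cells if c.keratin_positive
            and (compartments is None or c.compartment in compartments)]
    if not pool:
        raise EmptyRegionError("no keratin-positive cells in the region")
    n_ind = sum(1 for c in pool if c.group_id == INDIVIDUAL)
    return 100.0 * n_ind / len(pool)


def collective_positivity(grouped_fraction_fibrous: float,
                          grouped_fraction_adipose: float,
                          subtype: str) -> bool:
    """Positivity call for collective invasion.

    A sample is positive when the percentage of cells in multicellular
    organization reaches the subtype thresholds in both compartments
    (inclusive): 95/95 for IDC, 75 (fibrous) / 90 (adipose) for ILC.
    """
    if subtype not in POSITIVITY_THRESHOLDS:
        raise ValueError(f"unknown subtype {subtype!r}")
    for frac in (grouped_fraction_fibrous, grouped_fraction_adipose):
        if not 0 <= frac <= 100:
            raise ValueError("grouped fractions must lie in [0, 100]")
    thr_fib, thr_adi = POSITIVITY_THRESHOLDS[subtype]
    return (grouped_fraction_fibrous >= thr_fib
            and grouped_fraction_adipose >= thr_adi)


def score_concordance(score_a, score_b, method: str = "spearman"
                      ) -> tuple[float, float, int]:
    """Concordance of two per-slide scorings (e.g. automated vs visual).

    Pairs with a missing value in either score are dropped.  Returns
    ``(correlation, two_sided_p, n_complete_pairs)``; Spearman rank
    correlation by default (the visual score is ordinal), Pearson on
    request.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired (same length)")
    keep = np.isfinite(a) & np.isfinite(b)
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if method == "spearman":
        rho, p = stats.spearmanr(a[keep], b[keep])
    elif method == "pearson":
        rho, p = stats.pearsonr(a[keep], b[keep])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), n
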