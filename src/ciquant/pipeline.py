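"""Batch orchestration: slide quantification and survival analysis.

``run_slide_pipeline`` runs threshold -> exclusion -> area fractions ->
CI score -> cell classification over a directory of slides and returns one
row per slide.  ``run_survival_analysis`` joins per-patient CI scores with
follow-up data, splits at the median, and emits Kaplan-Meier curves, the
log-rank comparison, the O/E hazard ratio, and the secondary group
comparisons (score by metastasis status, correlations with covariates).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io, scoring, segmentation, survival
from .datatypes import RegionMasks
from .errors import CiquantError, EmptyRegionError, ExcludedSlideError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one batch run (YAML-serializable)."""

    image_dir: str = "slides"
    mask_dir: str = "masks"
    cohort_table: str = "cohort.csv"
    output_dir: str = "results"
    segment_channel: str = "ecadherin"
    background_method: str = "mode_subtract"
    threshold_method: str = "otsu"
    neighbor_radius_um: float = segmentation.NEIGHBOR_RADIUS_UM
    nucleus_min_distance_um: float = segmentation.NUCLEUS_MIN_DISTANCE_UM
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def quantify_slide(image, masks: RegionMasks, config: RunConfig) -> dict:
    """Quantify one slide from its image and supplied region masks."""
    seg_ch = segmentation.correct_background(
        image[config.segment_channel], method=config.background_method)
    tumor = segmentation.threshold_channel(seg_ch, method=config.threshold_method)
    if masks.exclusion is not None:
        tumor = segmentation.apply_exclusions(tumor, masks.exclusion)
    tumor &= masks.tissue
    masks = RegionMasks(tissue=masks.tissue, adipose=masks.adipose,
                        tumor=tumor, exclusion=masks.exclusion,
                        core=masks.core, provenance=masks.provenance)

    pct_adipose, pct_tia = scoring.area_fractions(masks)
    try:
        score = scoring.ci_score(pct_tia, pct_adipose)
        excluded = False
    except ExcludedSlideError:
        score, excluded = None, True

    nuc = segmentation.correct_background(
        image["nuclear"], method=config.background_method)
    nuclei = segmentation.detect_nuclei(
        nuc, pixel_size=image.pixel_size,
        min_distance_um=config.nucleus_min_distance_um)
    groups, cells = segmentation.label_groups(
        tumor, nuclei, pixel_size=image.pixel_size,
        neighbor_radius_um=config.neighbor_radius_um)
    cells = segmentation.assign_compartments(cells, masks)
    groups = segmentation.majority_group_compartments(groups, cells)

    def grouped_pct(compartment):
        try:
            return 100.0 - scoring.individualized_percentage(
                cells, compartments={compartment})
        except EmptyRegionError:
            return None

    try:
        ind_pct = scoring.individualized_percentage(
            cells, compartments={"fibrous", "adipose"})
    except EmptyRegionError:
        ind_pct = None

    return {
        "slide_id": image.slide_id,
        "pct_adipose": pct_adipose,
        "pct_tumor_in_adipose": pct_tia,
        "ci_score": score,
        "excluded": excluded,
        "individualized_pct": ind_pct,
        "grouped_pct_fibrous": grouped_pct("fibrous"),
        "grouped_pct_adipose": grouped_pct("adipose"),
        "n_groups": len(groups),
        "n_cells": sum(1 for c in cells if c.keratin_positive),
    }


def run_slide_pipeline(config: RunConfig) -> pd.DataFrame:
    """Quantify every slide under ``config.image_dir``.

    A slide that fails (unreadable image, mismatched masks) is reported as
    a row with ``error`` set, without aborting the run.  Results and a run
    manifest (config + hash + seed) are written to ``config.output_dir``.
    """
    image_dir = Path(config.image_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    slide_paths = sorted(image_dir.glob("*.tif"))
    if not slide_paths:
        raise FileNotFoundError(f"no .tif slides under {image_dir}")
    for path in slide_paths:
        slide_id = path.stem
        try:
            image = io.read_image(path)
            masks = io.read_masks(Path(config.mask_dir), slide_id, image.shape)
            rows.append(quantify_slide(image, masks, config))
        except (OSError, ValueError, CiquantError) as exc:
            logger.error("slide %s failed: %s", slide_id, exc)
            rows.append({"slide_id": slide_id, "error": str(exc)})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "slide_quant.csv", index=False)
    manifest = {"config": dataclasses.asdict(config),
                "config_hash": config.hash(), "seed": config.seed,
                "n_slides": len(rows)}
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


@dataclass
class SurvivalResult:
    """Outcome of the median-split survival stratification."""

    group_sizes: dict[str, int]
    km_curves: dict[str, survival.KaplanMeierCurve]
    logrank_chi2: float
    p_value: float
    hazard_ratio: Optional[float]
    hr_ci95: Optional[tuple[float, float]]
    median_cutoff: float
    n_missing_scores: int
    comparisons: dict = field(default_factory=dict)


def run_survival_analysis(cohort: pd.DataFrame,
                          score_column: str = "ci_score",
                          output_dir: Optional[Path] = None) -> SurvivalResult:
    """Median-split survival stratification of a cohort table.

    ``cohort`` needs ``time`` (months), ``event`` (0/1) and the score
    column; optional covariate columns (``lymph_node_status``, ``grade``,
    ``tumor_size_cm``, ``menopausal_status``) are rank-correlated with the
    score as negative controls.
    """
    required = {score_column, "time", "event"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")

    labels, median, n_missing = survival.dichotomize_median(
        cohort[score_column].to_numpy())
    keep = labels != ""
    data = cohort.loc[keep].copy()
    data["ci_group"] = labels[keep]
    sizes = data["ci_group"].value_counts().to_dict()
    if len(sizes) < 2:
        raise ValueError(
            f"median split produced a single stratum ({sizes}); "
            "both 'high' and 'low' groups are required")

    km = {g: survival.kaplan_meier(sub["time"], sub["event"])
          for g, sub in data.groupby("ci_group")}
    chi2, p = survival.logrank_test(data["ci_group"], data["time"],
                                    data["event"], group_order=["high", "low"])
    try:
        hr, ci = survival.hazard_ratio_logrank(
            data["ci_group"], data["time"], data["event"],
            group_order=["high", "low"])
    except CiquantError as exc:
        logger.warning("hazard ratio undefined: %s", exc)
        hr, ci = None, None

    comparisons = {}
    with_dm = data.loc[data["event"] == 1, score_column]
    without_dm = data.loc[data["event"] == 0, score_column]
    if len(with_dm) and len(without_dm):
        u, p_mw = survival.mann_whitney(with_dm, without_dm)
        comparisons["ci_score_by_metastasis"] = {
            "U": u, "p": p_mw, "n_dm": len(with_dm), "n_no_dm": len(without_dm)}
    for cov in ("lymph_node_status", "grade", "tumor_size_cm",
                "menopausal_status"):
        if cov in data.columns:
            rho, p_c, n = scoring.score_concordance(
                data[score_column], pd.to_numeric(data[cov], errors="coerce"))
            comparisons[f"ci_score_vs_{cov}"] = {"rho": rho, "p": p_c, "n": n}

    result = SurvivalResult(
        group_sizes={k: int(v) for k, v in sizes.items()},
        km_curves=km, logrank_chi2=chi2, p_value=p,
        hazard_ratio=hr, hr_ci95=ci, median_cutoff=median,
        n_missing_scores=n_missing, comparisons=comparisons)

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        steps = []
        for g, curve in km.items():
            t, s = curve.steps()
            steps.append(pd.DataFrame({"group": g, "time": t, "survival": s}))
        pd.concat(steps).to_csv(output_dir / "km_steps.csv", index=False)
        summary = {
            "group_sizes": result.group_sizes,
            "median_cutoff": median,
            "logrank_chi2": chi2, "p_value": p,
            "hazard_ratio": hr, "hr_ci95": list(ci) if ci else None,
            "n_missing_scores": n_missing,
            "comparisons": comparisons,
        }
        (output_dir / "survival_summary.json").write_text(
            json.dumps(summary, indent=2, default=float))
    return result
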