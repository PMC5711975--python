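"""Synthetic tissue-section and patient-cohort generators.

Every downstream stage of the pipeline (thresholding, group labeling, CI
scoring, survival stratification) is validated against slides and cohorts
with *known* ground truth produced here.

A synthetic slide emulates the geometry of a breast-tumor section at its
adipose margin: a central tumor core, surrounding fibrous stroma with
spindle-shaped stromal cells, an adipocyte-rich marginal band, and invading
multicellular groups (compact nests, broad strands, and thin single-file
chains) plus a small fraction of fully individualized cells.  Marker
channels are rendered from that geometry: DAPI-like nuclear signal on every
nucleus, pan-cytokeratin on every epithelial cell body, junctional
E-cadherin for the ductal (IDC) profile, CD44 for the lobular (ILC)
profile, and vimentin on stromal cells only.

A synthetic cohort emulates a follow-up study in which the hazard of
distant metastasis depends on whether a patient's collective-invasion score
lies above the cohort median, with independent exponential censoring capped
at a 60-month follow-up window.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import MultiChannelImage
from .errors import PackingError

# rendered signal amplitudes (arbitrary intensity units, 8-bit-like scale)
AMPLITUDES = {
    "nuclear": 255.0,
    "keratin": 200.0,
    "ecadherin": 180.0,
    "cd44": 180.0,
    "vimentin": 200.0,
    "adipocyte_rim": 12.0,
}

_PATTERNS = ("nest", "strand", "indian_file")


@dataclass
class SyntheticSlideParams:
    """Parameters of one synthetic slide.

    Lengths are micrometers; fractions are in [0, 1].  ``marker_profile``
    selects which junctional marker the epithelium carries: ``"IDC"``
    renders E-cadherin, ``"ILC"`` renders CD44 instead.
    """

    image_size: tuple[int, int] = (768, 768)
    pixel_size: float = 0.5
    adipose_fraction_target: float = 0.35
    adipocyte_radius_range: tuple[float, float] = (15.0, 35.0)
    tumor_core_fraction: float = 0.05
    n_groups: int = 30
    group_pattern_mix: dict[str, float] = field(
        default_factory=lambda: {"nest": 0.4, "strand": 0.3, "indian_file": 0.3}
    )
    group_size_range: tuple[int, int] = (4, 16)
    individualized_cell_fraction: float = 0.0075
    min_separation: float = 10.0
    marker_profile: str = "IDC"
    noise_level: float = 1.0
    seed: int = 0
    # placement of invading groups between the two peritumor compartments
    group_compartment_mix: dict[str, float] = field(
        default_factory=lambda: {"fibrous": 0.5, "adipose": 0.5}
    )
    n_stromal_cells: int = 40
    n_ducts: int = 0
    cell_radius: float = 4.0
    nucleus_radius: float = 2.2

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.group_pattern_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("group_pattern_mix proportions must sum to 1")
        if set(self.group_pattern_mix) - set(_PATTERNS):
            raise ValueError(f"unknown pattern in mix: {self.group_pattern_mix}")
        if not math.isclose(sum(self.group_compartment_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("group_compartment_mix proportions must sum to 1")
        if not 0.0 <= self.individualized_cell_fraction <= 1.0:
            raise ValueError("individualized_cell_fraction must lie in [0, 1]")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.group_size_range[0] < 2:
            raise ValueError("groups hold at least 2 cells")
        if not 0.0 <= self.adipose_fraction_target < 1.0:
            raise ValueError("adipose_fraction_target must lie in [0, 1)")
        if not 0.0 <= self.tumor_core_fraction < 1.0:
            raise ValueError("tumor_core_fraction must lie in [0, 1)")
        if self.marker_profile not in ("IDC", "ILC"):
            raise ValueError("marker_profile must be 'IDC' or 'ILC'")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class GroundTruthSlide:
    """Exact geometry underlying a rendered slide.

    ``cell_table`` lists every epithelial tumor cell (core, grouped and
    individual) with its nucleus centroid in pixel coordinates, its group id
    (0 = individualized cell) and its compartment.  The ``true_*`` fields
    are computed from the masks and counts before any rendering noise, so
    they satisfy the CI-score identity exactly.
    """

    adipose_mask: np.ndarray
    tumor_mask: np.ndarray
    exclusion_mask: np.ndarray
    tissue_mask: np.ndarray
    core_mask: np.ndarray
    stromal_mask: np.ndarray
    cell_table: pd.DataFrame
    true_pct_adipose: float
    true_pct_tumor_in_adipose: float
    true_ci_score: Optional[float]
    true_individualized_pct: float
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(AMPLITUDES))


# ---------------------------------------------------------------------------
# geometry helpers (pixel units)
# ---------------------------------------------------------------------------

def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = yy * yy + xx * xx <= radius * radius
    return yy[keep], xx[keep]


def _stamp(mask_or_img: np.ndarray, y: float, x: float,
           dy: np.ndarray, dx: np.ndarray, value: float | bool) -> None:
    """Paint a precomputed footprint at (y, x), clipped to the image."""
    h, w = mask_or_img.shape
    ys = (np.round(dy + y)).astype(int)
    xs = (np.round(dx + x)).astype(int)
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    ys, xs = ys[keep], xs[keep]
    if mask_or_img.dtype == bool:
        mask_or_img[ys, xs] = value
    else:
        np.maximum.at(mask_or_img, (ys, xs), value)


def _hex_lattice(n: int, spacing: float) -> np.ndarray:
    """First n points of a hexagonal lattice, closest to the origin first."""
    m = int(math.ceil(math.sqrt(n))) + 2
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            y = i * spacing * math.sqrt(3) / 2
            x = (j + 0.5 * (i % 2)) * spacing
            pts.append((y, x))
    pts = np.asarray(pts)
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]), kind="stable")
    return pts[order[:n]]


def _group_layout(rng: np.random.Generator, pattern: str, n_cells: int,
                  spacing: float) -> np.ndarray:
    """Nucleus-center offsets (px) for one multicellular group, centered."""
    if pattern == "nest":
        pts = _hex_lattice(n_cells, spacing)
    elif pattern == "strand":
        width = int(rng.integers(3, 7))
        length = int(math.ceil(n_cells / width))
        ii, jj = np.divmod(np.arange(n_cells), width)
        pts = np.column_stack([jj * spacing, ii * spacing]).astype(float)
        pts += rng.normal(scale=0.06 * spacing, size=pts.shape)
    elif pattern == "indian_file":
        width = int(rng.integers(1, 4))
        length = int(math.ceil(n_cells / width))
        ii, jj = np.divmod(np.arange(n_cells), width)
        # gentle curvature so files are not axis-aligned rectangles
        curve = 0.8 * spacing * np.sin(ii / max(length, 1) * math.pi)
        pts = np.column_stack([jj * spacing + curve, ii * spacing]).astype(float)
        pts += rng.normal(scale=0.08 * spacing, size=pts.shape)
    else:  # pragma: no cover - guarded by params validation
        raise ValueError(f"unknown pattern {pattern!r}")
    pts -= pts.mean(axis=0)
    theta = rng.uniform(0, 2 * math.pi)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    return pts @ rot.T


class _Packer:
    """Rejection-sampling placement of non-overlapping objects.

    An object is a set of circles (cell bodies) given as center offsets
    plus a common radius; collisions are checked circle-against-circle, so
    elongated single-file chains pack between earlier objects instead of
    claiming their whole bounding disc.
    """

    def __init__(self, rng: np.random.Generator, min_sep_px: float,
                 max_tries: int = 6000):
        self.rng = rng
        self.min_sep = min_sep_px
        self.max_tries = max_tries
        self._pts = np.empty((0, 2), dtype=float)
        self._margin = np.empty(0, dtype=float)

    def place(self, radius: float, lo_y: float, hi_y: float,
              lo_x: float, hi_x: float, offsets: np.ndarray | None = None,
              reject_fn=None, sep: float | None = None,
              what: str = "object") -> tuple[float, float]:
        """Place one object; returns its center (y, x).

        ``offsets`` are the member-circle centers relative to the object
        center (default: one circle at the center); the sampling box
        ``[lo_y, hi_y] x [lo_x, hi_x]`` constrains every member center.
        ``sep`` overrides the packer-wide separation for this object (two
        objects clear each other by the mean of their separations).
        """
        if offsets is None:
            offsets = np.zeros((1, 2))
        if sep is None:
            sep = self.min_sep
        if hi_y <= lo_y or hi_x <= lo_x:
            raise PackingError(
                f"no room for {what}: region "
                f"y=[{lo_y:.0f},{hi_y:.0f}] x=[{lo_x:.0f},{hi_x:.0f}]"
            )
        for _ in range(self.max_tries):
            y = self.rng.uniform(lo_y, hi_y)
            x = self.rng.uniform(lo_x, hi_x)
            cand = offsets + (y, x)
            if (cand[:, 0].min() < lo_y or cand[:, 0].max() > hi_y
                    or cand[:, 1].min() < lo_x or cand[:, 1].max() > hi_x):
                continue
            if reject_fn is not None and any(
                    reject_fn(cy, cx, radius) for cy, cx in cand):
                continue
            if self._pts.size:
                d = np.hypot(self._pts[:, 0:1] - cand[None, :, 0],
                             self._pts[:, 1:2] - cand[None, :, 1])
                if np.any(d < self._margin[:, None] + radius + sep / 2.0):
                    continue
            self._pts = np.vstack([self._pts, cand])
            self._margin = np.concatenate([
                self._margin, np.full(len(cand), radius + sep / 2.0)])
            return y, x
        raise PackingError(
            f"could not place {what} ({len(offsets)} circle(s), radius "
            f"{radius:.0f}px) after {self.max_tries} tries at "
            f"min_separation {self.min_sep:.0f}px"
        )


# ---------------------------------------------------------------------------
# slide generation
# ---------------------------------------------------------------------------

def generate_slide(params: SyntheticSlideParams
                   ) -> tuple[MultiChannelImage, GroundTruthSlide]:
    """Render one synthetic slide and return it with its ground truth.

    Raises
    ------
    PackingError
        If the requested number of objects cannot be placed at
        ``min_separation`` inside the available compartments.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    px = params.pixel_size
    sep_px = params.min_separation / px
    r_cell = params.cell_radius / px
    r_nuc = params.nucleus_radius / px
    spacing = 1.7 * r_cell

    tissue = np.ones((h, w), dtype=bool)

    # --- adipose band: rightmost columns, width set by the area target ----
    band_w = int(round(params.adipose_fraction_target * w))
    adipose_x0 = w - band_w
    adipose = np.zeros((h, w), dtype=bool)
    if band_w > 0:
        adipose[:, adipose_x0:] = True

    # --- tumor core: ellipse against the left edge ------------------------
    core = np.zeros((h, w), dtype=bool)
    core_area = params.tumor_core_fraction * h * w
    if core_area > 0:
        ax = math.sqrt(core_area / (2 * math.pi))  # semi-axis along x
        ay = 2 * ax
        ay = min(ay, 0.45 * h)
        ax = core_area / (math.pi * ay)
        max_ax = 0.45 * max(adipose_x0, 1)
        if ax > max_ax:
            raise PackingError("tumor core does not fit left of the adipose band")
        cy, cx = h / 2.0, ax + 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        core = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    else:
        ay = ax = 0.0
        cy = cx = -1e9

    def in_core_halo(y: float, x: float, r: float) -> bool:
        if core_area <= 0:
            return False
        return ((y - cy) / (ay + r + sep_px)) ** 2 + \
               ((x - cx) / (ax + r + sep_px)) ** 2 <= 1.0

    packer = _Packer(rng, sep_px)
    margin = sep_px

    def fibrous_box(r: float) -> tuple[float, float, float, float]:
        return (r + margin, h - r - margin, r + margin,
                max(adipose_x0 - r - margin, r + margin))

    def adipose_box(r: float) -> tuple[float, float, float, float]:
        return (r + margin, h - r - margin,
                adipose_x0 + r + margin, w - r - margin)

    # --- invading multicellular groups ------------------------------------
    patterns = list(params.group_pattern_mix)
    p_pattern = np.array([params.group_pattern_mix[k] for k in patterns])
    compartments = list(params.group_compartment_mix)
    p_comp = np.array([params.group_compartment_mix[k] for k in compartments])

    def _allocate(n: int) -> list[str]:
        # largest-remainder allocation so compartment counts are exact
        raw = p_comp * n
        counts = np.floor(raw).astype(int)
        for k in np.argsort(raw - counts)[::-1][: n - counts.sum()]:
            counts[k] += 1
        out = [c for c, k in zip(compartments, counts) for _ in range(k)]
        return [out[i] for i in rng.permutation(n)]

    group_comps = _allocate(params.n_groups)
    group_cells: list[tuple[float, float, int, str]] = []  # y, x, gid, comp
    next_gid = 2  # gid 1 reserved for the tumor core
    for comp in group_comps:
        pattern = patterns[rng.choice(len(patterns), p=p_pattern)]
        n_cells = int(rng.integers(params.group_size_range[0],
                                   params.group_size_range[1] + 1))
        box = adipose_box(r_cell) if comp == "adipose" else fibrous_box(r_cell)
        # elongated layouts may not fit at their first random orientation;
        # redraw the layout a few times before declaring the slide infeasible
        for attempt in range(4):
            offsets = _group_layout(rng, pattern, n_cells, spacing)
            try:
                y0, x0 = packer.place(r_cell, *box, offsets=offsets,
                                      reject_fn=in_core_halo,
                                      what=f"{pattern} group")
                break
            except PackingError:
                if attempt == 3:
                    raise
        for oy, ox in offsets:
            group_cells.append((y0 + oy, x0 + ox, next_gid, comp))
        next_gid += 1

    # --- individualized cells ---------------------------------------------
    n_grouped = len(group_cells)
    f = params.individualized_cell_fraction
    n_ind = int(round(f / (1.0 - f) * n_grouped)) if f < 1.0 else 0
    ind_cells: list[tuple[float, float, str]] = []
    for comp in _allocate(n_ind):
        box = adipose_box(r_cell) if comp == "adipose" else fibrous_box(r_cell)
        y0, x0 = packer.place(r_cell, *box,
                              reject_fn=in_core_halo, what="individual cell")
        ind_cells.append((y0, x0, comp))

    # --- normal ducts (keratin-positive, not tumor) ------------------------
    duct_outer = 30.0 / px
    duct_ring = 8.0 / px
    exclusion = np.zeros((h, w), dtype=bool)
    duct_centers: list[tuple[float, float]] = []
    for _ in range(params.n_ducts):
        y0, x0 = packer.place(duct_outer, *fibrous_box(duct_outer),
                              reject_fn=in_core_halo, what="duct")
        duct_centers.append((y0, x0))
        dy, dx = _disk_offsets(duct_outer + 4.0 / px)
        _stamp(exclusion, y0, x0, dy, dx, True)

    # --- stromal spindle cells ---------------------------------------------
    strom_a = 8.0 / px  # long semi-axis
    strom_b = 2.5 / px
    strom_sep = 2.0 / px  # stroma is scenery: only a small clearance needed
    stromal: list[tuple[float, float, float]] = []  # y, x, angle
    for _ in range(params.n_stromal_cells):
        y0, x0 = packer.place(strom_a, *fibrous_box(strom_a),
                              reject_fn=in_core_halo, sep=strom_sep,
                              what="stromal cell")
        stromal.append((y0, x0, rng.uniform(0, math.pi)))

    # --- adipocytes: packed discs inside the band (rendered scenery) -------
    adipocytes: list[tuple[float, float, float]] = []
    if band_w > 0:
        lo_r, hi_r = (r / px for r in params.adipocyte_radius_range)
        target = 0.55 * band_w * h
        filled, tries = 0.0, 0
        apack = _Packer(rng, min_sep_px=1.0, max_tries=200)
        while filled < target and tries < 4 * params.n_groups + 400:
            tries += 1
            r = rng.uniform(lo_r, hi_r)
            try:
                y0, x0 = apack.place(r, r, h - r, adipose_x0 + r, w - r)
            except PackingError:
                break
            adipocytes.append((y0, x0, r))
            filled += math.pi * r * r

    # --- build masks --------------------------------------------------------
    tumor = core.copy()
    dy_c, dx_c = _disk_offsets(r_cell)
    for y0, x0, _, _ in group_cells:
        _stamp(tumor, y0, x0, dy_c, dx_c, True)
    for y0, x0, _ in ind_cells:
        _stamp(tumor, y0, x0, dy_c, dx_c, True)

    stromal_mask = np.zeros((h, w), dtype=bool)
    e_dy, e_dx = np.mgrid[-int(strom_a) - 1 : int(strom_a) + 2,
                          -int(strom_a) - 1 : int(strom_a) + 2]
    for y0, x0, ang in stromal:
        u = e_dy * math.cos(ang) + e_dx * math.sin(ang)
        v = -e_dy * math.sin(ang) + e_dx * math.cos(ang)
        keep = (u / strom_a) ** 2 + (v / strom_b) ** 2 <= 1.0
        _stamp(stromal_mask, y0, x0, e_dy[keep], e_dx[keep], True)

    # --- ground-truth cell table -------------------------------------------
    rows: list[tuple[float, float, int, str]] = []
    # core nuclei on a jittered hex grid clipped to the core ellipse
    if core_area > 0:
        n_core_max = int(core_area / (spacing * spacing))
        lattice = _hex_lattice(max(n_core_max, 1), spacing)
        jitter = rng.normal(scale=0.05 * spacing, size=lattice.shape)
        pts = lattice + jitter
        inside = ((pts[:, 0] / (ay - r_nuc)) ** 2
                  + (pts[:, 1] / max(ax - r_nuc, 1e-9)) ** 2) <= 1.0
        for oy, ox in pts[inside]:
            rows.append((cy + oy, cx + ox, 1, "core"))
    for y0, x0, gid, comp in group_cells:
        rows.append((y0, x0, gid, comp))
    for y0, x0, comp in ind_cells:
        rows.append((y0, x0, 0, comp))
    cell_table = pd.DataFrame(rows, columns=["row", "col", "group_id",
                                             "compartment"])

    # --- render channels ----------------------------------------------------
    amp = dict(AMPLITUDES)
    chans = {name: np.zeros((h, w), dtype=np.float64)
             for name in ("nuclear", "ecadherin", "keratin", "vimentin", "cd44")}

    chans["keratin"][tumor] = amp["keratin"]
    junctional = "ecadherin" if params.marker_profile == "IDC" else "cd44"
    chans[junctional][tumor] = amp[junctional]
    chans["vimentin"][stromal_mask] = amp["vimentin"]

    dy_n, dx_n = _disk_offsets(r_nuc)
    for y0, x0, _, _ in rows:
        _stamp(chans["nuclear"], y0, x0, dy_n, dx_n, amp["nuclear"])
    # stromal nuclei: small elongated blobs
    n_dy, n_dx = np.mgrid[-int(strom_a) : int(strom_a) + 1,
                          -int(strom_a) : int(strom_a) + 1]
    for y0, x0, ang in stromal:
        u = n_dy * math.cos(ang) + n_dx * math.sin(ang)
        v = -n_dy * math.sin(ang) + n_dx * math.cos(ang)
        keep = (u / (0.55 * strom_a)) ** 2 + (v / (0.8 * strom_b)) ** 2 <= 1.0
        _stamp(chans["nuclear"], y0, x0, n_dy[keep], n_dx[keep],
               amp["nuclear"])
    # duct epithelium: keratin-positive ring with nuclei, not in tumor mask
    for y0, x0 in duct_centers:
        dy_o, dx_o = _disk_offsets(duct_outer)
        rr = np.hypot(dy_o, dx_o)
        ring = rr >= duct_outer - duct_ring
        _stamp(chans["keratin"], y0, x0, dy_o[ring], dx_o[ring], amp["keratin"])
        _stamp(chans["ecadherin"], y0, x0, dy_o[ring], dx_o[ring],
               amp["ecadherin"])
        n_on_ring = int(2 * math.pi * (duct_outer - duct_ring / 2) / spacing)
        for k in range(n_on_ring):
            th = 2 * math.pi * k / n_on_ring
            ny = y0 + (duct_outer - duct_ring / 2) * math.sin(th)
            nx = x0 + (duct_outer - duct_ring / 2) * math.cos(th)
            _stamp(chans["nuclear"], ny, nx, dy_n, dx_n, amp["nuclear"])
    # adipocyte rims: faint autofluorescence on the vimentin channel
    for y0, x0, r in adipocytes:
        dy_o, dx_o = _disk_offsets(r)
        rim = np.hypot(dy_o, dx_o) >= r - 2.0
        _stamp(chans["vimentin"], y0, x0, dy_o[rim], dx_o[rim],
               amp["adipocyte_rim"])

    for name in chans:
        chans[name] = ndimage.gaussian_filter(chans[name], sigma=1.0)

    nl = params.noise_level
    if nl > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        for name in chans:
            coarse = rng.normal(size=(9, 9))
            bg = ndimage.zoom(coarse, (h / 9, w / 9), order=3)[:h, :w]
            bg = (bg - bg.min()) * (12.0 * nl / max(np.ptp(bg), 1e-12))
            gdir = rng.uniform(0, 2 * math.pi)
            grad = (yy * math.sin(gdir) + xx * math.cos(gdir))
            grad = (grad - grad.min()) / max(np.ptp(grad), 1e-12) * 8.0 * nl
            img = chans[name] + bg + grad
            img += rng.normal(size=(h, w)) * nl * (2.0 + 0.6 * np.sqrt(img))
            chans[name] = np.clip(img, 0.0, None)

    image = MultiChannelImage(channels={k: v.astype(np.float32)
                                        for k, v in chans.items()},
                              pixel_size=px, slide_id=f"synthetic-{params.seed}")

    # --- ground-truth quantities -------------------------------------------
    true_pct_adipose = 100.0 * adipose.sum() / tissue.sum()
    tumor_px = tumor.sum()
    true_pct_tia = (100.0 * (tumor & adipose).sum() / tumor_px
                    if tumor_px else 0.0)
    true_ci = (true_pct_tia / true_pct_adipose
               if true_pct_adipose > 0 else None)
    peri = cell_table[cell_table.compartment != "core"]
    true_ind_pct = (100.0 * (peri.group_id == 0).sum() / len(peri)
                    if len(peri) else 0.0)

    truth = GroundTruthSlide(
        adipose_mask=adipose,
        tumor_mask=tumor,
        exclusion_mask=exclusion,
        tissue_mask=tissue,
        core_mask=core,
        stromal_mask=stromal_mask,
        cell_table=cell_table,
        true_pct_adipose=float(true_pct_adipose),
        true_pct_tumor_in_adipose=float(true_pct_tia),
        true_ci_score=None if true_ci is None else float(true_ci),
        true_individualized_pct=float(true_ind_pct),
        amplitudes=amp,
    )
    return image, truth


#: mean individualized-cell percentages emulated per subtype: ductal
#: carcinomas shed almost no single cells, lobular ones noticeably more
INDIVIDUALIZED_FRACTION = {"IDC": 0.0075, "ILC": 0.0465}


def validation_slide_params(profile: str = "IDC", seed: int = 0,
                            **overrides) -> SyntheticSlideParams:
    """Parameters of a large validation slide for per-cell classification.

    Roughly 2200 epithelial cells in the peritumor zone, with the
    subtype's individualized-cell fraction (0.75% IDC, 4.65% ILC).
    """
    fields = dict(
        image_size=(2560, 2560),
        n_groups=220,
        group_size_range=(4, 16),
        tumor_core_fraction=0.02,
        individualized_cell_fraction=INDIVIDUALIZED_FRACTION[profile],
        marker_profile=profile,
        n_stromal_cells=120,
        seed=seed,
    )
    fields.update(overrides)
    return SyntheticSlideParams(**fields)


def slide_params_for_ci(target_ci: float, seed: int = 0,
                        **overrides) -> SyntheticSlideParams:
    """Slide parameters whose realized CI score lands near ``target_ci``.

    The CI score of a slide is determined by three geometric knobs: the
    adipose area fraction ``a``, the fraction ``f_a`` of invading groups
    placed inside the adipose band, and the core-to-invasion area balance.
    Since ``CI = f_a * G / ((C + G) * a)`` for invasion area ``G`` and core
    area ``C``, the helper fixes ``a`` and ``f_a`` per regime and solves
    for the core fraction.  The realized score (rasterized masks, random
    group sizes) lands near, not exactly on, the target; read the truth.
    """
    if target_ci <= 0:
        raise ValueError("target_ci must be positive")
    a = 0.3
    if target_ci > 0.9 / a:
        raise ValueError(f"target_ci above the geometric maximum {0.9 / a}")
    f_a = min(0.9, max(0.1, 1.15 * target_ci * a))
    n_groups = overrides.pop("n_groups", 12)
    size_lo, size_hi = overrides.pop("group_size_range", (3, 8))
    params_probe = SyntheticSlideParams(seed=seed, **overrides) \
        if overrides else SyntheticSlideParams(seed=seed)
    r_cell_px = params_probe.cell_radius / params_probe.pixel_size
    # expected invasion area: mean group size, ~80% effective disc coverage
    n_cells = n_groups * 0.5 * (size_lo + size_hi)
    g_px = 0.8 * math.pi * r_cell_px ** 2 * n_cells
    h, w = params_probe.image_size
    g_frac = g_px / (h * w)
    core_frac = max(0.0, g_frac * (f_a / (target_ci * a) - 1.0))
    fields = dict(overrides)
    fields.update(
        seed=seed, adipose_fraction_target=a, tumor_core_fraction=core_frac,
        n_groups=n_groups, group_size_range=(size_lo, size_hi),
        group_compartment_mix={"fibrous": 1.0 - f_a, "adipose": f_a})
    return SyntheticSlideParams(**fields)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortParams:
    """Parameters of one simulated follow-up cohort.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_ratio * I[ci_score > cohort median])``
    (units: events/month); censoring is an independent exponential capped
    administratively at ``followup_cap`` months.
    """

    n_patients: int = 200
    ci_score_distribution: tuple[str, dict] = (
        "lognormal", {"mean": -0.35, "sigma": 0.9})
    log_hazard_ratio: float = math.log(2.3)
    baseline_hazard: float = 0.008
    censoring_rate: float = 0.005
    followup_cap: Optional[float] = 60.0
    subtype_mix: float = 0.8  # fraction IDC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if not 0.0 <= self.subtype_mix <= 1.0:
            raise ValueError("subtype_mix must lie in [0, 1]")


def generate_cohort(params: SyntheticCohortParams
                    ) -> tuple[pd.DataFrame, dict]:
    """Simulate one cohort; returns (table, true generating parameters).

    The table has one row per patient with columns ``patient_id``,
    ``subtype``, ``ci_score``, ``time`` (months, > 0), ``event`` (1 =
    distant metastasis observed) and a ``high_ci`` indicator relative to
    the cohort median.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    family, kw = params.ci_score_distribution
    if family == "lognormal":
        ci = rng.lognormal(mean=kw["mean"], sigma=kw["sigma"], size=n)
    elif family == "gamma":
        ci = rng.gamma(shape=kw["shape"], scale=kw["scale"], size=n)
    else:
        raise ValueError(f"unknown ci_score distribution {family!r}")

    median = float(np.median(ci))
    high = ci > median
    hazard = params.baseline_hazard * np.exp(params.log_hazard_ratio * high)
    t_event = rng.exponential(1.0 / hazard)
    if params.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / params.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    if params.followup_cap is not None:
        t_cens = np.minimum(t_cens, params.followup_cap)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # exponential times are continuous: clip away numerically-zero times
    time = np.maximum(time, 1e-9)

    subtype = np.where(rng.random(n) < params.subtype_mix, "IDC", "ILC")
    table = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "subtype": subtype,
        "ci_score": ci,
        "time": time,
        "event": event,
        "high_ci": high.astype(int),
    })
    true_params = {
        "log_hazard_ratio": params.log_hazard_ratio,
        "hazard_ratio": math.exp(params.log_hazard_ratio),
        "baseline_hazard": params.baseline_hazard,
        "censoring_rate": params.censoring_rate,
        "followup_cap": params.followup_cap,
        "ci_median": median,
    }
    return table, true_params
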