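"""Deterministic synthetic fixtures: rendered slides with ground truth, and
survival cohorts with proportional-hazards structure.

The slide generator emulates the morphologies the pipeline must handle —
tumor blobs with necrotic cores, DCIS-like non-invasive inclusions with
dense decoy lymphoid aggregates, and stromal TILs placed by an
(optionally inhomogeneous) Poisson point process — and returns exact
ground truth (label mask, cell list, per-cell compartment).  The cohort
generator draws sTIL densities, clinical covariates and exponential
survival times under a linear (per-300-cells/mm²) or step hazard model.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .backends import ClassPalette, SlideImage
from .geometry import (
    AuditCode,
    EmptyMacroTumorError,
    GeometryParams,
    RegionPartition,
    build_partition,
)
from .raster import BinaryMask, Calibration, CellClass, CellDetections, LabelMask, TissueClass

__all__ = ["SlideSpec", "CohortSpec", "SlideRender", "render_slide", "simulate_cohort"]


# ---------------------------------------------------------------------------
# slides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlideSpec:
    """Layout and intensity parameters of a rendered slide.

    Defaults give a 4×4 mm slide at 2 µm/px with three tumor blobs,
    necrotic cores, two DCIS-like inclusions surrounded by decoy lymphoid
    aggregates, and a stromal TIL intensity of 600 cells/mm² (the order of
    magnitude of the biomarker's clinically relevant range, whose working
    cutpoint is 470 cells/mm²).
    """

    microns_per_pixel: float = 2.0
    width_px: int = 2000
    height_px: int = 2000
    n_tumor_blobs: int = 3
    tumor_blob_radius_um: tuple[float, float] = (500.0, 900.0)
    necrosis_core_fraction: float = 0.25  # core radius as a fraction of blob radius
    n_dcis: int = 2
    dcis_radius_um: tuple[float, float] = (60.0, 120.0)
    dcis_offset_um: tuple[float, float] = (350.0, 600.0)  # from a tumor blob edge
    stromal_til_per_mm2: float = 600.0
    tumor_til_per_mm2: float = 40.0
    necrosis_til_per_mm2: float = 40.0
    dcis_aggregate_til_per_mm2: float = 3000.0
    dcis_aggregate_radius_um: float = 100.0
    other_cells_per_mm2: float = 150.0
    cell_radius_um: float = 4.0
    min_cell_separation_um: float = 0.0
    til_field: str = "uniform"  # or "gradient": stromal intensity ramps left→right
    palette: ClassPalette = field(default_factory=ClassPalette)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    seed: int = 0


@dataclass
class SlideRender:
    """A rendered slide plus its exact ground truth."""

    image: SlideImage
    labels: LabelMask
    cells: CellDetections
    compartments: np.ndarray  # (n,) AuditCode ground truth per cell
    partition: RegionPartition

    @property
    def kept_count(self) -> int:
        return int((self.compartments == int(AuditCode.KEPT)).sum())

    def stroma_intensity(self) -> float:
        """Ground-truth kept count / scoring-stroma area (cells/mm²)."""
        return self.kept_count / self.partition.tumor_associated_stroma.area_mm2


def _paint_disk(raster: np.ndarray, cx: float, cy: float, r_px: float, value) -> None:
    h, w = raster.shape[:2]
    x0, x1 = max(int(cx - r_px) - 1, 0), min(int(cx + r_px) + 2, w)
    y0, y1 = max(int(cy - r_px) - 1, 0), min(int(cy + r_px) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px * r_px
    raster[y0:y1, x0:x1][inside] = value


def _sample_points(
    rng: np.random.Generator,
    weight: np.ndarray,
    intensity_per_mm2: float,
    cal: Calibration,
) -> np.ndarray:
    """Poisson point process with per-pixel weights (sum of weights × pixel
    area = effective area).  Returns (n, 2) float (x, y) with sub-pixel jitter."""
    total_area = float(weight.sum()) * cal.pixel_area_mm2
    if total_area <= 0 or intensity_per_mm2 <= 0:
        return np.zeros((0, 2))
    n = rng.poisson(intensity_per_mm2 * total_area)
    if n == 0:
        return np.zeros((0, 2))
    flat = weight.ravel() / weight.sum()
    idx = rng.choice(len(flat), size=n, p=flat)
    iy, ix = np.unravel_index(idx, weight.shape)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    x = np.clip(ix + jitter[:, 0], 0, cal.width_px - 1e-6)
    y = np.clip(iy + jitter[:, 1], 0, cal.height_px - 1e-6)
    return np.column_stack([x, y])


def _thin_min_separation(points: np.ndarray, min_sep_px: float) -> np.ndarray:
    """Greedy thinning: keep earlier points, drop later ones closer than
    ``min_sep_px`` to a kept point.  Returns a boolean keep vector."""
    n = len(points)
    keep = np.ones(n, dtype=bool)
    if n < 2 or min_sep_px <= 0:
        return keep
    tree = cKDTree(points)
    for i, j in sorted(tree.query_pairs(min_sep_px)):
        if keep[i] and keep[j]:
            keep[max(i, j)] = False
    return keep


def render_slide(spec: SlideSpec) -> SlideRender:
    """Render a slide and return image + exact ground truth.

    Layer order (later overrides earlier): STROMA < TUMOR < NECROSIS < DCIS,
    with necrotic cores generated inside tumor blobs and DCIS placed in
    stroma at a configured offset from a tumor blob edge.  Each placed cell
    is tagged with its true compartment using the geometric partition of the
    ground-truth label mask.
    """
    rng = np.random.default_rng(spec.seed)
    cal = Calibration(spec.microns_per_pixel, spec.width_px, spec.height_px)
    mpp = spec.microns_per_pixel
    labels = np.full(cal.shape, int(TissueClass.BACKGROUND), dtype=np.uint8)

    # tissue: one big ellipse of stroma
    h, w = cal.shape
    yy, xx = np.mgrid[0:h, 0:w]
    tissue = ((xx - w / 2) / (0.46 * w)) ** 2 + ((yy - h / 2) / (0.46 * h)) ** 2 <= 1.0
    labels[tissue] = int(TissueClass.STROMA)

    # tumor blobs (2 overlapping disks each, for irregular outline) + necrotic cores
    blob_centers: list[tuple[float, float, float]] = []
    for _ in range(spec.n_tumor_blobs):
        r_um = rng.uniform(*spec.tumor_blob_radius_um)
        r = r_um / mpp
        cx = rng.uniform(0.30 * w, 0.70 * w)
        cy = rng.uniform(0.30 * h, 0.70 * h)
        _paint_disk(labels, cx, cy, r, int(TissueClass.TUMOR))
        ang = rng.uniform(0, 2 * np.pi)
        _paint_disk(
            labels,
            cx + 0.5 * r * np.cos(ang),
            cy + 0.5 * r * np.sin(ang),
            0.75 * r,
            int(TissueClass.TUMOR),
        )
        blob_centers.append((cx, cy, r))
    if spec.necrosis_core_fraction > 0:
        for cx, cy, r in blob_centers:
            _paint_disk(labels, cx, cy, spec.necrosis_core_fraction * r, int(TissueClass.NECROSIS))

    # DCIS inclusions near (but outside) tumor blobs, in stroma
    dcis_centers: list[tuple[float, float, float]] = []
    for k in range(spec.n_dcis):
        cx, cy, r = blob_centers[k % len(blob_centers)] if blob_centers else (w / 2, h / 2, 0.0)
        rr = rng.uniform(*spec.dcis_radius_um) / mpp
        off = (r + rng.uniform(*spec.dcis_offset_um) / mpp)
        ang = rng.uniform(0, 2 * np.pi)
        px, py = cx + off * np.cos(ang), cy + off * np.sin(ang)
        px = float(np.clip(px, rr + 2, w - rr - 3))
        py = float(np.clip(py, rr + 2, h - rr - 3))
        _paint_disk(labels, px, py, rr, int(TissueClass.NONINVASIVE_EPITHELIUM))
        dcis_centers.append((px, py, rr))

    label_mask = LabelMask(labels, cal)
    try:
        partition = build_partition(label_mask, spec.geometry)
    except EmptyMacroTumorError:
        # tumor-free layout: legal fixture for pipeline failure paths
        empty = BinaryMask(np.zeros(cal.shape, bool), cal)
        partition = RegionPartition(empty, empty, empty, empty, spec.geometry)

    # point processes per compartment
    stroma_w = (labels == int(TissueClass.STROMA)).astype(float)
    if spec.til_field == "gradient":
        stroma_w = stroma_w * (0.5 + 1.0 * (xx / max(w - 1, 1)))
    elif spec.til_field != "uniform":
        raise ValueError(f"unknown til_field {spec.til_field!r}")
    tumor_w = (labels == int(TissueClass.TUMOR)).astype(float)
    necro_w = (labels == int(TissueClass.NECROSIS)).astype(float)
    agg_w = np.zeros(cal.shape)
    if dcis_centers and spec.dcis_aggregate_til_per_mm2 > 0:
        ring = np.zeros(cal.shape, dtype=bool)
        for px, py, rr in dcis_centers:
            _paint_disk(ring, px, py, rr + spec.dcis_aggregate_radius_um / mpp, True)
        agg_w = (ring & (labels == int(TissueClass.STROMA))).astype(float)

    til_pts = [
        _sample_points(rng, stroma_w, spec.stromal_til_per_mm2, cal),
        _sample_points(rng, tumor_w, spec.tumor_til_per_mm2, cal),
        _sample_points(rng, necro_w, spec.necrosis_til_per_mm2, cal),
        _sample_points(rng, agg_w, spec.dcis_aggregate_til_per_mm2, cal),
    ]
    other_pts = _sample_points(rng, (labels != int(TissueClass.BACKGROUND)).astype(float),
                               spec.other_cells_per_mm2, cal)
    points = np.vstack(til_pts + [other_pts])
    cls = np.concatenate(
        [np.full(sum(len(p) for p in til_pts), int(CellClass.TIL), np.int64),
         np.full(len(other_pts), int(CellClass.OTHER), np.int64)]
    )
    if spec.min_cell_separation_um > 0 and len(points):
        keep = _thin_min_separation(points, spec.min_cell_separation_um / mpp)
        points, cls = points[keep], cls[keep]
    cells = CellDetections(points, cls, cal)

    # ground-truth compartment per cell: direct mask lookup with the audit
    # precedence (independent of geometry.filter_tils)
    comp = np.full(len(cells), int(AuditCode.OUTSIDE_STROMA), dtype=np.int64)
    if len(cells):
        ix, iy = cells.nearest_pixels()
        pc = labels[iy, ix]
        zone = partition.exclusion_zone.raster[iy, ix]
        stroma = partition.tumor_associated_stroma.raster[iy, ix]
        for i in range(len(cells)):
            if cls[i] != int(CellClass.TIL):
                comp[i] = int(AuditCode.NOT_TIL)
            elif pc[i] == int(TissueClass.TUMOR):
                comp[i] = int(AuditCode.IN_TUMOR)
            elif pc[i] == int(TissueClass.NECROSIS):
                comp[i] = int(AuditCode.IN_NECROSIS)
            elif zone[i]:
                comp[i] = int(AuditCode.NEAR_EPI)
            elif stroma[i]:
                comp[i] = int(AuditCode.KEPT)

    # image: tissue colors, cells painted on top as small disks
    pal = spec.palette
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[:] = pal.background
    for t_cls, col in pal.tissue_colors.items():
        rgb[labels == t_cls] = col
    cell_r = spec.cell_radius_um / mpp
    for (x, y), c in zip(cells.points, cells.labels):
        _paint_disk(rgb, x, y, cell_r, pal.cell_colors[int(c)])

    return SlideRender(SlideImage(rgb, cal), label_mask, cells, comp, partition)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

DEFAULT_COV_LOG_HRS = {
    "age_ge50": float(np.log(2.5)),
    "size_gt2cm": float(np.log(1.5)),
    "nodes_1_3": float(np.log(1.7)),
    "nodes_ge4": float(np.log(4.0)),
    "type_lobular": float(np.log(1.8)),
    "type_other": float(np.log(0.95)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated survival cohort.

    Defaults: 257 patients; log-normal sTIL density with median ≈ 430
    cells/mm² (the working 470 cells/mm² cutpoint sits near the median, so a
    dichotomization splits the cohort roughly in half); linear hazard model
    with log-HR ln(0.8) per 300 cells/mm²; exponential baseline calibrated
    to roughly half the cohort dying over the staggered 5.5–15-year
    follow-up, as in long-follow-up TNBC cohorts.
    """

    n: int = 257
    density_log_mu: float = float(np.log(430.0))
    density_log_sigma: float = 0.8
    effect: str = "linear"  # or "step"
    log_hr_per_300: float = float(np.log(0.8))
    step_at: float = 470.0
    step_log_hr: float = float(np.log(0.45))
    baseline_hazard_per_day: float = 7e-5
    rfs_baseline_hazard_per_day: float = 5e-5
    censor_min_days: float = 2000.0
    censor_max_days: float = 5478.0
    cov_log_hrs: dict = field(default_factory=lambda: dict(DEFAULT_COV_LOG_HRS))
    manual_noise_sd: float = 0.45  # log-scale noise linking manual % to density
    block2_prob: float = 0.8
    seed: int = 0


def _biomarker_log_relrisk(density: np.ndarray, spec: CohortSpec) -> np.ndarray:
    if spec.effect == "linear":
        return spec.log_hr_per_300 * density / 300.0
    if spec.effect == "step":
        return np.where(density >= spec.step_at, spec.step_log_hr, 0.0)
    raise ValueError(f"unknown effect {spec.effect!r}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with survival endpoints and clinical covariates.

    Columns: id, stil_density, manual_stil_pct_block1/2, manual_stil_pct,
    os_time, os_event, rfs_time, rfs_event, age_years, tumor_size_cm,
    n_positive_nodes, tumor_type.  RFS treats death without relapse as
    censoring.  Raises if the spec admits no events.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    density = rng.lognormal(spec.density_log_mu, spec.density_log_sigma, n)

    age = rng.normal(58, 12, n)
    size = np.round(rng.lognormal(np.log(2.2), 0.45, n), 1)
    nodes = rng.poisson(1.2, n)
    tumor_type = rng.choice(["ductal", "lobular", "other"], size=n, p=[0.80, 0.05, 0.15])

    cov = {
        "age_ge50": (age >= 50).astype(float),
        "size_gt2cm": (size > 2).astype(float),
        "nodes_1_3": ((nodes >= 1) & (nodes <= 3)).astype(float),
        "nodes_ge4": (nodes >= 4).astype(float),
        "type_lobular": (tumor_type == "lobular").astype(float),
        "type_other": (tumor_type == "other").astype(float),
    }
    cov_lp = np.zeros(n)
    for k, beta in spec.cov_log_hrs.items():
        cov_lp += beta * cov[k]
    lp = _biomarker_log_relrisk(density, spec) + cov_lp

    death_t = rng.exponential(1.0 / (spec.baseline_hazard_per_day * np.exp(lp)))
    relapse_t = rng.exponential(1.0 / (spec.rfs_baseline_hazard_per_day * np.exp(lp)))
    censor_t = rng.uniform(spec.censor_min_days, spec.censor_max_days, n)

    os_time = np.minimum(death_t, censor_t)
    os_event = (death_t <= censor_t).astype(int)
    # RFS: censored at death or last visit
    rfs_stop = np.minimum(death_t, censor_t)
    rfs_time = np.minimum(relapse_t, rfs_stop)
    rfs_event = (relapse_t <= rfs_stop).astype(int)

    frac = os_event.mean()
    if frac <= 0 or frac >= 1:
        raise ValueError(f"degenerate cohort spec: OS event fraction {frac:.2f}")

    manual_scale = 10.0 / 470.0  # 470 cells/mm² corresponds to ~10% area coverage
    b1 = density * manual_scale * rng.lognormal(0.0, spec.manual_noise_sd, n)
    b2 = density * manual_scale * rng.lognormal(0.0, spec.manual_noise_sd, n)
    b1 = np.clip(np.round(b1), 0, 95)
    b2 = np.where(rng.uniform(size=n) < spec.block2_prob, np.clip(np.round(b2), 0, 95), np.nan)
    manual = np.where(np.isnan(b2), b1, (b1 + b2) / 2.0)

    return pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "stil_density": density,
            "manual_stil_pct_block1": b1,
            "manual_stil_pct_block2": b2,
            "manual_stil_pct": manual,
            "os_time": os_time,
            "os_event": os_event,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
            "age_years": np.round(age, 1),
            "tumor_size_cm": size,
            "n_positive_nodes": nodes,
            "tumor_type": tumor_type,
        }
    )
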