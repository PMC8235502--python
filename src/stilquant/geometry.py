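"""Tumor-microenvironment geometry: macro-tumor outline, tumor-associated
stroma, and guideline exclusion zones.

The macro-tumor outline emulates the envelope a pathologist would draw
around the entire tumor: local tumor-area fraction under a fixed circular
kernel (default radius 750 µm) is thresholded and regularized with a
morphological closing/opening.  The tumor-associated stroma adds an
invasive-margin band (default 250 µm) outside the macro outline, then
removes tumor, necrosis and non-invasive epithelium.  TILs are excluded
inside tumor and necrosis and within a buffer (default 150 µm) of
non-invasive epithelium, where dense lymphoid aggregates would otherwise
inflate the stromal count.
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .raster import (
    BinaryMask,
    CalibrationError,
    CellClass,
    CellDetections,
    LabelMask,
    TissueClass,
    dilate_um,
    disk_kernel_fraction,
    morph_close_open,
)

__all__ = [
    "GeometryParams",
    "RegionPartition",
    "AuditCode",
    "FilteredCells",
    "EmptyMacroTumorError",
    "macro_tumor_outline",
    "tumor_associated_stroma",
    "exclusion_zone",
    "filter_tils",
    "build_partition",
]


class EmptyMacroTumorError(ValueError):
    """No macro-tumor region could be outlined (no or too little tumor)."""


@dataclass(frozen=True)
class GeometryParams:
    """Physical parameters of the stroma definition.

    kernel_radius_um : circular kernel for local tumor-area fraction (750 µm).
    tumor_fraction_threshold : local tumor fraction defining macro-tumor
        membership; not guideline-fixed, default 0.10 (sparse satellite nests
        merge, isolated single glands do not).
    morph_radius_um : structuring-element radius of the closing/opening
        regularizer; not guideline-fixed, default 250 µm.
    margin_um : invasive-margin band added outside the macro outline (250 µm).
    epi_exclusion_um : buffer around non-invasive epithelium inside which
        TILs are excluded (150 µm).
    """

    kernel_radius_um: float = 750.0
    tumor_fraction_threshold: float = 0.10
    morph_radius_um: float = 250.0
    margin_um: float = 250.0
    epi_exclusion_um: float = 150.0

    def __post_init__(self) -> None:
        if not (self.kernel_radius_um > 0 and self.morph_radius_um > 0):
            raise ValueError("kernel and morphology radii must be > 0")
        if not (0 < self.tumor_fraction_threshold <= 1):
            raise ValueError("tumor_fraction_threshold must be in (0, 1]")
        if self.margin_um < 0 or self.epi_exclusion_um < 0:
            raise ValueError("margins must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


class AuditCode(enum.IntEnum):
    """Per-cell outcome of the TIL filter; precedence
    IN_TUMOR > IN_NECROSIS > NEAR_EPI > OUTSIDE_STROMA for excluded TILs."""

    KEPT = 0
    IN_TUMOR = 1
    IN_NECROSIS = 2
    NEAR_EPI = 3
    OUTSIDE_STROMA = 4
    NOT_TIL = 5


@dataclass
class RegionPartition:
    """Derived region masks of one slide.

    ``tumor_associated_stroma`` is the *scoring* stroma: the morphological
    stroma definition minus the exclusion zone, so it is disjoint from
    ``exclusion_zone`` and is the exact denominator region of the density.
    ``raw_stroma`` keeps the pre-exclusion stroma for review.
    """

    macro_tumor: BinaryMask
    tumor_associated_stroma: BinaryMask
    exclusion_zone: BinaryMask
    raw_stroma: BinaryMask
    params: GeometryParams

    def __post_init__(self) -> None:
        cal = self.macro_tumor.calibration
        for m in (self.tumor_associated_stroma, self.exclusion_zone, self.raw_stroma):
            if m.calibration != cal:
                raise CalibrationError("all partition masks must share one calibration")
        if (self.tumor_associated_stroma.raster & self.exclusion_zone.raster).any():
            raise ValueError("scoring stroma must be disjoint from the exclusion zone")


def macro_tumor_outline(labels: LabelMask, params: GeometryParams) -> tuple[BinaryMask, bool]:
    """Outline the macro-tumor region from the tumor-class raster.

    Thresholds the local tumor-area fraction under the circular kernel, then
    applies closing/opening, then intersects with tissue.  Returns the mask
    and a flag that is False when no tumor pixels exist (empty outline);
    downstream density computation must refuse an empty macro-tumor.
    """
    tumor = labels.class_mask(TissueClass.TUMOR)
    if tumor.is_empty():
        return BinaryMask(np.zeros(labels.calibration.shape, bool), labels.calibration), False
    frac = disk_kernel_fraction(tumor, params.kernel_radius_um)
    core = BinaryMask(frac >= params.tumor_fraction_threshold, labels.calibration)
    smoothed = morph_close_open(core, params.morph_radius_um)
    macro = smoothed & labels.tissue_mask()
    return macro, not macro.is_empty()


def tumor_associated_stroma(
    labels: LabelMask, macro: BinaryMask, params: GeometryParams
) -> BinaryMask:
    """Stromal tissue inside the macro-tumor plus the invasive-margin band.

    (macro ∪ 250 µm dilation) ∩ tissue, minus tumor, necrosis and
    non-invasive epithelium.  Raises on an empty macro outline.
    """
    if macro.is_empty():
        raise EmptyMacroTumorError("cannot define tumor-associated stroma: empty macro-tumor")
    region = macro | dilate_um(macro, params.margin_um) if params.margin_um > 0 else macro
    stroma = region & labels.tissue_mask()
    for cls in (TissueClass.TUMOR, TissueClass.NECROSIS, TissueClass.NONINVASIVE_EPITHELIUM):
        stroma = stroma - labels.class_mask(cls)
    return stroma


def exclusion_zone(labels: LabelMask, params: GeometryParams) -> BinaryMask:
    """Region where detected TILs are discarded: tumor ∪ necrosis ∪ the
    epithelial buffer (non-invasive epithelium dilated by 150 µm)."""
    zone = labels.class_mask(TissueClass.TUMOR) | labels.class_mask(TissueClass.NECROSIS)
    epi = labels.class_mask(TissueClass.NONINVASIVE_EPITHELIUM)
    if not epi.is_empty():
        zone = zone | dilate_um(epi, params.epi_exclusion_um)
    return zone


def build_partition(labels: LabelMask, params: GeometryParams | None = None) -> RegionPartition:
    """Run the full geometric stage and return the region partition."""
    params = params or GeometryParams()
    macro, ok = macro_tumor_outline(labels, params)
    if not ok:
        raise EmptyMacroTumorError("no macro-tumor region found in label mask")
    raw = tumor_associated_stroma(labels, macro, params)
    zone = exclusion_zone(labels, params)
    scoring = raw - zone
    return RegionPartition(macro, scoring, zone, raw, params)


@dataclass
class FilteredCells:
    """Kept TILs plus the per-input-point audit trail (order-aligned)."""

    kept: CellDetections
    codes: np.ndarray  # (n_input,) AuditCode values

    def count(self, code: AuditCode) -> int:
        return int((self.codes == int(code)).sum())


def filter_tils(
    cells: CellDetections,
    stroma: BinaryMask,
    zone: BinaryMask,
    labels: LabelMask,
) -> FilteredCells:
    """Apply guideline exclusion to detected cells.

    A TIL is kept iff its nearest pixel lies in the scoring stroma and not
    in the exclusion zone.  Every input point gets exactly one audit code;
    kept + excluded counts conserve the input TIL count.
    """
    cal = cells.calibration
    if cal != stroma.calibration or cal != zone.calibration or cal != labels.calibration:
        raise CalibrationError("cells, masks and labels must share one calibration")
    n = len(cells)
    codes = np.full(n, int(AuditCode.OUTSIDE_STROMA), dtype=np.int64)
    if n == 0:
        return FilteredCells(cells.select(np.zeros(0, bool)), codes)
    ix, iy = cells.nearest_pixels()
    is_til = cells.labels == int(CellClass.TIL)
    pix_class = labels.raster[iy, ix]
    in_zone = zone.raster[iy, ix]
    in_stroma = stroma.raster[iy, ix] & ~in_zone

    codes[~is_til] = int(AuditCode.NOT_TIL)
    til = is_til
    codes[til & (pix_class == int(TissueClass.TUMOR))] = int(AuditCode.IN_TUMOR)
    sel = til & (pix_class != int(TissueClass.TUMOR))
    codes[sel & (pix_class == int(TissueClass.NECROSIS))] = int(AuditCode.IN_NECROSIS)
    sel &= pix_class != int(TissueClass.NECROSIS)
    codes[sel & in_zone] = int(AuditCode.NEAR_EPI)
    sel &= ~in_zone
    codes[sel & in_stroma] = int(AuditCode.KEPT)
    codes[sel & ~in_stroma] = int(AuditCode.OUTSIDE_STROMA)

    kept = cells.select(codes == int(AuditCode.KEPT))
    return FilteredCells(kept, codes)


def connected_components(mask: BinaryMask) -> int:
    """Number of 8-connected components (diagnostic helper)."""
    _, n = ndimage.label(mask.raster, structure=np.ones((3, 3), int))
    return int(n)
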