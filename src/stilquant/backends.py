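"""Pluggable inference backends for the three image stages.

A production deployment would plug trained segmentation/detection models in
here; the pipeline only depends on the stage contracts.  The shipped
reference backends are deterministic rule-based implementations that invert
the synthetic renderer's color coding, which gives exact ground truth for
end-to-end testing of everything downstream of inference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .raster import (
    BinaryMask,
    Calibration,
    CalibrationError,
    CellClass,
    CellDetections,
    LabelMask,
    TissueClass,
)

__all__ = [
    "SlideImage",
    "Stage",
    "ClassPalette",
    "TissueDetector",
    "TissueSegmenter",
    "CellDetector",
    "ReferenceTissueDetector",
    "ReferenceTissueSegmenter",
    "ReferenceCellDetector",
    "UnmappableColorError",
]


@dataclass
class SlideImage:
    """8-bit RGB slide raster with physical calibration."""

    rgb: np.ndarray  # (h, w, 3) uint8
    calibration: Calibration

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("slide image must be (h, w, 3)")
        if self.rgb.shape[:2] != self.calibration.shape:
            raise CalibrationError("image dimensions inconsistent with calibration")


class Stage(enum.Enum):
    TISSUE_DETECT = "tissue_detect"
    TISSUE_SEGMENT = "tissue_segment"
    CELL_DETECT = "cell_detect"


@dataclass(frozen=True)
class ClassPalette:
    """Color coding shared by the synthetic renderer and reference backends.

    ``cell_class_to_tissue`` tells the segmenter which tissue class a pixel
    covered by a rendered cell should be attributed to (cells sit on top of
    tissue; stromal attribution is correct for the vast majority).
    """

    background: tuple[int, int, int] = (245, 245, 247)
    tissue_colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: {
            int(TissueClass.STROMA): (235, 180, 200),
            int(TissueClass.TUMOR): (120, 80, 160),
            int(TissueClass.NECROSIS): (200, 120, 90),
            int(TissueClass.NONINVASIVE_EPITHELIUM): (230, 200, 120),
        }
    )
    cell_colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: {
            int(CellClass.TIL): (40, 60, 150),
            int(CellClass.OTHER): (90, 160, 90),
        }
    )
    cell_class_to_tissue: dict[int, int] = field(
        default_factory=lambda: {
            int(CellClass.TIL): int(TissueClass.STROMA),
            int(CellClass.OTHER): int(TissueClass.STROMA),
        }
    )

    def with_permuted_tissue_colors(self, perm: dict[int, int]) -> "ClassPalette":
        """Swap tissue class colors according to a class→class permutation."""
        new = {c: self.tissue_colors[perm.get(c, c)] for c in self.tissue_colors}
        return replace(self, tissue_colors=new)


class UnmappableColorError(ValueError):
    """A pixel color has no class assignment under strict segmentation."""


class TissueDetector:
    """Stage contract: SlideImage → BinaryMask (tissue vs glass)."""

    name = "abstract-tissue-detector"
    stage = Stage.TISSUE_DETECT

    def detect_tissue(self, image: SlideImage) -> BinaryMask:  # pragma: no cover
        raise NotImplementedError


class TissueSegmenter:
    """Stage contract: SlideImage + tissue mask → LabelMask.

    ``class_definition`` is free text describing what the backend calls each
    class (e.g. whether a hyalinized scar is labeled necrosis); the contract
    does not enforce a histologic definition.
    """

    name = "abstract-tissue-segmenter"
    stage = Stage.TISSUE_SEGMENT
    class_definition = ""

    def segment_tissue(self, image: SlideImage, tissue: BinaryMask) -> LabelMask:  # pragma: no cover
        raise NotImplementedError


class CellDetector:
    """Stage contract: SlideImage + ROI → CellDetections (TIL vs OTHER).

    ``class_definition`` documents the backend's TIL boundary (e.g. all
    mononuclear immune cells, lymphocytes and plasma cells).
    """

    name = "abstract-cell-detector"
    stage = Stage.CELL_DETECT
    class_definition = ""

    def detect_cells(self, image: SlideImage, roi: BinaryMask) -> CellDetections:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# reference implementations (invert the synthetic renderer)
# ---------------------------------------------------------------------------


class ReferenceTissueDetector(TissueDetector):
    """Chromatic-distance threshold from the renderer's background color,
    then removal of connected components smaller than ``min_component_mm2``."""

    name = "reference-color"

    def __init__(
        self,
        palette: ClassPalette | None = None,
        chroma_threshold: float = 30.0,
        min_component_mm2: float = 0.01,
    ) -> None:
        self.palette = palette or ClassPalette()
        self.chroma_threshold = chroma_threshold
        self.min_component_mm2 = min_component_mm2

    def detect_tissue(self, image: SlideImage) -> BinaryMask:
        bg = np.array(self.palette.background, dtype=float)
        dist = np.linalg.norm(image.rgb.astype(float) - bg, axis=2)
        raw = dist > self.chroma_threshold
        if raw.any() and self.min_component_mm2 > 0:
            lab, n = ndimage.label(raw, structure=np.ones((3, 3), int))
            if n:
                sizes = ndimage.sum_labels(raw, lab, index=np.arange(1, n + 1))
                min_px = self.min_component_mm2 / image.calibration.pixel_area_mm2
                keep = np.flatnonzero(sizes >= min_px) + 1
                raw = np.isin(lab, keep)
        return BinaryMask(raw, image.calibration)


class ReferenceTissueSegmenter(TissueSegmenter):
    """Nearest-color classification against the renderer palette.

    Rendered cell colors are mapped to the tissue class configured in
    ``palette.cell_class_to_tissue``.  Under ``strict`` mode any pixel whose
    color does not exactly match a palette entry raises, naming the color.
    """

    name = "reference-color"
    class_definition = (
        "tumor / necrosis (incl. hyalinized scar) / non-invasive epithelium / stroma "
        "by renderer color code"
    )

    def __init__(self, palette: ClassPalette | None = None, strict: bool = False) -> None:
        self.palette = palette or ClassPalette()
        self.strict = strict

    def _color_table(self) -> tuple[np.ndarray, np.ndarray]:
        colors, classes = [], []
        for cls, col in self.palette.tissue_colors.items():
            colors.append(col)
            classes.append(cls)
        for cell_cls, col in self.palette.cell_colors.items():
            colors.append(col)
            classes.append(self.palette.cell_class_to_tissue[cell_cls])
        colors.append(self.palette.background)
        classes.append(int(TissueClass.BACKGROUND))
        return np.array(colors, dtype=float), np.array(classes, dtype=np.uint8)

    def segment_tissue(self, image: SlideImage, tissue: BinaryMask) -> LabelMask:
        if tissue.calibration != image.calibration:
            raise CalibrationError("tissue mask calibration differs from image")
        colors, classes = self._color_table()
        px = image.rgb.reshape(-1, 3).astype(float)
        d2 = ((px[:, None, :] - colors[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        if self.strict:
            exact = d2[np.arange(len(px)), nearest] == 0
            if not exact.all():
                bad = np.unique(px[~exact].astype(int), axis=0)
                raise UnmappableColorError(
                    f"colors with no exact palette match: {bad[:10].tolist()}"
                )
        raster = classes[nearest].reshape(image.calibration.shape)
        raster = np.where(tissue.raster, raster, np.uint8(TissueClass.BACKGROUND))
        return LabelMask(raster, image.calibration)


class ReferenceCellDetector(CellDetector):
    """Connected components of cell-colored pixels, filtered by area and
    circularity (4πA/P²), labeled by color class, restricted to the ROI."""

    name = "reference-color"
    class_definition = "mononuclear immune cells by renderer cell color"

    def __init__(
        self,
        palette: ClassPalette | None = None,
        min_area_um2: float = 12.0,
        max_area_um2: float = 120.0,
        circularity_min: float = 0.6,
        color_tolerance: float = 10.0,
    ) -> None:
        self.palette = palette or ClassPalette()
        self.min_area_um2 = min_area_um2
        self.max_area_um2 = max_area_um2
        self.circularity_min = circularity_min
        self.color_tolerance = color_tolerance

    def detect_cells(self, image: SlideImage, roi: BinaryMask) -> CellDetections:
        if roi.calibration != image.calibration:
            raise CalibrationError("roi calibration differs from image")
        cal = image.calibration
        um2_per_px = cal.microns_per_pixel**2
        pts: list[tuple[float, float]] = []
        labs: list[int] = []
        for cell_cls, col in self.palette.cell_colors.items():
            dist = np.linalg.norm(image.rgb.astype(float) - np.array(col, float), axis=2)
            binary = dist <= self.color_tolerance
            if not binary.any():
                continue
            lab = cc_label(binary, connectivity=2)
            for rp in regionprops(lab):
                area_um2 = rp.area * um2_per_px
                if not (self.min_area_um2 <= area_um2 <= self.max_area_um2):
                    continue
                # Crofton perimeter: the contour-tracing perimeter degenerates
                # for 1-px-thin components (circularity > 1 for a bar)
                perim = rp.perimeter_crofton
                if perim > 0 and 4 * np.pi * rp.area / perim**2 < self.circularity_min:
                    continue
                cy, cx = rp.centroid
                ix = int(np.clip(round(cx), 0, cal.width_px - 1))
                iy = int(np.clip(round(cy), 0, cal.height_px - 1))
                if not roi.raster[iy, ix]:
                    continue
                pts.append((cx, cy))
                labs.append(int(cell_cls))
        points = np.array(pts, float).reshape(-1, 2)
        return CellDetections(points, np.array(labs, np.int64), cal)
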