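"""Calibrated raster and point primitives.

Everything downstream (macro-tumor outlining, exclusion buffers, density
kernels) is built from four operators defined here: disk-kernel local
averaging, morphological closing/opening, Euclidean dilation, and
point-to-mask distance queries.  All operators are parameterized in microns
and converted through a :class:`Calibration`, so the same code runs at any
(isotropic) resolution.

Conventions
-----------
* 0-based pixel indices; x rightward, y downward.  A point ``(x, y)`` in
  pixel units measures distances to *pixel centers*, where the center of
  pixel ``(ix, iy)`` is the point ``(ix, iy)``.
* A discretized disk of radius ``r`` contains every pixel whose center lies
  within ``r`` of the disk center (inclusive boundary).
* Out-of-image pixels are background (False) except for the erosion step of
  a closing, which ignores the border so that closing never removes pixels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

__all__ = [
    "Calibration",
    "TissueClass",
    "CellClass",
    "LabelMask",
    "BinaryMask",
    "CellDetections",
    "CalibrationError",
    "disk_footprint",
    "disk_kernel_fraction",
    "morph_close_open",
    "dilate_um",
    "erode_um",
    "within_distance",
]


class CalibrationError(ValueError):
    """Raised when physical calibration is missing, anisotropic or inconsistent."""


@dataclass(frozen=True)
class Calibration:
    """Isotropic physical scale binding a raster grid to real units.

    Parameters
    ----------
    microns_per_pixel : float
        Edge length of one pixel in µm (must be > 0; anisotropic pixels are
        rejected at load time, so a single scalar suffices).
    width_px, height_px : int
        Raster dimensions.
    """

    microns_per_pixel: float
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0):
            raise CalibrationError("microns_per_pixel must be > 0")
        if self.width_px <= 0 or self.height_px <= 0:
            raise CalibrationError("raster dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (height, width)."""
        return (self.height_px, self.width_px)

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm²: (µm/px / 1000)²."""
        return (self.microns_per_pixel / 1000.0) ** 2

    def um_to_px(self, um: float) -> float:
        return um / self.microns_per_pixel

    def px_to_um(self, px: float) -> float:
        return px * self.microns_per_pixel

    def area_mm2(self, n_pixels: int) -> float:
        return n_pixels * self.pixel_area_mm2


class TissueClass(enum.IntEnum):
    """Tissue-level classes of the segmentation stage."""

    BACKGROUND = 0
    STROMA = 1
    TUMOR = 2
    NECROSIS = 3
    NONINVASIVE_EPITHELIUM = 4


class CellClass(enum.IntEnum):
    """Cell-level classes: mononuclear immune cells (TIL) vs everything else."""

    OTHER = 0
    TIL = 1


def _check_same_calibration(a: Calibration, b: Calibration, what: str) -> None:
    if a != b:
        raise CalibrationError(f"calibration mismatch between {what}: {a} vs {b}")


@dataclass
class BinaryMask:
    """A boolean raster with physical calibration."""

    raster: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.shape != self.calibration.shape:
            raise CalibrationError(
                f"mask shape {self.raster.shape} != calibration shape {self.calibration.shape}"
            )

    @property
    def area_mm2(self) -> float:
        return self.calibration.area_mm2(int(self.raster.sum()))

    def is_empty(self) -> bool:
        return not bool(self.raster.any())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_calibration(self.calibration, other.calibration, "masks")
        return BinaryMask(self.raster & other.raster, self.calibration)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_calibration(self.calibration, other.calibration, "masks")
        return BinaryMask(self.raster | other.raster, self.calibration)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_calibration(self.calibration, other.calibration, "masks")
        return BinaryMask(self.raster & ~other.raster, self.calibration)


@dataclass
class LabelMask:
    """Class-labeled raster: one :class:`TissueClass` code per pixel."""

    raster: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=np.uint8)
        if self.raster.shape != self.calibration.shape:
            raise CalibrationError(
                f"label raster shape {self.raster.shape} != calibration {self.calibration.shape}"
            )
        valid = {int(c) for c in TissueClass}
        present = set(np.unique(self.raster).tolist())
        if not present <= valid:
            raise ValueError(f"unknown class codes in label raster: {sorted(present - valid)}")

    def class_mask(self, cls: TissueClass) -> BinaryMask:
        return BinaryMask(self.raster == int(cls), self.calibration)

    def tissue_mask(self) -> BinaryMask:
        """All non-background pixels."""
        return BinaryMask(self.raster != int(TissueClass.BACKGROUND), self.calibration)


@dataclass
class CellDetections:
    """Point set of detected cells in pixel coordinates with TIL/OTHER labels.

    Point order is stable through filtering so per-point audit vectors align.
    """

    points: np.ndarray  # (n, 2) float, columns (x_px, y_px)
    labels: np.ndarray  # (n,) int, CellClass codes
    calibration: Calibration

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels length mismatch")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (
                (x < 0).any()
                or (y < 0).any()
                or (x >= self.calibration.width_px).any()
                or (y >= self.calibration.height_px).any()
            ):
                raise ValueError("cell coordinates outside the calibrated frame")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_til(self) -> int:
        return int((self.labels == int(CellClass.TIL)).sum())

    @property
    def n_other(self) -> int:
        return int((self.labels == int(CellClass.OTHER)).sum())

    def select(self, keep: np.ndarray) -> "CellDetections":
        keep = np.asarray(keep, dtype=bool)
        return CellDetections(self.points[keep], self.labels[keep], self.calibration)

    def nearest_pixels(self) -> tuple[np.ndarray, np.ndarray]:
        """Snap each point to its nearest pixel center; returns (ix, iy)."""
        ix = np.clip(np.rint(self.points[:, 0]).astype(int), 0, self.calibration.width_px - 1)
        iy = np.clip(np.rint(self.points[:, 1]).astype(int), 0, self.calibration.height_px - 1)
        return ix, iy


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------


def disk_footprint(radius_px: float) -> np.ndarray:
    """Discretized disk: pixel centers with dx² + dy² ≤ radius² (inclusive)."""
    r = int(np.floor(radius_px + 1e-9))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= radius_px * radius_px + 1e-9


def _radius_px(calibration: Calibration, radius_um: float, name: str) -> float:
    r = calibration.um_to_px(radius_um)
    if r < 1.0:
        raise CalibrationError(
            f"{name}={radius_um} µm is below one pixel at "
            f"{calibration.microns_per_pixel} µm/px; calibration mismatch?"
        )
    return r


def _count_convolve(arr: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Integer-valued 'same' convolution of a 0/1 array with a 0/1 footprint."""
    out = fftconvolve(arr.astype(np.float64), footprint.astype(np.float64), mode="same")
    return np.rint(out)


def disk_kernel_fraction(mask: BinaryMask, radius_um: float) -> np.ndarray:
    """Local fraction of true pixels within a circular kernel.

    At each pixel the disk is clipped to the image and the count is
    normalized by the number of disk pixels actually inside the image, so
    values near the border are unbiased.  Returns a float array in [0, 1]
    of the same shape as the mask.
    """
    r_px = _radius_px(mask.calibration, radius_um, "radius_um")
    fp = disk_footprint(r_px)
    num = _count_convolve(mask.raster, fp)
    den = _count_convolve(np.ones_like(mask.raster, dtype=np.float64), fp)
    return np.clip(num / den, 0.0, 1.0)


def _edt_sq(background: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance (exact integer) to the nearest True pixel."""
    if not background.any():
        return np.full(background.shape, np.inf)
    d = ndimage.distance_transform_edt(~background)
    return np.rint(d * d)


def dilate_um(mask: BinaryMask, distance_um: float) -> BinaryMask:
    """Euclidean dilation: pixels within ``distance_um`` of a true pixel center.

    ``distance_um = 0`` returns the mask unchanged.  Exact (EDT-based), so it
    agrees with a brute-force nearest-true-pixel scan.
    """
    if distance_um < 0:
        raise ValueError("distance_um must be >= 0")
    if distance_um == 0 or mask.is_empty():
        return BinaryMask(mask.raster.copy(), mask.calibration)
    r_px = mask.calibration.um_to_px(distance_um)
    d2 = _edt_sq(mask.raster)
    return BinaryMask(d2 <= r_px * r_px + 1e-9, mask.calibration)


def erode_um(mask: BinaryMask, distance_um: float, border_is_foreground: bool = False) -> BinaryMask:
    """Euclidean erosion with the same discretized disk.

    A pixel survives iff no false pixel center lies within ``distance_um``.
    With ``border_is_foreground`` the out-of-image region is ignored (used by
    the erosion half of a closing); otherwise the border erodes inward.
    """
    if distance_um < 0:
        raise ValueError("distance_um must be >= 0")
    if distance_um == 0:
        return BinaryMask(mask.raster.copy(), mask.calibration)
    r_px = mask.calibration.um_to_px(distance_um)
    a = mask.raster
    if border_is_foreground:
        d2 = _edt_sq(~a)
        out = a & ~(d2 <= r_px * r_px + 1e-9)
    else:
        pad = int(np.ceil(r_px)) + 1
        ap = np.pad(a, pad, constant_values=False)
        d2 = _edt_sq(~ap)
        out = (a & ~(d2 <= r_px * r_px + 1e-9)[pad:-pad, pad:-pad])
    return BinaryMask(out, mask.calibration)


def morph_close_open(mask: BinaryMask, radius_um: float) -> BinaryMask:
    """Morphological closing then opening with the discretized disk element.

    Closing bridges gaps narrower than twice the radius; the subsequent
    opening removes isolated specks smaller than the element.  The composite
    is an idempotent morphological filter.
    """
    _radius_px(mask.calibration, radius_um, "radius_um")
    closed = erode_um(dilate_um(mask, radius_um), radius_um, border_is_foreground=True)
    opened = dilate_um(erode_um(closed, radius_um), radius_um)
    return opened


def within_distance(points: CellDetections, mask: BinaryMask, distance_um: float) -> np.ndarray:
    """Flag points lying within ``distance_um`` of any true pixel center.

    Distances are exact point-to-pixel-center Euclidean distances (no raster
    snapping), inclusive at the boundary.  An empty mask yields all-false.
    """
    if distance_um < 0:
        raise ValueError("distance_um must be >= 0")
    _check_same_calibration(points.calibration, mask.calibration, "points and mask")
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if mask.is_empty():
        return np.zeros(n, dtype=bool)
    true_yx = np.argwhere(mask.raster)
    tree = cKDTree(true_yx[:, ::-1])  # (x, y) order
    d, _ = tree.query(points.points, k=1)
    r_px = mask.calibration.um_to_px(distance_um)
    return d <= r_px + 1e-9
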