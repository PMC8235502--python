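"""Landmark-based affine alignment of serial/restained sections and
transfer of dot annotations between slide frames.

Serial sections stained with different protocols (e.g. H&E then CD3/CD79a
IHC) are related by an approximately affine coordinate change; fitting it
from landmark pairs lets IHC-derived center-dot cell annotations be carried
onto the H&E frame.  Only the least-squares landmark fit is provided;
acceptance of a given residual level is left to the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .raster import Calibration, CellDetections

__all__ = ["AffineTransform", "AffineFitReport", "fit_affine", "transfer_annotations"]


class DegenerateLandmarksError(ValueError):
    """Fewer than 3 pairs, or a collinear landmark configuration."""


@dataclass(frozen=True)
class AffineTransform:
    """2×3 matrix mapping source-frame (x, y) to target-frame (x', y')."""

    matrix: tuple  # ((a, b, tx), (c, d, ty))

    def __post_init__(self) -> None:
        m = self.as_array()
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if abs(det) < 1e-9:
            raise ValueError("affine transform is singular (|det| < 1e-9)")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float).reshape(2, 3)

    @classmethod
    def from_array(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, float).reshape(2, 3)
        return cls(matrix=tuple(tuple(row) for row in m))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls.from_array(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 2)
        m = self.as_array()
        return pts @ m[:, :2].T + m[:, 2]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        a, b = self.as_array(), other.as_array()
        lin = a[:, :2] @ b[:, :2]
        t = a[:, :2] @ b[:, 2] + a[:, 2]
        return AffineTransform.from_array(np.column_stack([lin, t]))

    def invert(self) -> "AffineTransform":
        m = self.as_array()
        lin_inv = np.linalg.inv(m[:, :2])
        return AffineTransform.from_array(np.column_stack([lin_inv, -lin_inv @ m[:, 2]]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.as_array().tolist()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        with open(path) as fh:
            return cls.from_array(np.array(json.load(fh)["matrix"]))


@dataclass
class AffineFitReport:
    """Least-squares fit diagnostics; residuals in px (and µm if calibrated)."""

    transform: AffineTransform
    residuals_px: np.ndarray  # per-pair Euclidean residual
    rms_px: float
    rms_um: float | None


def fit_affine(
    src_points,
    dst_points,
    target_calibration: Calibration | None = None,
) -> AffineFitReport:
    """Least-squares affine minimizing Σ‖A·src − dst‖² over ≥3 non-collinear
    correspondence pairs."""
    src = np.asarray(src_points, float).reshape(-1, 2)
    dst = np.asarray(dst_points, float).reshape(-1, 2)
    if len(src) != len(dst):
        raise ValueError("src and dst landmark lists differ in length")
    if len(src) < 3:
        raise DegenerateLandmarksError("at least 3 landmark pairs required")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design, tol=1e-9) < 3:
        raise DegenerateLandmarksError("collinear landmark configuration")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    transform = AffineTransform.from_array(sol.T)
    res = np.linalg.norm(transform.apply(src) - dst, axis=1)
    rms_px = float(np.sqrt(np.mean(res**2)))
    rms_um = (
        rms_px * target_calibration.microns_per_pixel if target_calibration is not None else None
    )
    return AffineFitReport(transform=transform, residuals_px=res, rms_px=rms_px, rms_um=rms_um)


def transfer_annotations(
    dots: CellDetections,
    transform: AffineTransform,
    target_calibration: Calibration,
) -> tuple[CellDetections, int]:
    """Map dot annotations into the target frame; dots landing outside the
    frame are dropped and their count returned.  Labels are preserved and
    point order is stable."""
    mapped = transform.apply(dots.points) if len(dots) else dots.points.copy()
    inside = np.ones(len(dots), dtype=bool)
    if len(dots):
        inside = (
            (mapped[:, 0] >= 0)
            & (mapped[:, 0] < target_calibration.width_px)
            & (mapped[:, 1] >= 0)
            & (mapped[:, 1] < target_calibration.height_px)
        )
    out = CellDetections(mapped[inside], dots.labels[inside], target_calibration)
    return out, int((~inside).sum())
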