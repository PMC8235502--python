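"""sTIL density and local-density heatmap.

The slide-level biomarker is the number of kept TILs per mm² of
tumor-associated stroma.  The heatmap shows the same quantity locally under
a fixed circular kernel (default radius 200 µm), restricted to stroma and
normalized by the disk∩stroma area so boundary pixels are not
underestimated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from . import __version__
from .geometry import GeometryParams
from .raster import (
    BinaryMask,
    CalibrationError,
    CellClass,
    CellDetections,
    _count_convolve,
    disk_footprint,
)

__all__ = ["BiomarkerResult", "compute_density", "local_density_heatmap", "render_heatmap"]

DEFAULT_HEATMAP_RADIUS_UM = 200.0


class UndefinedDensityError(ValueError):
    """Raised when the stroma area is zero: the density is undefined, never 0."""


@dataclass
class BiomarkerResult:
    """Slide-level sTIL biomarker with provenance.

    Invariant: ``stil_density_per_mm2 * stroma_area_mm2 == til_count`` exactly
    (the density is stored unrounded; rounding happens only at display).
    """

    stil_density_per_mm2: float
    til_count: int
    stroma_area_mm2: float
    params: dict
    provenance: dict
    heatmap: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        return {
            "stil_density_per_mm2": self.stil_density_per_mm2,
            "til_count": self.til_count,
            "stroma_area_mm2": self.stroma_area_mm2,
            "params": self.params,
            "provenance": self.provenance,
        }


def _provenance(kept: CellDetections, stroma: BinaryMask) -> dict:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(kept.points).tobytes())
    h.update(np.ascontiguousarray(kept.labels).tobytes())
    h.update(np.packbits(stroma.raster).tobytes())
    return {
        "input_sha256": h.hexdigest(),
        "stilquant_version": __version__,
        "microns_per_pixel": stroma.calibration.microns_per_pixel,
    }


def compute_density(
    kept: CellDetections,
    stroma: BinaryMask,
    params: GeometryParams | None = None,
) -> BiomarkerResult:
    """sTIL density = kept TIL count / stroma area in mm².

    Raises :class:`UndefinedDensityError` on zero stroma area rather than
    silently reporting 0.
    """
    if kept.calibration != stroma.calibration:
        raise CalibrationError("cells and stroma mask must share one calibration")
    area = stroma.area_mm2
    if area <= 0:
        raise UndefinedDensityError("stroma area is zero: sTIL density undefined")
    count = int((kept.labels == int(CellClass.TIL)).sum())
    p = (params or GeometryParams()).to_dict()
    p["heatmap_radius_um"] = DEFAULT_HEATMAP_RADIUS_UM
    return BiomarkerResult(
        stil_density_per_mm2=count / area,
        til_count=count,
        stroma_area_mm2=area,
        params=p,
        provenance=_provenance(kept, stroma),
    )


def local_density_heatmap(
    kept: CellDetections,
    stroma: BinaryMask,
    radius_um: float = DEFAULT_HEATMAP_RADIUS_UM,
) -> np.ndarray:
    """Local sTIL density (cells/mm²) under a circular kernel, on stroma.

    Points are snapped to their nearest pixel; the value at a stroma pixel p
    is (TILs within radius of p) / (disk∩stroma area in mm²).  Non-stroma
    pixels carry NaN.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if kept.calibration != stroma.calibration:
        raise CalibrationError("cells and stroma mask must share one calibration")
    cal = stroma.calibration
    r_px = cal.um_to_px(radius_um)
    if r_px < 1:
        raise CalibrationError("heatmap radius below one pixel")
    fp = disk_footprint(r_px)

    counts = np.zeros(cal.shape, dtype=np.float64)
    til = kept.labels == int(CellClass.TIL)
    if til.any():
        ix, iy = kept.select(til).nearest_pixels()
        np.add.at(counts, (iy, ix), 1.0)

    num = _count_convolve(counts, fp)
    area_px = _count_convolve(stroma.raster, fp)
    out = np.full(cal.shape, np.nan)
    s = stroma.raster
    out[s] = num[s] / (area_px[s] * cal.pixel_area_mm2)
    return out


# fixed value→color ramp (viridis-like stops, interpolated linearly)
_RAMP = np.array(
    [[68, 1, 84], [59, 82, 139], [33, 145, 140], [94, 201, 98], [253, 231, 37]],
    dtype=float,
)


def _colorize(vals: np.ndarray, vmax: float) -> np.ndarray:
    t = np.clip(vals / vmax if vmax > 0 else np.zeros_like(vals), 0.0, 1.0)
    pos = t * (len(_RAMP) - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, len(_RAMP) - 1)
    w = (pos - lo)[..., None]
    return ((1 - w) * _RAMP[lo] + w * _RAMP[hi]).astype(np.uint8)


def render_heatmap(heatmap: np.ndarray, out_path, vmax: float | None = None) -> None:
    """Write the heatmap as an 8-bit color-mapped PNG with a ramp legend.

    The value→color ramp is fixed; values above ``vmax`` (default: finite
    max) are clamped to the top color and the legend notes the clamp.
    Output bytes are deterministic for fixed input.
    """
    finite = np.isfinite(heatmap)
    vals = np.where(finite, heatmap, 0.0)
    data_max = float(vals[finite].max()) if finite.any() else 0.0
    if vmax is None:
        vmax = data_max
    rgb = _colorize(vals, vmax)
    rgb[~finite] = (255, 255, 255)  # non-stroma → white

    h, w = heatmap.shape
    bar_w = 48
    canvas = np.full((h, w + bar_w, 3), 255, dtype=np.uint8)
    canvas[:, :w] = rgb
    if h >= 60:  # ramp bar needs vertical room; tiny heatmaps get labels only
        ramp_vals = np.linspace(vmax, 0.0, h - 40)
        ramp = _colorize(ramp_vals[:, None], vmax)
        canvas[20 : 20 + len(ramp_vals), w + 8 : w + 24] = ramp

    img = Image.fromarray(canvas, mode="RGB")
    draw = ImageDraw.Draw(img)
    top_label = f"{vmax:.0f}" + ("+" if data_max > vmax else "")
    draw.text((w + 8, 6), top_label, fill=(0, 0, 0))
    draw.text((w + 8, h - 16), "0", fill=(0, 0, 0))
    img.save(out_path, format="PNG")
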