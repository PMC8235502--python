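"""File I/O for masks, detections, slides and landmarks.

Formats are deliberately plain: paletted PNG / single-channel TIFF rasters
with a JSON sidecar carrying the class map and µm-per-pixel calibration;
0/255 PNG binary masks; CSV or GeoJSON point lists with the calibration in
a header/metadata field.  Anisotropic calibrations are rejected at load
time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .backends import SlideImage
from .geometry import RegionPartition
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
    "save_label_mask",
    "load_label_mask",
    "save_binary_mask",
    "load_binary_mask",
    "save_cells_csv",
    "load_cells_csv",
    "save_cells_geojson",
    "load_cells_geojson",
    "save_slide_image",
    "load_slide_image",
    "save_partition",
    "load_landmarks_csv",
    "save_landmarks_csv",
]

_CLASS_PALETTE_PNG = {
    int(TissueClass.BACKGROUND): (255, 255, 255),
    int(TissueClass.STROMA): (235, 180, 200),
    int(TissueClass.TUMOR): (120, 80, 160),
    int(TissueClass.NECROSIS): (200, 120, 90),
    int(TissueClass.NONINVASIVE_EPITHELIUM): (230, 200, 120),
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, microns_per_pixel: float, extra: dict | None = None) -> None:
    meta = {
        "microns_per_pixel": microns_per_pixel,
        "classes": {str(int(c)): c.name for c in TissueClass},
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise CalibrationError(f"missing calibration sidecar: {sc}")
    meta = json.loads(sc.read_text())
    mpp = meta.get("microns_per_pixel")
    if mpp is None:
        raise CalibrationError(f"sidecar {sc} lacks microns_per_pixel")
    if isinstance(mpp, (list, tuple)):
        if len(set(mpp)) != 1:
            raise CalibrationError(f"anisotropic calibration in {sc}: {mpp}")
        meta["microns_per_pixel"] = float(mpp[0])
    return meta


def save_label_mask(mask: LabelMask, path) -> None:
    """Paletted PNG or single-channel TIFF + JSON sidecar with class map."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.raster)
    else:
        img = Image.fromarray(mask.raster, mode="P")
        palette = []
        for code in range(max(_CLASS_PALETTE_PNG) + 1):
            palette.extend(_CLASS_PALETTE_PNG.get(code, (0, 0, 0)))
        img.putpalette(palette)
        img.save(path, format="PNG")
    _write_sidecar(path, mask.calibration.microns_per_pixel)


def load_label_mask(path) -> LabelMask:
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raster = tifffile.imread(path)
    else:
        raster = np.asarray(Image.open(path).convert("P"), dtype=np.uint8)
    cal = Calibration(float(meta["microns_per_pixel"]), raster.shape[1], raster.shape[0])
    return LabelMask(raster, cal)


def save_binary_mask(mask: BinaryMask, path) -> None:
    """0/255 grayscale PNG + sidecar."""
    path = Path(path)
    Image.fromarray((mask.raster * np.uint8(255))).save(path, format="PNG")
    _write_sidecar(path, mask.calibration.microns_per_pixel)


def load_binary_mask(path) -> BinaryMask:
    path = Path(path)
    meta = _read_sidecar(path)
    arr = np.asarray(Image.open(path).convert("L"))
    cal = Calibration(float(meta["microns_per_pixel"]), arr.shape[1], arr.shape[0])
    return BinaryMask(arr > 127, cal)


_CELL_HEADER = "# stilquant cells v1 microns_per_pixel={mpp} width_px={w} height_px={h}\n"


def save_cells_csv(cells: CellDetections, path) -> None:
    """CSV with a metadata header line and columns x_px, y_px, label."""
    path = Path(path)
    cal = cells.calibration
    labels = [CellClass(int(v)).name for v in cells.labels]
    df = pd.DataFrame({"x_px": cells.points[:, 0], "y_px": cells.points[:, 1], "label": labels})
    with open(path, "w") as fh:
        fh.write(_CELL_HEADER.format(mpp=cal.microns_per_pixel, w=cal.width_px, h=cal.height_px))
        df.to_csv(fh, index=False)


def load_cells_csv(path) -> CellDetections:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# stilquant cells"):
            raise CalibrationError(f"{path}: missing calibration header line")
        kv = dict(tok.split("=") for tok in header.split() if "=" in tok)
        df = pd.read_csv(fh)
    cal = Calibration(float(kv["microns_per_pixel"]), int(kv["width_px"]), int(kv["height_px"]))
    labels = np.array([int(CellClass[name]) for name in df["label"]], dtype=np.int64)
    return CellDetections(df[["x_px", "y_px"]].to_numpy(float), labels, cal)


def save_cells_geojson(cells: CellDetections, path) -> None:
    """GeoJSON FeatureCollection of Point features with a "label" property;
    calibration carried in foreign members."""
    cal = cells.calibration
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"label": CellClass(int(lab)).name},
        }
        for (x, y), lab in zip(cells.points, cells.labels)
    ]
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "microns_per_pixel": cal.microns_per_pixel,
        "width_px": cal.width_px,
        "height_px": cal.height_px,
    }
    Path(path).write_text(json.dumps(doc))


def load_cells_geojson(path) -> CellDetections:
    doc = json.loads(Path(path).read_text())
    try:
        cal = Calibration(float(doc["microns_per_pixel"]), int(doc["width_px"]), int(doc["height_px"]))
    except KeyError as exc:
        raise CalibrationError(f"{path}: missing calibration member {exc}") from exc
    pts, labs = [], []
    for feat in doc["features"]:
        pts.append(feat["geometry"]["coordinates"])
        labs.append(int(CellClass[feat["properties"]["label"]]))
    return CellDetections(np.array(pts, float).reshape(-1, 2), np.array(labs, np.int64), cal)


def save_slide_image(image: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.rgb)
    else:
        Image.fromarray(image.rgb).save(path, format="PNG")
    _write_sidecar(path, image.calibration.microns_per_pixel)


def load_slide_image(path) -> SlideImage:
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        rgb = tifffile.imread(path)
    else:
        rgb = np.asarray(Image.open(path).convert("RGB"))
    cal = Calibration(float(meta["microns_per_pixel"]), rgb.shape[1], rgb.shape[0])
    return SlideImage(rgb, cal)


def save_partition(partition: RegionPartition, out_dir) -> None:
    """Per-mask PNGs + a provenance JSON embedding the geometry parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_binary_mask(partition.macro_tumor, out / "macro_tumor.png")
    save_binary_mask(partition.tumor_associated_stroma, out / "tumor_associated_stroma.png")
    save_binary_mask(partition.exclusion_zone, out / "exclusion_zone.png")
    save_binary_mask(partition.raw_stroma, out / "raw_stroma.png")
    (out / "geometry_params.json").write_text(
        json.dumps(partition.params.to_dict(), indent=2, sort_keys=True)
    )


def save_landmarks_csv(src: np.ndarray, dst: np.ndarray, path) -> None:
    pd.DataFrame(
        {
            "src_x": np.asarray(src, float)[:, 0],
            "src_y": np.asarray(src, float)[:, 1],
            "dst_x": np.asarray(dst, float)[:, 0],
            "dst_y": np.asarray(dst, float)[:, 1],
        }
    ).to_csv(path, index=False)


def load_landmarks_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df[["src_x", "src_y"]].to_numpy(float), df[["dst_x", "dst_y"]].to_numpy(float)
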