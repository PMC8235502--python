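"""End-to-end orchestration: slide → masks → geometry → density → heatmap,
and cohort → cutpoint → survival tables → concordance report.

Both entry points are plain functions over the library modules; the CLI in
:mod:`stilquant.cli` is a thin wrapper.  Every artifact embeds the config
hash and input hashes so reruns are reproducible bit-for-bit for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, io, stats
from .backends import (
    ClassPalette,
    ReferenceCellDetector,
    ReferenceTissueDetector,
    ReferenceTissueSegmenter,
    SlideImage,
)
from .density import (
    DEFAULT_HEATMAP_RADIUS_UM,
    BiomarkerResult,
    compute_density,
    local_density_heatmap,
    render_heatmap,
)
from .geometry import AuditCode, EmptyMacroTumorError, GeometryParams, build_partition, filter_tils
from .raster import CellClass, CellDetections, LabelMask, dilate_um

log = logging.getLogger("stilquant")

__all__ = ["PipelineConfig", "run_slide", "run_cohort", "SlideRunError"]


class SlideRunError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable run configuration (hashed into provenance)."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    heatmap_radius_um: float = DEFAULT_HEATMAP_RADIUS_UM
    backend: str = "reference-color"
    backend_options: dict = field(default_factory=dict)
    manual_cutpoint_pct: float = stats.MANUAL_CUTPOINT_PCT
    density_cutpoint: float | None = None  # None → select by maxstat
    maxstat_window: tuple[float, float] = (0.10, 0.90)
    maxstat_p_method: str = "miller-siegmund"
    seed: int = 0

    _KNOWN = (
        "geometry",
        "heatmap_radius_um",
        "backend",
        "backend_options",
        "manual_cutpoint_pct",
        "density_cutpoint",
        "maxstat_window",
        "maxstat_p_method",
        "seed",
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(cls._KNOWN)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "geometry" in kwargs:
            geo = kwargs["geometry"]
            unknown_geo = set(geo) - {f.name for f in dataclasses.fields(GeometryParams)}
            if unknown_geo:
                raise ValueError(f"unknown geometry keys: {sorted(unknown_geo)}")
            kwargs["geometry"] = GeometryParams(**geo)
        if "maxstat_window" in kwargs:
            kwargs["maxstat_window"] = tuple(kwargs["maxstat_window"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maxstat_window"] = list(d["maxstat_window"])
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _hash_inputs(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _reference_backends(config: PipelineConfig):
    opts = dict(config.backend_options)
    palette = opts.pop("palette", None) or ClassPalette()
    return (
        ReferenceTissueDetector(palette, **opts.get("tissue_detect", {})),
        ReferenceTissueSegmenter(palette, **opts.get("tissue_segment", {})),
        ReferenceCellDetector(palette, **opts.get("cell_detect", {})),
    )


def run_slide(
    config: PipelineConfig,
    out_dir,
    image: SlideImage | None = None,
    labels: LabelMask | None = None,
    cells: CellDetections | None = None,
    backends: tuple | None = None,
) -> BiomarkerResult:
    """Run the slide-level pipeline and write all artifacts to ``out_dir``.

    Either a raw ``image`` (inference backends run) or precomputed
    ``labels`` + ``cells`` (backends skipped) must be provided.  Writes
    region masks, the per-cell audit table, the biomarker JSON, and the
    heatmap (float TIFF + rendered PNG).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geo = config.geometry
    log.info(
        "geometry parameters: kernel_radius=%g µm, morph_radius=%g µm, margin=%g µm, "
        "epi_exclusion=%g µm, heatmap_radius=%g µm",
        geo.kernel_radius_um, geo.morph_radius_um, geo.margin_um,
        geo.epi_exclusion_um, config.heatmap_radius_um,
    )

    if image is not None and (labels is None or cells is None):
        detector, segmenter, cell_detector = backends or _reference_backends(config)
        tissue = detector.detect_tissue(image)
        labels = segmenter.segment_tissue(image, tissue)
        io.save_label_mask(labels, out / "labels.png")
        try:
            partition = build_partition(labels, geo)
        except EmptyMacroTumorError as exc:
            raise SlideRunError(str(exc)) from exc
        roi = dilate_um(partition.macro_tumor, geo.margin_um)
        cells = cell_detector.detect_cells(image, roi)
    elif labels is not None and cells is not None:
        io.save_label_mask(labels, out / "labels.png")
        try:
            partition = build_partition(labels, geo)
        except EmptyMacroTumorError as exc:
            raise SlideRunError(str(exc)) from exc
    else:
        raise ValueError("provide either image, or labels and cells")

    io.save_partition(partition, out / "masks")
    filtered = filter_tils(cells, partition.tumor_associated_stroma, partition.exclusion_zone, labels)
    audit = pd.DataFrame(
        {
            "x_px": cells.points[:, 0],
            "y_px": cells.points[:, 1],
            "label": [CellClass(int(v)).name for v in cells.labels],
            "audit": [AuditCode(int(c)).name for c in filtered.codes],
        }
    )
    audit.to_csv(out / "cell_audit.csv", index=False)

    result = compute_density(filtered.kept, partition.tumor_associated_stroma, geo)
    heatmap = local_density_heatmap(
        filtered.kept, partition.tumor_associated_stroma, config.heatmap_radius_um
    )
    result.heatmap = heatmap
    tifffile.imwrite(out / "heatmap.tiff", heatmap.astype(np.float32))
    render_heatmap(heatmap, out / "heatmap.png")

    payload = result.to_json_dict()
    payload["provenance"]["config_sha256"] = config.hash()
    payload["provenance"]["cells_labels_sha256"] = _hash_inputs(
        cells.points, cells.labels, labels.raster
    )
    (out / "biomarker.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    log.info(
        "sTIL density %.1f cells/mm² (%d TILs / %.3f mm² stroma)",
        result.stil_density_per_mm2, result.til_count, result.stroma_area_mm2,
    )
    return result


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_COVARIATES = stats.COVARIATE_CODINGS


def _tidy(fit: stats.SurvivalFit, model: str, endpoint: str) -> pd.DataFrame:
    df = fit.summary()
    df.insert(0, "endpoint", endpoint)
    df.insert(0, "model", model)
    df["n"] = fit.n_used
    df["events"] = fit.n_events
    return df


def run_cohort(config: PipelineConfig, table: pd.DataFrame, out_dir) -> dict:
    """Run the cohort-level statistics and write tidy CSV artifacts.

    Emits: the selected density cutpoint, KM step tables and plots for both
    endpoints under both dichotomizations, univariate and multivariate Cox
    tables (manual and density models), the manual-vs-density concordance
    report, and a summary JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = stats.prepare_cohort(table)
    n_total = len(df)
    complete = df.dropna(subset=["stil_density", "manual_stil_pct", "os_time", "os_event"])
    log.info("cohort: %d patients, %d excluded for incomplete core data",
             n_total, n_total - len(complete))

    # cutpoint selection on OS
    if config.density_cutpoint is None:
        try:
            cut = stats.maxstat_cutpoint(
                complete["os_time"], complete["os_event"], complete["stil_density"],
                window=config.maxstat_window, p_method=config.maxstat_p_method,
                seed=config.seed,
            )
        except ValueError as exc:
            log.warning("cutpoint selection not possible (%s); using the median density", exc)
            cut = None
        if cut is None:
            density_cutpoint = float(np.median(complete["stil_density"])) if len(complete) else 0.0
            cut_info = {"cutpoint": density_cutpoint, "p_method": "median fallback"}
        else:
            density_cutpoint = cut.cutpoint
            cut_info = {
                "cutpoint": cut.cutpoint,
                "statistic": cut.statistic,
                "p_adjusted": cut.p_adjusted,
                "p_method": cut.p_method,
                "window": list(cut.window),
                "n_candidates": cut.n_candidates,
            }
    else:
        density_cutpoint = float(config.density_cutpoint)
        cut_info = {"cutpoint": density_cutpoint, "p_method": "fixed"}

    manual_grp = stats.dichotomize(df["manual_stil_pct"], config.manual_cutpoint_pct, "strictly_greater")
    density_grp = stats.dichotomize(df["stil_density"], density_cutpoint, "geq")

    km_rows = []
    logrank_rows = []
    for endpoint, tcol, ecol in (("OS", "os_time", "os_event"), ("RFS", "rfs_time", "rfs_event")):
        sub = df.reset_index(drop=True).dropna(subset=[tcol, ecol, "stil_density", "manual_stil_pct"])
        for marker, grp in (("manual", manual_grp), ("density", density_grp)):
            high = grp.high[sub.index.to_numpy()]
            for level, m in (("high", high), ("low", ~high)):
                if m.sum() == 0:
                    continue
                km = stats.km_estimate(sub[tcol].to_numpy()[m], sub[ecol].to_numpy()[m])
                t = km.to_frame()
                t.insert(0, "group", level)
                t.insert(0, "marker", marker)
                t.insert(0, "endpoint", endpoint)
                km_rows.append(t)
            if 0 < high.sum() < len(sub):
                lr = stats.logrank_stat(sub[tcol].to_numpy(), sub[ecol].to_numpy(), high)
                logrank_rows.append(
                    {"endpoint": endpoint, "marker": marker, "z": lr.z, "chi2": lr.chi2, "p": lr.p}
                )
    pd.concat(km_rows, ignore_index=True).to_csv(out / "km_curves.csv", index=False)
    pd.DataFrame(logrank_rows).to_csv(out / "logrank.csv", index=False)
    _plot_km(df, manual_grp, density_grp, out)

    scaling = {"manual_stil_pct": stats.MANUAL_SCALE, "stil_density": stats.DENSITY_SCALE}
    uni, multi = [], []
    single_terms = [["age_ge50"], ["nodes_1_3", "nodes_ge4"], ["size_gt2cm"],
                    ["type_lobular", "type_other"], ["manual_stil_pct"], ["stil_density"]]
    for endpoint, tcol, ecol in (("OS", "os_time", "os_event"), ("RFS", "rfs_time", "rfs_event")):
        for terms in single_terms:
            try:
                fit = stats.cox_fit(df, tcol, ecol, terms, scaling)
                uni.append(_tidy(fit, "univariate", endpoint))
            except (ValueError, stats.CoxConvergenceError) as exc:
                log.warning("univariate Cox (%s, %s) skipped: %s", endpoint, terms, exc)
        for marker in ("manual_stil_pct", "stil_density"):
            terms = [marker, "size_gt2cm", "age_ge50", "nodes_1_3", "nodes_ge4",
                     "type_lobular", "type_other"]
            try:
                fit = stats.cox_fit(df, tcol, ecol, terms, scaling)
                multi.append(_tidy(fit, f"multivariate_{marker}", endpoint))
            except (ValueError, stats.CoxConvergenceError) as exc:
                log.warning("multivariate Cox (%s, %s) skipped: %s", endpoint, marker, exc)
    if uni:
        pd.concat(uni, ignore_index=True).to_csv(out / "cox_univariate.csv", index=False)
    if multi:
        pd.concat(multi, ignore_index=True).to_csv(out / "cox_multivariate.csv", index=False)

    rep = stats.concordance_report(
        manual_grp.high, density_grp.high, ids=df["id"].to_numpy(),
        manual_scores=df["manual_stil_pct"], auto_scores=df["stil_density"],
        manual_cutpoint=config.manual_cutpoint_pct, auto_cutpoint=density_cutpoint,
    )
    rep.discrepant.to_csv(out / "discrepant_cases.csv", index=False)

    r_s, p_s = float("nan"), float("nan")
    both = df.dropna(subset=["manual_stil_pct", "stil_density"])
    if len(both) >= 3:
        from scipy.stats import spearmanr

        r_s, p_s = spearmanr(both["manual_stil_pct"], both["stil_density"])

    summary = {
        "config_sha256": config.hash(),
        "stilquant_version": __version__,
        "n_patients": n_total,
        "cutpoint": cut_info,
        "dichotomization": {
            "manual": {"cutpoint": config.manual_cutpoint_pct, "rule": "strictly_greater"},
            "density": {"cutpoint": density_cutpoint, "rule": "geq"},
        },
        "concordance": {
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "tp": rep.tp, "fp": rep.fp, "tn": rep.tn, "fn": rep.fn,
        },
        "spearman_manual_vs_density": {"r_s": float(r_s), "p": float(p_s)},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _plot_km(df: pd.DataFrame, manual_grp, density_grp, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, (name, grp) in zip(axes, (("manual sTIL", manual_grp), ("sTIL density", density_grp))):
        for level, m, color in (("high", grp.high, "tab:red"), ("low", ~grp.high, "tab:blue")):
            sub = df[m & df["os_time"].notna()]
            if len(sub) == 0:
                continue
            km = stats.km_estimate(sub["os_time"], sub["os_event"])
            ax.step(km.timeline, km.survival, where="post", color=color, label=level)
        ax.set_title(name)
        ax.set_xlabel("days")
        ax.legend()
    axes[0].set_ylabel("overall survival")
    fig.tight_layout()
    fig.savefig(out / "km_os.png", dpi=100)
    plt.close(fig)
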