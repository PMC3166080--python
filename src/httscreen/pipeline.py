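"""End-to-end orchestration: simulate -> QC -> segment -> morphometry ->
statistics -> report.

Stages communicate through plain TSV caches, so any stage can be rerun
from the previous stage's output and reproduce identical downstream
statistics. All exclusions (out-of-focus fields, cell-free fields,
treatments with too few usable images) are logged with the rule that
fired and recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .model import ScreenModel
from .morphometry import (
    FEATURE_NAMES,
    compute_features,
    fit_area_bins,
    fit_length_groups,
    save_models,
)
from .plate_io import (
    Channel,
    FieldImage,
    Genotype,
    PlateLayout,
    adaptive_focus_threshold,
    assess_field_quality,
    focus_metric,
    image_filename,
    load_plate_layout,
    qc_table,
    read_field_image,
    select_usable_wells,
)
from .segmentation import (
    SegmentationConfig,
    SegmentationResult,
    calibrate_aggregate_threshold,
    count_aggregate_pixels,
    segment_morphology,
)
from .stats import Stage1Rule
from .synthetic import ScreenData

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Configuration of one analysis run."""

    images_dir: str = ""
    layout_path: str = ""
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    alpha: float = 0.05
    threshold_multiplier: float = 2.0
    min_images: int = 6
    stage1_rule: Stage1Rule = Stage1Rule.AND
    rescue_floor: float = 1e-6
    aggregate_quantile: float = 0.999
    focus_fraction: float = 0.25
    model_scope: str = "per-screen"  # or "per-plate"
    seed: int = 0

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation"]["morph_threshold_method"] = \
            self.segmentation.morph_threshold_method.value
        d["stage1_rule"] = self.stage1_rule.value
        return d


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0
    input_checksum: str = ""
    counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        tested = self.counts.get("treatments_tested", 0)
        excl = self.counts.get("treatments_excluded", 0)
        total = self.counts.get("treatments_total", tested + excl)
        if tested + excl != total:  # pragma: no cover - defensive
            raise ConfigurationError("manifest counts inconsistent")
        path.write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# field sources
# ---------------------------------------------------------------------------

def iter_disk_fields(images_dir: Path, layout: PlateLayout):
    """Yield (well, site, morphology image, reporter image) for every
    well/site pair found on disk."""
    for well_id in layout.wells:
        site = 1
        while True:
            mpath = images_dir / image_filename(layout.plate_id, well_id,
                                                site, Channel.MORPHOLOGY)
            rpath = images_dir / image_filename(layout.plate_id, well_id,
                                                site, Channel.REPORTER)
            if not mpath.exists():
                break
            morph = read_field_image(mpath, well_id, site, Channel.MORPHOLOGY)
            rep = read_field_image(rpath, well_id, site, Channel.REPORTER)
            yield well_id, site, morph, rep
            site += 1


def infer_plate_id(images_dir: Path) -> str | None:
    """Recover the plate id from ``{plate}_{well}_s{site}_{channel}.tif``
    filenames (the plate id itself may contain underscores)."""
    for p in sorted(images_dir.glob("*.tif")):
        parts = p.stem.split("_")
        if len(parts) >= 4 and parts[-2].startswith("s"):
            return "_".join(parts[:-3])
    return None


def _checksum_dir(images_dir: Path) -> str:
    crc = 0
    for p in sorted(images_dir.glob("*.tif")):
        crc = zlib.crc32(f"{p.name}:{p.stat().st_size}".encode(), crc)
    return f"{crc:08x}"


# ---------------------------------------------------------------------------
# staged analysis
# ---------------------------------------------------------------------------

@dataclass
class QuantifiedScreen:
    """Per-field segmentation output plus QC for one screen."""

    layout: PlateLayout
    seg_results: dict[tuple[str, int], SegmentationResult]
    qc: pd.DataFrame
    aggregate_threshold: float


def quantify_fields(fields, layout: PlateLayout,
                    config: ScreenConfig) -> QuantifiedScreen:
    """Segment every field, calibrate the aggregate threshold on the
    non-pathogenic vehicle wells, count aggregate pixels and run QC.

    ``fields`` yields (well, site, morphology FieldImage, reporter
    FieldImage) tuples.
    """
    ctrl_wells = set(layout.vehicle_wells(Genotype.HTT15Q))
    if len(ctrl_wells) < 1:
        raise ConfigurationError("layout has no Htt15Q vehicle wells to "
                                 "calibrate the aggregate threshold")
    seg_results: dict[tuple[str, int], SegmentationResult] = {}
    reporters: dict[tuple[str, int], FieldImage] = {}
    morphs: dict[tuple[str, int], FieldImage] = {}
    for well, site, morph, rep in fields:
        seg_results[(well, site)] = segment_morphology(morph,
                                                       config.segmentation)
        reporters[(well, site)] = rep
        morphs[(well, site)] = morph

    ref_imgs = [img for (w, _s), img in reporters.items() if w in ctrl_wells]
    threshold = calibrate_aggregate_threshold(ref_imgs,
                                              q=config.aggregate_quantile)
    seg_cfg = dataclasses.replace(config.segmentation,
                                  aggregate_threshold=threshold)
    for key, rep in reporters.items():
        seg_results[key].aggregate_pixel_count = count_aggregate_pixels(
            rep, seg_cfg)

    # focus threshold adapts to the plate's vehicle wells
    vehicle_wells = {w for w, c in layout.wells.items() if c.is_vehicle}
    metrics = {key: focus_metric(img) for key, img in morphs.items()}
    vehicle_metrics = [m for (w, _s), m in metrics.items()
                       if w in vehicle_wells]
    focus_cut = adaptive_focus_threshold(vehicle_metrics,
                                         config.focus_fraction)
    reports = []
    for (well, site), img in morphs.items():
        rep = assess_field_quality(img, seg_results[(well, site)].neuromere_count,
                                   focus_threshold=focus_cut)
        if not rep.usable:
            rule = "out of focus" if not rep.in_focus else "no cell profiles"
            logger.info("excluding field %s site %d: %s", well, site, rule)
        reports.append(rep)
    return QuantifiedScreen(layout=layout, seg_results=seg_results,
                            qc=qc_table(reports),
                            aggregate_threshold=threshold)


def build_feature_table(quant: QuantifiedScreen, config: ScreenConfig,
                        models_out: Path | None = None) -> pd.DataFrame:
    """Fit the binning models on pooled vehicle-well objects and compute
    the eight-feature vector for every usable field."""
    layout = quant.layout
    usable = {(r.well, r.site) for r in quant.qc.itertuples() if r.usable}
    vehicle_wells = {w for w, c in layout.wells.items() if c.is_vehicle}
    pooled_areas: list[float] = []
    pooled_lengths: list[float] = []
    for (well, site), seg in quant.seg_results.items():
        if well in vehicle_wells and (well, site) in usable:
            pooled_areas.extend(np.log2(seg.neuromere_areas_um2))
            pooled_lengths.extend(seg.neurite_segment_lengths_um)
    area_model = fit_area_bins(pooled_areas, seed=config.seed)
    length_model = fit_length_groups(pooled_lengths, seed=config.seed)
    if models_out is not None:
        save_models(area_model, length_model, models_out,
                    provenance={"n_areas": len(pooled_areas),
                                "n_lengths": len(pooled_lengths),
                                "scope": config.model_scope,
                                "source_wells": sorted(vehicle_wells)})

    rows = []
    for (well, site), seg in quant.seg_results.items():
        if (well, site) not in usable or seg.neuromere_count == 0:
            continue
        fv = compute_features(seg, area_model, length_model)
        row = {"plate": layout.plate_id, "well": well, "site": site}
        row.update({n: getattr(fv, n) for n in FEATURE_NAMES})
        row["aggregate_pixels"] = seg.aggregate_pixel_count
        row["zero_neurites"] = fv.zero_neurites
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_screen(fields, layout: PlateLayout, config: ScreenConfig,
                   out_dir: Path | None = None):
    """Full analysis of an image stream; returns (features, results,
    manifest). When ``out_dir`` is given, all stage tables are written."""
    started = time.time()
    quant = quantify_fields(fields, layout, config)
    models_out = out_dir / "models.json" if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    features = build_feature_table(quant, config, models_out)

    inclusion = select_usable_wells(
        [r for r in _qc_reports(quant.qc)], layout,
        min_images=config.min_images)
    included = set(inclusion[inclusion["included"]]["treatment_id"])
    well_to_treatment = {w: c.treatment_id for w, c in layout.wells.items()}
    features = features[[well_to_treatment[w] in included
                         for w in features["well"]]].reset_index(drop=True)

    model = ScreenModel(features, layout, alpha=config.alpha,
                        threshold_multiplier=config.threshold_multiplier,
                        stage1_rule=config.stage1_rule,
                        rescue_floor=config.rescue_floor)
    results = model.fit()

    n_treat = len(layout.treatments())
    manifest = RunManifest(
        config=config.snapshot(), started=started, finished=time.time(),
        counts={
            "images_read": len(quant.seg_results),
            "images_usable": int(quant.qc["usable"].sum()),
            "treatments_total": n_treat,
            "treatments_tested": len(results.agg_tests),
            "treatments_excluded": n_treat - len(results.agg_tests),
            "hits_dual": results.class_counts["DUAL_HIT"],
            "hits_suppressor_only": results.class_counts["AGG_SUPPRESSOR_ONLY"],
        })

    if out_dir:
        write_segmentation_tables(quant, out_dir)
        features.to_csv(out_dir / "features.tsv", sep="\t", index=False)
        inclusion.to_csv(out_dir / "inclusion.tsv", sep="\t", index=False)
        results.hit_table.to_csv(out_dir / "hits.tsv", sep="\t", index=False)
        results.scatter_data().to_csv(out_dir / "scatter.tsv", sep="\t",
                                      index=False)
        (out_dir / "summary.txt").write_text(results.summary() + "\n")
        manifest.write(out_dir / "manifest.json")
    return features, results, manifest


def _qc_reports(qc: pd.DataFrame):
    from .plate_io import QCReport
    return [QCReport(well_id=r.well, site_index=int(r.site),
                     in_focus=bool(r.in_focus), has_cells=bool(r.has_cells),
                     focus_metric=float(r.focus_metric))
            for r in qc.itertuples()]


def write_segmentation_tables(quant: QuantifiedScreen, out_dir: Path) -> None:
    """Cache segmentation output as TSV: per-object rows plus per-field
    aggregate counts and mask sizes."""
    obj_rows, agg_rows = [], []
    for (well, site), seg in sorted(quant.seg_results.items()):
        for i, a in enumerate(seg.neuromere_areas_um2):
            obj_rows.append({"well": well, "site": site,
                             "object_type": "neuromere", "id": i,
                             "area_um2": a, "length_um": ""})
        for i, ln in enumerate(seg.neurite_segment_lengths_um):
            obj_rows.append({"well": well, "site": site,
                             "object_type": "neurite", "id": i,
                             "area_um2": "", "length_um": ln})
        agg_rows.append({"well": well, "site": site,
                         "aggregate_pixels": seg.aggregate_pixel_count,
                         "neuromere_mask_px": seg.neuromere_pixel_mask_size,
                         "neurite_mask_px": seg.neurite_pixel_mask_size})
    pd.DataFrame(obj_rows, columns=["well", "site", "object_type", "id",
                                    "area_um2", "length_um"]) \
        .to_csv(out_dir / "segmentation.tsv", sep="\t", index=False)
    pd.DataFrame(agg_rows).to_csv(out_dir / "aggregates.tsv", sep="\t",
                                  index=False)
    quant.qc.to_csv(out_dir / "qc.tsv", sep="\t", index=False)
    (out_dir / "aggregate_threshold.json").write_text(
        json.dumps({"aggregate_threshold": quant.aggregate_threshold}))


def load_segmentation_tables(cache_dir: Path,
                             layout: PlateLayout) -> QuantifiedScreen:
    """Rebuild a QuantifiedScreen from cached stage tables."""
    objs = pd.read_csv(cache_dir / "segmentation.tsv", sep="\t")
    aggs = pd.read_csv(cache_dir / "aggregates.tsv", sep="\t")
    qc = pd.read_csv(cache_dir / "qc.tsv", sep="\t")
    thr = json.loads((cache_dir / "aggregate_threshold.json").read_text())
    seg_results: dict[tuple[str, int], SegmentationResult] = {}
    for r in aggs.itertuples():
        seg_results[(r.well, int(r.site))] = SegmentationResult(
            aggregate_pixel_count=int(r.aggregate_pixels),
            neuromere_pixel_mask_size=int(r.neuromere_mask_px),
            neurite_pixel_mask_size=int(r.neurite_mask_px))
    for r in objs.itertuples():
        seg = seg_results[(r.well, int(r.site))]
        if r.object_type == "neuromere":
            seg.neuromere_areas_um2.append(float(r.area_um2))
        else:
            seg.neurite_segment_lengths_um.append(float(r.length_um))
    return QuantifiedScreen(layout=layout, seg_results=seg_results, qc=qc,
                            aggregate_threshold=thr["aggregate_threshold"])


def run_screen(config: ScreenConfig, out_dir: str | Path):
    """Disk-to-disk run: read TIFFs and the layout CSV named by ``config``,
    analyse, and write all output tables into ``out_dir``."""
    images_dir = Path(config.images_dir)
    layout = load_plate_layout(config.layout_path,
                               plate_id=infer_plate_id(images_dir))
    for genotype in (Genotype.HTT15Q, Genotype.HTT138Q):
        if len(layout.vehicle_wells(genotype)) < 2:
            raise ConfigurationError(
                f"layout needs >= 2 vehicle wells for {genotype.value}")
    out_dir = Path(out_dir)
    features, results, manifest = analyze_screen(
        iter_disk_fields(images_dir, layout), layout, config, out_dir)
    manifest.input_checksum = _checksum_dir(images_dir)
    manifest.write(out_dir / "manifest.json")
    return features, results, manifest


def analyze_screen_data(data: ScreenData, config: ScreenConfig,
                        out_dir: Path | None = None):
    """Analyse an in-memory synthetic screen (no TIFF round trip)."""
    fields = ((w, s, m, r) for w, s, m, r in data.fields)
    return analyze_screen(fields, data.layout, config, out_dir)
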