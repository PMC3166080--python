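"""Plate, well and image I/O for the screening pipeline.

Models the screen's plate/well/site structure, reads and writes the
single-plane grayscale TIFFs produced by automated microscopy, and applies
the image- and well-level exclusion rules used for hit calling: wells of a
treatment are only analysed when they contribute enough in-focus images
that actually contain cells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import FormatError, ValidationError

#: µm per pixel edge of the screen's acquisition geometry
#: (1392x1040 px fields spanning 897x670 µm at 10x).
DEFAULT_PIXEL_SIZE_UM = 897.0 / 1392.0

#: Acquisition field shape (rows, cols) of the original screen.
SCREEN_FIELD_SHAPE = (1040, 1392)


class Channel(str, enum.Enum):
    """Imaging channel of a field."""

    MORPHOLOGY = "MORPHOLOGY"  # membrane-bound GFP, all neurons
    REPORTER = "REPORTER"      # Htt-RFP fusion reporter


class Genotype(str, enum.Enum):
    HTT15Q = "HTT15Q"    # non-pathogenic control
    HTT138Q = "HTT138Q"  # pathogenic, aggregate-forming


class TreatmentKind(str, enum.Enum):
    COMPOUND = "COMPOUND"
    RNAI = "RNAI"
    VEHICLE = "VEHICLE"  # DMSO
    MOCK = "MOCK"        # untreated / media-only


@dataclass(frozen=True)
class FieldImage:
    """One channel of one imaged site of one well.

    ``pixels`` is a 2-D non-negative integer array; ``pixel_size_um`` is the
    edge length of a pixel in micrometres.
    """

    well_id: str
    site_index: int
    channel: Channel
    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError("pixels must have an integer dtype")
        if px.min() < 0:
            raise ValidationError("pixel intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.site_index < 1:
            raise ValidationError("site_index must be >= 1")

    @property
    def bit_max(self) -> int:
        """Maximum representable intensity of the image's bit depth."""
        return int(np.iinfo(self.pixels.dtype).max)

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass(frozen=True)
class WellCondition:
    genotype: Genotype
    treatment_id: str
    treatment_kind: TreatmentKind
    concentration: str = ""
    replicate_group: str = ""

    @property
    def is_vehicle(self) -> bool:
        return self.treatment_kind in (TreatmentKind.VEHICLE, TreatmentKind.MOCK)


@dataclass
class PlateLayout:
    """Assignment of a genotype/treatment condition to each well of a plate."""

    plate_id: str
    wells: dict[str, WellCondition] = field(default_factory=dict)

    def __getitem__(self, well_id: str) -> WellCondition:
        return self.wells[well_id]

    def __contains__(self, well_id: str) -> bool:
        return well_id in self.wells

    def wells_where(self, genotype: Genotype | None = None,
                    kind: TreatmentKind | None = None,
                    treatment_id: str | None = None) -> list[str]:
        out = []
        for wid, cond in self.wells.items():
            if genotype is not None and cond.genotype != genotype:
                continue
            if kind is not None and cond.treatment_kind != kind:
                continue
            if treatment_id is not None and cond.treatment_id != treatment_id:
                continue
            out.append(wid)
        return out

    def vehicle_wells(self, genotype: Genotype) -> list[str]:
        return [w for w, c in self.wells.items()
                if c.genotype == genotype and c.is_vehicle]

    def treatments(self) -> list[str]:
        """Unique non-vehicle treatment ids, in layout order."""
        seen: dict[str, None] = {}
        for cond in self.wells.values():
            if not cond.is_vehicle:
                seen.setdefault(cond.treatment_id)
        return list(seen)


@dataclass(frozen=True)
class QCReport:
    """Per-field quality-control verdict.

    ``usable`` is the conjunction of the two exclusion predicates: the field
    must be in focus and must contain at least one segmented cell-body
    cluster.
    """

    well_id: str
    site_index: int
    in_focus: bool
    has_cells: bool
    focus_metric: float

    @property
    def usable(self) -> bool:
        return self.in_focus and self.has_cells


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def image_filename(plate_id: str, well_id: str, site_index: int,
                   channel: Channel) -> str:
    """Canonical TIFF filename: ``{plate}_{well}_s{site}_{channel}.tif``."""
    return f"{plate_id}_{well_id}_s{site_index}_{channel.value}.tif"


def write_field_image(image: FieldImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels)
    return path


def read_field_image(path: str | Path, well_id: str, site_index: int,
                     channel: Channel,
                     pixel_size_um: float | None = None) -> FieldImage:
    """Read a single-plane grayscale TIFF as a :class:`FieldImage`.

    Calibration is taken from ``pixel_size_um`` when given, otherwise the
    screen default (897/1392 µm/px) is used.
    """
    path = Path(path)
    try:
        pixels = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - decoder specifics
        raise FormatError(f"cannot decode TIFF {path}: {exc}") from exc
    if pixels.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-plane grayscale image, "
            f"got shape {pixels.shape}")
    if not np.issubdtype(pixels.dtype, np.integer):
        raise FormatError(f"{path}: expected integer pixel data, "
                          f"got dtype {pixels.dtype}")
    return FieldImage(well_id=well_id, site_index=site_index, channel=channel,
                      pixels=pixels,
                      pixel_size_um=pixel_size_um or DEFAULT_PIXEL_SIZE_UM)


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = ["well", "genotype", "treatment_id", "treatment_kind",
                  "concentration", "unit", "replicate_group"]


def load_plate_layout(path: str | Path, plate_id: str | None = None) -> PlateLayout:
    """Load a plate layout CSV (columns: well, genotype, treatment_id,
    treatment_kind, concentration, unit, replicate_group)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing layout columns {missing}")
    layout = PlateLayout(plate_id=plate_id or path.stem)
    for i, row in df.iterrows():
        well = row["well"].strip()
        if well in layout.wells:
            raise ValidationError(f"{path} row {i}: duplicate well id {well!r}")
        try:
            genotype = Genotype(row["genotype"].strip().upper())
        except ValueError:
            raise ValidationError(
                f"{path} row {i}: unknown genotype {row['genotype']!r}") from None
        try:
            kind = TreatmentKind(row["treatment_kind"].strip().upper())
        except ValueError:
            raise ValidationError(
                f"{path} row {i}: unknown treatment_kind "
                f"{row['treatment_kind']!r}") from None
        conc = row["concentration"].strip()
        if conc and row["unit"].strip():
            conc = f"{conc} {row['unit'].strip()}"
        layout.wells[well] = WellCondition(
            genotype=genotype,
            treatment_id=row["treatment_id"].strip(),
            treatment_kind=kind,
            concentration=conc,
            replicate_group=row["replicate_group"].strip(),
        )
    return layout


def save_plate_layout(layout: PlateLayout, path: str | Path) -> Path:
    rows = []
    for well, cond in layout.wells.items():
        conc, unit = cond.concentration, ""
        if " " in conc:
            conc, unit = conc.split(" ", 1)
        rows.append({"well": well, "genotype": cond.genotype.value,
                     "treatment_id": cond.treatment_id,
                     "treatment_kind": cond.treatment_kind.value,
                     "concentration": conc, "unit": unit,
                     "replicate_group": cond.replicate_group})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def focus_metric(image: FieldImage) -> float:
    """Variance of the discrete Laplacian of the min-max normalised image.

    Sharp, structured fields score high; defocused or featureless fields
    score near zero. Used as a surrogate for the screen's manual
    out-of-focus exclusion.
    """
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return 0.0
    norm = (px - lo) / (hi - lo)
    lap = ndimage.laplace(norm)
    return float(lap.var())


def assess_field_quality(image: FieldImage, neuromere_count: int | None,
                         focus_threshold: float = 0.0) -> QCReport:
    """Build the QC report for a morphology-channel field.

    ``has_cells`` is true when segmentation found at least one neuromere;
    ``in_focus`` compares the Laplacian-variance focus metric against
    ``focus_threshold`` (a threshold of 0 disables focus exclusion).
    """
    fm = focus_metric(image)
    return QCReport(
        well_id=image.well_id,
        site_index=image.site_index,
        in_focus=fm >= focus_threshold,
        has_cells=bool(neuromere_count) if neuromere_count is not None else False,
        focus_metric=fm,
    )


def adaptive_focus_threshold(vehicle_metrics: list[float],
                             fraction: float = 0.25) -> float:
    """Plate-adaptive focus cutoff: ``fraction`` x the median focus metric
    of the plate's vehicle wells."""
    if not vehicle_metrics:
        return 0.0
    return fraction * float(np.median(vehicle_metrics))


def select_usable_wells(qc_reports: list[QCReport], layout: PlateLayout,
                        min_images: int = 6) -> pd.DataFrame:
    """Apply the per-treatment image-count exclusion rule.

    A treatment (pooled over its replicate wells; 3 sites x 2 duplicate
    wells = 6 images in the screen's design) is included when at least
    ``min_images`` of its images pass QC. Returns one row per treatment
    with columns treatment_id, n_images, n_usable, included, reason.
    Vehicle wells are pooled per (genotype, treatment) as well.
    """
    if min_images < 1:
        raise ValidationError("min_images must be >= 1")
    by_treatment: dict[str, dict[str, int]] = {}
    keys_in_order: list[str] = []

    def key_for(cond: WellCondition) -> str:
        return cond.treatment_id

    for cond in layout.wells.values():
        k = key_for(cond)
        if k not in by_treatment:
            by_treatment[k] = {"n_images": 0, "n_usable": 0}
            keys_in_order.append(k)
    for rep in qc_reports:
        if rep.well_id not in layout:
            continue
        k = key_for(layout[rep.well_id])
        by_treatment[k]["n_images"] += 1
        if rep.usable:
            by_treatment[k]["n_usable"] += 1

    rows = []
    for k in keys_in_order:
        counts = by_treatment[k]
        if counts["n_images"] == 0:
            included, reason = False, "no images"
        elif counts["n_usable"] < min_images:
            included = False
            reason = (f"only {counts['n_usable']} usable images "
                      f"(< {min_images})")
        else:
            included, reason = True, ""
        rows.append({"treatment_id": k, "n_images": counts["n_images"],
                     "n_usable": counts["n_usable"], "included": included,
                     "reason": reason})
    return pd.DataFrame(rows)


def qc_table(reports: list[QCReport]) -> pd.DataFrame:
    """QC output table (TSV-ready): well, site, focus_metric, in_focus,
    has_cells, usable."""
    return pd.DataFrame(
        [{"well": r.well_id, "site": r.site_index,
          "focus_metric": r.focus_metric, "in_focus": r.in_focus,
          "has_cells": r.has_cells, "usable": r.usable}
         for r in reports])
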