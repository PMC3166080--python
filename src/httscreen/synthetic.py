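"""Synthetic two-channel culture fields and whole synthetic screens.

No raw images from the original screen are publicly deposited, so every
downstream stage is exercised on generated data with known ground truth.
A field consists of:

* neuromeres — sparse bright quasi-circular blobs whose log2 areas (µm²)
  follow a three-component Gaussian mixture (the structure the area-binning
  stage assumes);
* neurites — thin (2 px) branched random-walk polylines emanating from blob
  boundaries, segment lengths gamma-distributed, forking with a per-step
  branch probability;
* a reporter channel with diffuse (soluble) signal over the neuronal mask
  and, in the mutant, bright punctate aggregates well above the soluble
  band;
* Gaussian point-spread blur and Gaussian read noise.

The non-pathogenic control (Htt15Q) has no aggregates, high soluble
reporter filling neurites, larger neuromeres and longer neurites; the
pathogenic mutant (Htt138Q) has numerous aggregates, low soluble signal,
smaller neuromeres, shorter neurites and increased branching. A ``rescue``
parameter in [0, 1] interpolates every mutant parameter linearly towards
the control set.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .plate_io import (
    DEFAULT_PIXEL_SIZE_UM,
    Channel,
    FieldImage,
    Genotype,
    PlateLayout,
    TreatmentKind,
    WellCondition,
    image_filename,
    save_plate_layout,
    write_field_image,
)

logger = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))

#: default test-scale field shape (rows, cols); the acquisition geometry
#: of the real screen (1040 x 1392) is available via ``field_shape``.
DEFAULT_FIELD_SHAPE = (256, 256)

BACKGROUND_LEVEL = 200.0
SOMA_INTENSITY = 6000.0
NEURITE_INTENSITY = 4000.0
BIT_MAX = 65535


@dataclass(frozen=True)
class CultureParams:
    """Generative parameters of one culture condition.

    Rates are per field; areas are parameterised on the log2-µm² scale;
    neurite lengths are gamma(length_shape, length_scale) in µm.
    """

    neuromere_rate: float = 5.0
    area_mixture: tuple[tuple[float, float, float], ...] = (
        (0.5, 6.0, 0.35), (0.3, 7.5, 0.35), (0.2, 9.0, 0.35))
    neurites_per_neuromere: float = 2.5
    length_shape: float = 3.0
    length_scale: float = 12.0
    branch_prob: float = 0.03
    aggregate_rate: float = 0.0
    aggregate_radius_px: int = 2
    aggregate_intensity: float = 12000.0
    soluble_reporter_level: float = 3000.0
    noise_sd: float = 50.0
    psf_sigma_px: float = 1.0
    rescue: float = 0.0

    def __post_init__(self) -> None:
        if min(self.neuromere_rate, self.neurites_per_neuromere,
               self.aggregate_rate) < 0:
            raise ValidationError("rates must be >= 0")
        w = sum(c[0] for c in self.area_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError("area mixture weights must sum to 1")
        means = [c[1] for c in self.area_mixture]
        if sorted(means) != means or len(set(means)) != len(means):
            raise ValidationError("area mixture means must be strictly increasing")
        if self.aggregate_radius_px < 1:
            raise ValidationError("aggregate_radius_px must be >= 1")


def control_params() -> CultureParams:
    """Htt15Q control condition: no aggregates, bright soluble reporter,
    large neuromeres, long sparse neurites."""
    return CultureParams()


def mutant_params() -> CultureParams:
    """Htt138Q condition: numerous aggregates over dim soluble signal,
    smaller neuromeres, shorter and more branched neurites."""
    return CultureParams(
        area_mixture=((0.5, 5.2, 0.35), (0.3, 6.7, 0.35), (0.2, 8.2, 0.35)),
        length_scale=7.0,
        branch_prob=0.08,
        aggregate_rate=25.0,
        soluble_reporter_level=800.0,
    )


def interpolate_params(mutant: CultureParams, control: CultureParams,
                       rescue: float) -> CultureParams:
    """Element-wise linear interpolation mutant -> control; rescue=0 is the
    mutant, rescue=1 the control."""
    if not 0.0 <= rescue <= 1.0:
        raise ValidationError("rescue must lie in [0, 1]")

    def lerp(a: float, b: float) -> float:
        return a + rescue * (b - a)

    mixture = tuple(
        (lerp(wm, wc), lerp(mm, mc), lerp(sm, sc))
        for (wm, mm, sm), (wc, mc, sc)
        in zip(mutant.area_mixture, control.area_mixture))
    return dataclasses.replace(
        mutant,
        neuromere_rate=lerp(mutant.neuromere_rate, control.neuromere_rate),
        area_mixture=mixture,
        neurites_per_neuromere=lerp(mutant.neurites_per_neuromere,
                                    control.neurites_per_neuromere),
        length_shape=lerp(mutant.length_shape, control.length_shape),
        length_scale=lerp(mutant.length_scale, control.length_scale),
        branch_prob=lerp(mutant.branch_prob, control.branch_prob),
        aggregate_rate=lerp(mutant.aggregate_rate, control.aggregate_rate),
        soluble_reporter_level=lerp(mutant.soluble_reporter_level,
                                    control.soluble_reporter_level),
        rescue=rescue,
    )


class EffectLabel(str, enum.Enum):
    NULL = "NULL"
    AGG_SUPPRESSOR = "AGG_SUPPRESSOR"
    DUAL_RESCUER = "DUAL_RESCUER"
    TOXIC = "TOXIC"


@dataclass(frozen=True)
class EffectSpec:
    """True effect of a planted treatment. ``suppression_factor`` scales
    the aggregate rate (AGG_SUPPRESSOR); ``rescue`` interpolates all
    parameters towards the control (DUAL_RESCUER)."""

    label: EffectLabel = EffectLabel.NULL
    suppression_factor: float = 1.0
    rescue: float = 0.0


@dataclass
class FieldTruth:
    """Everything planted in one field."""

    neuromere_count: int = 0
    neuromere_areas_um2: list[float] = field(default_factory=list)
    log2_areas_drawn: list[float] = field(default_factory=list)
    mixture_components: list[int] = field(default_factory=list)
    segment_lengths_um: list[float] = field(default_factory=list)
    aggregate_pixel_count: int = 0


@dataclass
class ScreenTruth:
    """Per-treatment true effect labels of a synthetic screen."""

    effects: dict[str, EffectSpec] = field(default_factory=dict)
    fields: dict[tuple[str, int], FieldTruth] = field(default_factory=dict)

    def positives(self, label: EffectLabel) -> list[str]:
        return [t for t, e in self.effects.items() if e.label == label]


def field_rng(seed: int, plate_id: str, well_id: str, site: int) -> np.random.Generator:
    """Independent, order-insensitive substream for one field, derived by a
    stable hash of (seed, plate, well, site)."""
    tag = zlib.crc32(f"{plate_id}/{well_id}/{site}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


# ---------------------------------------------------------------------------
# field rendering
# ---------------------------------------------------------------------------

def _place_blob(rng: np.random.Generator, shape: tuple[int, int],
                radius: float, placed: list[tuple[float, float, float]],
                max_tries: int = 50) -> tuple[float, float] | None:
    h, w = shape
    margin = radius + 2.0
    if 2 * margin >= min(h, w):
        return None
    for _ in range(max_tries):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (radius + r + 3.0) ** 2
               for y, x, r in placed):
            return cy, cx
    return None


def _render_blob(mask: np.ndarray, rng: np.random.Generator, cy: float,
                 cx: float, radius: float) -> int:
    """Rasterise a quasi-circular (slightly elliptical, rotated) blob of the
    given equivalent radius; returns the number of newly set pixels."""
    q = rng.uniform(0.85, 1.0)
    theta = rng.uniform(0, np.pi)
    a, b = radius / np.sqrt(q), radius * np.sqrt(q)
    r_int = int(np.ceil(max(a, b))) + 1
    y0, y1 = int(cy) - r_int, int(cy) + r_int + 1
    x0, x1 = int(cx) - r_int, int(cx) + r_int + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    ys = slice(max(0, y0), min(mask.shape[0], y1))
    xs = slice(max(0, x0), min(mask.shape[1], x1))
    sub = blob[ys.start - y0:ys.stop - y0, xs.start - x0:xs.stop - x0]
    before = int(mask[ys, xs].sum())
    mask[ys, xs] |= sub
    return int(mask[ys, xs].sum()) - before


def _walk_neurite(rng: np.random.Generator, mask: np.ndarray,
                  soma_mask: np.ndarray, start: tuple[int, int],
                  theta: float, length_um: float, params: CultureParams,
                  pixel_size_um: float, segments: list[float],
                  depth: int = 0, max_depth: int = 3) -> None:
    """Grow one neurite path, recording arc lengths of the segments between
    fork points (diagonal steps count sqrt(2) px).

    Walks terminate when they hit the field border, a soma, or an already
    drawn neurite pixel, so the recorded arc length matches the rendered
    geometry exactly (crossings never double-count).
    """
    h, w = mask.shape
    y, x = start
    arc_px = 0.0
    length_px = length_um / pixel_size_um
    jitter = 0.08
    grace = 2  # steps after a spawn during which collisions are ignored
    step = 0
    while arc_px < length_px:
        theta += rng.normal(0.0, jitter)
        dy, dx = int(np.round(np.sin(theta))), int(np.round(np.cos(theta)))
        if dy == 0 and dx == 0:
            dx = 1
        y += dy
        x += dx
        step += 1
        if not (1 <= y < h - 1 and 1 <= x < w - 1):
            break
        if step > grace and (mask[y, x] or soma_mask[y, x]):
            break
        if not mask[y, x]:  # revisits inside the grace window add no arc
            mask[y, x] = True
            arc_px += SQRT2 if (dy != 0 and dx != 0) else 1.0
        if depth < max_depth and rng.random() < params.branch_prob:
            # fork: close the current segment, spawn a child, continue anew
            segments.append(arc_px * pixel_size_um)
            child_len = rng.gamma(params.length_shape, params.length_scale)
            side = 1.0 if rng.random() < 0.5 else -1.0
            _walk_neurite(rng, mask, soma_mask, (y, x), theta + side * 0.9,
                          child_len, params, pixel_size_um, segments,
                          depth + 1, max_depth)
            length_px -= arc_px
            arc_px = 0.0
            step = 0
    if arc_px > 0:
        segments.append(arc_px * pixel_size_um)


def generate_culture_field(
    params: CultureParams,
    seed: int | np.random.Generator,
    field_shape: tuple[int, int] = DEFAULT_FIELD_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    well_id: str = "A01",
    site_index: int = 1,
) -> tuple[FieldImage, FieldImage, FieldTruth]:
    """Render one two-channel field and its ground truth.

    Identical (params, seed) always yields bit-identical images.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    h, w = field_shape
    truth = FieldTruth()
    soma_mask = np.zeros((h, w), dtype=bool)
    neurite_mask = np.zeros((h, w), dtype=bool)
    pa = pixel_size_um ** 2

    weights = np.array([c[0] for c in params.area_mixture])
    means = np.array([c[1] for c in params.area_mixture])
    sds = np.array([c[2] for c in params.area_mixture])

    n_blobs = rng.poisson(params.neuromere_rate)
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_blobs):
        comp = int(rng.choice(len(weights), p=weights / weights.sum()))
        log2_area = rng.normal(means[comp], sds[comp])
        area_px = 2.0 ** log2_area / pa
        radius = float(np.sqrt(area_px / np.pi))
        pos = _place_blob(rng, (h, w), radius, placed)
        if pos is None:
            logger.warning("field too crowded: skipped a neuromere of "
                           "radius %.1f px", radius)
            continue
        cy, cx = pos
        npx = _render_blob(soma_mask, rng, cy, cx, radius)
        placed.append((cy, cx, radius))
        truth.neuromere_areas_um2.append(npx * pa)
        truth.log2_areas_drawn.append(float(log2_area))
        truth.mixture_components.append(comp)
        # neurites emanate from just outside the blob boundary; emanation
        # angles are stratified around the circle so that processes from
        # one neuromere rarely merge near their roots
        n_neur = rng.poisson(params.neurites_per_neuromere)
        phase = rng.uniform(0, 2 * np.pi)
        for i_neur in range(n_neur):
            theta = phase + 2 * np.pi * (i_neur + rng.uniform(0, 0.6)) \
                / max(n_neur, 1)
            rr = radius + 1.0
            while rr < radius + 6.0:
                sy = int(round(cy + rr * np.sin(theta)))
                sx = int(round(cx + rr * np.cos(theta)))
                if not (0 <= sy < h and 0 <= sx < w):
                    break
                if not soma_mask[sy, sx]:
                    length = rng.gamma(params.length_shape,
                                       params.length_scale)
                    _walk_neurite(rng, neurite_mask, soma_mask, (sy, sx),
                                  theta, length, params, pixel_size_um,
                                  truth.segment_lengths_um)
                    break
                rr += 1.0
    truth.neuromere_count = len(truth.neuromere_areas_um2)

    # widen neurites to ~2 px so they survive the point spread function
    # (a 2x2 dilation keeps diagonal runs skeletonisable at full length)
    neurite_mask = ndimage.binary_dilation(neurite_mask,
                                           np.ones((2, 2), dtype=bool))
    neurite_mask &= ~soma_mask
    neuronal_mask = soma_mask | neurite_mask

    morph = np.full((h, w), BACKGROUND_LEVEL)
    morph[neurite_mask] = NEURITE_INTENSITY
    morph[soma_mask] = SOMA_INTENSITY

    reporter = np.full((h, w), BACKGROUND_LEVEL)
    reporter[neuronal_mask] += params.soluble_reporter_level
    agg_mask = np.zeros((h, w), dtype=bool)
    n_agg = rng.poisson(params.aggregate_rate)
    if n_agg:
        candidates = np.flatnonzero(neuronal_mask)
        for _ in range(n_agg):
            if candidates.size:
                idx = int(rng.choice(candidates))
                cy, cx = divmod(idx, w)
            else:
                cy, cx = rng.integers(2, h - 2), rng.integers(2, w - 2)
            r = params.aggregate_radius_px
            yy, xx = np.mgrid[max(0, cy - r):min(h, cy + r + 1),
                              max(0, cx - r):min(w, cx + r + 1)]
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            intensity = rng.uniform(params.aggregate_intensity,
                                    1.5 * params.aggregate_intensity)
            patch = reporter[yy.min():yy.max() + 1, xx.min():xx.max() + 1]
            patch[disc] = np.maximum(patch[disc], intensity)
            agg_mask[yy.min():yy.max() + 1, xx.min():xx.max() + 1] |= disc
    truth.aggregate_pixel_count = int(agg_mask.sum())

    def finish(channel_img: np.ndarray) -> np.ndarray:
        out = channel_img
        if params.psf_sigma_px > 0:
            out = ndimage.gaussian_filter(out, params.psf_sigma_px)
        if params.noise_sd > 0:
            out = out + rng.normal(0.0, params.noise_sd, out.shape)
        return np.clip(np.round(out), 0, BIT_MAX).astype(np.uint16)

    morph_img = FieldImage(well_id=well_id, site_index=site_index,
                           channel=Channel.MORPHOLOGY, pixels=finish(morph),
                           pixel_size_um=pixel_size_um)
    rep_img = FieldImage(well_id=well_id, site_index=site_index,
                         channel=Channel.REPORTER, pixels=finish(reporter),
                         pixel_size_um=pixel_size_um)
    return morph_img, rep_img, truth


# ---------------------------------------------------------------------------
# whole screens
# ---------------------------------------------------------------------------

def _well_name(index: int, n_cols: int = 12) -> str:
    return f"{chr(ord('A') + index // n_cols)}{index % n_cols + 1:02d}"


def build_screen_layout(
    treatment_ids: list[str],
    wells_per_treatment: int = 2,
    vehicle_wells_per_genotype: int = 4,
    plate_id: str = "SYN1",
    treatment_kind: TreatmentKind = TreatmentKind.COMPOUND,
) -> PlateLayout:
    """Standard synthetic plate: mock-treated Htt15Q control wells, DMSO
    Htt138Q vehicle wells, and duplicate compound wells on the Htt138Q
    background (the screen's design)."""
    layout = PlateLayout(plate_id=plate_id)
    idx = 0
    for _ in range(vehicle_wells_per_genotype):
        layout.wells[_well_name(idx)] = WellCondition(
            Genotype.HTT15Q, "MOCK_15Q", TreatmentKind.MOCK,
            replicate_group="vehicle15Q")
        idx += 1
    for _ in range(vehicle_wells_per_genotype):
        layout.wells[_well_name(idx)] = WellCondition(
            Genotype.HTT138Q, "DMSO_138Q", TreatmentKind.VEHICLE,
            replicate_group="vehicle138Q")
        idx += 1
    for tid in treatment_ids:
        for rep in range(wells_per_treatment):
            layout.wells[_well_name(idx)] = WellCondition(
                Genotype.HTT138Q, tid, treatment_kind,
                replicate_group=f"{tid}_r{rep + 1}")
            idx += 1
    return layout


def params_for_condition(cond: WellCondition, effect: EffectSpec | None,
                         base_control: CultureParams,
                         base_mutant: CultureParams) -> CultureParams:
    """Map a well's condition and true effect to generator parameters."""
    if cond.genotype is Genotype.HTT15Q:
        return base_control
    if cond.is_vehicle or effect is None or effect.label is EffectLabel.NULL:
        return base_mutant
    if effect.label is EffectLabel.AGG_SUPPRESSOR:
        return dataclasses.replace(
            base_mutant,
            aggregate_rate=base_mutant.aggregate_rate * effect.suppression_factor)
    if effect.label is EffectLabel.DUAL_RESCUER:
        return interpolate_params(base_mutant, base_control, effect.rescue)
    if effect.label is EffectLabel.TOXIC:
        mixture = tuple((wgt, mu - 0.5, sd)
                        for wgt, mu, sd in base_mutant.area_mixture)
        return dataclasses.replace(base_mutant, area_mixture=mixture,
                                   length_scale=base_mutant.length_scale * 0.6)
    raise ValidationError(f"unknown effect label {effect.label}")


@dataclass
class ScreenData:
    """In-memory synthetic screen: per-field images plus truth."""

    layout: PlateLayout
    truth: ScreenTruth
    fields: list[tuple[str, int, FieldImage, FieldImage]]  # well, site, morph, rep


def generate_screen(
    layout: PlateLayout,
    effects: dict[str, EffectSpec],
    seed: int,
    fields_per_well: int = 3,
    field_shape: tuple[int, int] = DEFAULT_FIELD_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    base_control: CultureParams | None = None,
    base_mutant: CultureParams | None = None,
    out_dir: str | Path | None = None,
) -> ScreenData:
    """Generate every field of a synthetic screen.

    ``effects`` maps treatment ids to their true effect; treatments absent
    from the map are NULL. When ``out_dir`` is given, TIFFs, the layout CSV
    and a truth JSON are also written there.
    """
    base_control = base_control or control_params()
    base_mutant = base_mutant or mutant_params()
    unknown = set(effects) - set(t for t in layout.treatments())
    if unknown:
        raise ValidationError(f"effect map names absent treatments: "
                              f"{sorted(unknown)}")
    for genotype in (Genotype.HTT15Q, Genotype.HTT138Q):
        if len(layout.vehicle_wells(genotype)) < 2:
            raise ValidationError(
                f"need >= 2 vehicle wells for {genotype.value}")

    truth = ScreenTruth()
    for tid in layout.treatments():
        truth.effects[tid] = effects.get(tid, EffectSpec(EffectLabel.NULL))

    data = ScreenData(layout=layout, truth=truth, fields=[])
    for well_id, cond in layout.wells.items():
        effect = truth.effects.get(cond.treatment_id)
        params = params_for_condition(cond, effect, base_control, base_mutant)
        for site in range(1, fields_per_well + 1):
            rng = field_rng(seed, layout.plate_id, well_id, site)
            morph, rep, ftruth = generate_culture_field(
                params, rng, field_shape, pixel_size_um, well_id, site)
            truth.fields[(well_id, site)] = ftruth
            data.fields.append((well_id, site, morph, rep))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_plate_layout(layout, out_dir / "layout.csv")
        for well_id, site, morph, rep in data.fields:
            for img in (morph, rep):
                write_field_image(img, out_dir / image_filename(
                    layout.plate_id, well_id, site, img.channel))
        _write_truth_json(truth, out_dir / "truth.json")
    return data


def _write_truth_json(truth: ScreenTruth, path: Path) -> None:
    payload = {
        "effects": {t: {"label": e.label.value,
                        "suppression_factor": e.suppression_factor,
                        "rescue": e.rescue}
                    for t, e in truth.effects.items()},
        "fields": {f"{well}:{site}": {
            "neuromere_count": ft.neuromere_count,
            "neuromere_areas_um2": ft.neuromere_areas_um2,
            "log2_areas_drawn": ft.log2_areas_drawn,
            "segment_lengths_um": ft.segment_lengths_um,
            "aggregate_pixel_count": ft.aggregate_pixel_count,
        } for (well, site), ft in truth.fields.items()},
    }
    path.write_text(json.dumps(payload, indent=1))
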