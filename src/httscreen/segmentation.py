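"""Segmentation of neuronal cultures from two-channel field images.

The morphology channel (membrane GFP) is decomposed into neuromeres
(clusters of neuronal cell bodies, segmented as thick bright regions) and
neurites (thin processes, measured as skeleton segment lengths between
branch points). The reporter channel (Htt-RFP) is reduced to a single
per-field aggregation measure: the number of pixels brighter than an
empirically calibrated intensity threshold.

Pipeline for the morphology channel:

1. background subtraction with a wide median filter (computed on a
   decimated grid for speed, then interpolated back);
2. binarisation (Otsu by default, fixed threshold optional);
3. morphological opening with a disc separates thick somata from thin
   neurites; opened components above a minimum area are neuromeres;
4. the neurite mask is the binary mask minus the (dilated) neuromeres;
   it is skeletonised and the skeleton is split at junction pixels
   (>= 3 neighbours) into segments whose length counts diagonal steps
   as sqrt(2) x pixel size.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, opening, skeletonize
from skimage.transform import resize

from .errors import ConfigurationError, ValidationError
from .plate_io import Channel, FieldImage

SQRT2 = float(np.sqrt(2.0))


class ThresholdMethod(str, enum.Enum):
    OTSU = "OTSU"
    FIXED = "FIXED"


@dataclass
class SegmentationConfig:
    """Tunables of the morphology/reporter segmentation.

    ``aggregate_threshold`` is the empirically set reporter intensity above
    which a pixel counts as aggregate; it is normally set per screen by
    :func:`calibrate_aggregate_threshold` on aggregate-free control wells.
    """

    morph_threshold_method: ThresholdMethod = ThresholdMethod.OTSU
    fixed_threshold: float = 0.0
    background_window_px: int = 101
    soma_opening_radius_px: int = 4
    min_neuromere_area_px: int = 50
    min_segment_length_px: int = 5
    neuromere_exclusion_radius_px: int = 1
    aggregate_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.soma_opening_radius_px < 1 or self.min_neuromere_area_px < 1 \
                or self.min_segment_length_px < 1:
            raise ValidationError("radii and minima must be >= 1")


@dataclass
class SegmentationResult:
    """Per-field segmentation output.

    Areas are in µm² (pixel count x pixel_size²), lengths in µm, both
    sorted descending. ``aggregate_pixel_count`` is filled by
    :func:`count_aggregate_pixels` on the matching reporter field.
    """

    neuromere_areas_um2: list[float] = field(default_factory=list)
    neurite_segment_lengths_um: list[float] = field(default_factory=list)
    aggregate_pixel_count: int = 0
    neuromere_pixel_mask_size: int = 0
    neurite_pixel_mask_size: int = 0
    neuromere_mask: np.ndarray | None = field(default=None, repr=False,
                                              compare=False)
    neurite_mask: np.ndarray | None = field(default=None, repr=False,
                                            compare=False)

    @property
    def neuromere_count(self) -> int:
        return len(self.neuromere_areas_um2)

    @property
    def neurite_count(self) -> int:
        return len(self.neurite_segment_lengths_um)


def estimate_background(pixels: np.ndarray, window_px: int,
                        decimate: int = 4) -> np.ndarray:
    """Median-filter background estimate.

    The median is taken over a ``window_px`` square; for speed it is
    computed on a ``decimate``-fold subsampled grid and interpolated back,
    which is accurate for backgrounds varying on scales >> window.
    """
    small = pixels[::decimate, ::decimate].astype(np.float64)
    size = max(3, window_px // decimate)
    med = ndimage.median_filter(small, size=size, mode="nearest")
    return resize(med, pixels.shape, order=1, preserve_range=True,
                  anti_aliasing=False)


def _binary_mask(image: FieldImage, config: SegmentationConfig) -> np.ndarray:
    px = image.pixels.astype(np.float64)
    bg = estimate_background(px, config.background_window_px)
    sub = np.clip(px - bg, 0.0, None)
    if config.morph_threshold_method is ThresholdMethod.FIXED:
        thr = config.fixed_threshold
    else:
        if np.ptp(sub) == 0:
            return np.zeros_like(sub, dtype=bool)
        thr = threshold_otsu(sub)
    return sub > thr


def _skeleton_segments(skel: np.ndarray, pixel_size_um: float,
                       min_length_px: int) -> list[float]:
    """Split a skeleton at junction pixels and measure each segment's
    path length (orthogonal steps 1, diagonal steps sqrt(2), in pixels)."""
    if not skel.any():
        return []
    # 8-neighbour count per skeleton pixel
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    nnb = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
    junctions = skel & (nnb >= 3)
    segments = skel & ~junctions
    labels, n = ndimage.label(segments, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    # accumulate adjacency edge lengths per segment; edges touching a
    # junction pixel are credited to the adjacent segment so that the
    # split does not shorten the measured paths
    jmark = junctions.astype(np.int8)
    lengths_px = np.zeros(n + 1)
    shifts = [((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), SQRT2), ((1, -1), SQRT2)]
    for (dr, dc), wgt in shifts:
        sl_a = (slice(max(0, -dr), labels.shape[0] - max(0, dr)),
                slice(max(0, -dc), labels.shape[1] - max(0, dc)))
        sl_b = (slice(max(0, dr), labels.shape[0] + min(0, dr) or None),
                slice(max(0, dc), labels.shape[1] + min(0, dc) or None))
        a, b = labels[sl_a], labels[sl_b]
        ja, jb = jmark[sl_a], jmark[sl_b]
        same = (a > 0) & (a == b)
        np.add.at(lengths_px, a[same], wgt)
        seg_junc = (a > 0) & (jb > 0)
        np.add.at(lengths_px, a[seg_junc], wgt)
        junc_seg = (b > 0) & (ja > 0)
        np.add.at(lengths_px, b[junc_seg], wgt)
    lengths_px = lengths_px[1:]
    lengths_px = lengths_px[lengths_px >= min_length_px]
    return sorted((lengths_px * pixel_size_um).tolist(), reverse=True)


def segment_morphology(image: FieldImage, config: SegmentationConfig,
                       keep_masks: bool = False) -> SegmentationResult:
    """Extract neuromere areas and neurite segment lengths from a
    morphology-channel field. Blank fields yield empty lists. With
    ``keep_masks`` the binary neuromere/neurite masks are attached to the
    result (diagnostics; they are always disjoint)."""
    if image.channel is not Channel.MORPHOLOGY:
        raise ValidationError("segment_morphology expects the MORPHOLOGY channel")
    mask = _binary_mask(image, config)
    result = SegmentationResult()
    if not mask.any():
        return result

    opened = opening(mask, disk(config.soma_opening_radius_px))
    labels, n = ndimage.label(opened)
    neuromere_mask = np.zeros_like(mask)
    areas_px: list[int] = []
    if n:
        counts = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(counts >= config.min_neuromere_area_px) + 1
        if keep.size:
            neuromere_mask = np.isin(labels, keep)
            # the opening erodes soma boundaries; measure areas from the
            # original mask pixels claimed by each kept component
            claim = ndimage.grey_dilation(
                labels, footprint=disk(config.soma_opening_radius_px))
            claimed = np.where(mask, claim, 0)
            claimed_counts = np.bincount(claimed.ravel(), minlength=n + 1)
            areas_px = sorted(claimed_counts[keep].tolist(), reverse=True)

    pa = image.pixel_area_um2
    result.neuromere_areas_um2 = [a * pa for a in areas_px]
    result.neuromere_pixel_mask_size = int(neuromere_mask.sum())

    excl = dilation(neuromere_mask,
                    disk(config.neuromere_exclusion_radius_px))
    neurite_mask = mask & ~excl
    result.neurite_pixel_mask_size = int(neurite_mask.sum())
    skel = skeletonize(neurite_mask)
    result.neurite_segment_lengths_um = _skeleton_segments(
        skel, image.pixel_size_um, config.min_segment_length_px)
    if keep_masks:
        result.neuromere_mask = neuromere_mask
        result.neurite_mask = neurite_mask
    return result


def count_aggregate_pixels(image: FieldImage,
                           config: SegmentationConfig) -> int:
    """Number of reporter pixels strictly brighter than the aggregate
    threshold. Pixels saturated at the bit-depth maximum always count."""
    if config.aggregate_threshold is None:
        raise ConfigurationError(
            "aggregate_threshold is unset; run calibrate_aggregate_threshold "
            "or set it explicitly")
    px = image.pixels
    above = (px > config.aggregate_threshold) | (px >= image.bit_max)
    return int(np.count_nonzero(above))


def calibrate_aggregate_threshold(reference_images: list[FieldImage],
                                  q: float = 0.999) -> float:
    """Empirical aggregate threshold: the ``q``-quantile of pooled pixel
    intensities of aggregate-free reference fields (Htt15Q vehicle wells).

    By construction, applying the threshold back to the reference
    population yields near-zero aggregate counts.
    """
    if not reference_images:
        raise ConfigurationError("need at least one reference image")
    if not 0.0 < q < 1.0:
        raise ValidationError("quantile q must lie in (0, 1)")
    pooled = np.concatenate([im.pixels.ravel() for im in reference_images])
    return float(np.quantile(pooled, q))


def neuronal_mask_sizes(seg: SegmentationResult) -> tuple[int, int]:
    """(neuromere pixels, neurite pixels) of a segmented field — the
    denominator of the reporter-distribution ratio."""
    return seg.neuromere_pixel_mask_size, seg.neurite_pixel_mask_size
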