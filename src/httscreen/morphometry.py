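"""Eight-metric morphology profile from segmented fields.

Neuromere areas are log2-transformed and binned small/medium/large by a
three-component univariate Gaussian mixture fitted by EM; neurite segment
lengths are grouped short/medium/long by k-means (k = 3). Bin and group
counts are converted to percentages of each field's totals — controlling
for well-to-well variation in cell number — and combined with the mean
neuromere area and mean neurite length into a fixed-order eight-entry
feature vector:

    pct_small_neuromere, pct_medium_neuromere, pct_large_neuromere,
    mean_neuromere_area, pct_short_neurite, pct_medium_neurite,
    pct_long_neurite, mean_neurite_length

Both models are fitted once per screen on objects pooled from vehicle
wells of both genotypes and then frozen, so that bin boundaries are
comparable across treatments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm
from sklearn.cluster import KMeans

from .errors import DegenerateDataError, UndefinedRatioError, ValidationError
from .segmentation import SegmentationResult

FEATURE_NAMES = (
    "pct_small_neuromere", "pct_medium_neuromere", "pct_large_neuromere",
    "mean_neuromere_area",
    "pct_short_neurite", "pct_medium_neurite", "pct_long_neurite",
    "mean_neurite_length",
)
N_FEATURES = len(FEATURE_NAMES)
N_AREA_BINS = 3
N_LENGTH_GROUPS = 3


@dataclass(frozen=True)
class AreaBinModel:
    """Three-component Gaussian mixture on the log2-area (µm²) scale,
    components sorted by mean (small < medium < large)."""

    weights: tuple[float, float, float]
    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    fitted_n: int
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValidationError("mixture sds must be positive")
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise ValidationError("mixture means must be strictly increasing")

    def posteriors(self, log2_areas: np.ndarray) -> np.ndarray:
        """(n, 3) posterior component probabilities."""
        x = np.asarray(log2_areas, dtype=float)[:, None]
        dens = np.array(self.weights) * norm.pdf(x, self.means, self.sds)
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0  # far-tail values: fall back to equal odds
        dens[(dens.sum(axis=1) == 0)] = 1.0 / 3.0
        return dens / np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)


def _em_gmm_1d(x: np.ndarray, means0: np.ndarray, sds0: np.ndarray,
               weights0: np.ndarray, tol: float = 1e-8,
               max_iter: int = 500) -> tuple[np.ndarray, np.ndarray,
                                             np.ndarray, float, list[float]]:
    """Plain EM for a univariate Gaussian mixture with deterministic
    initialisation; returns (weights, means, sds, loglik, loglik trace)."""
    n = x.size
    w, mu, sd = weights0.copy(), means0.copy(), sds0.copy()
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        dens = w * norm.pdf(x[:, None], mu, sd)
        row = dens.sum(axis=1)
        row = np.maximum(row, 1e-300)
        ll = float(np.log(row).sum())
        trace.append(ll)
        resp = dens / row[:, None]
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, 1e-12))
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return w, mu, sd, trace[-1], trace


def fit_area_bins(log2_areas: np.ndarray | list[float],
                  seed: int | None = None) -> AreaBinModel:
    """Fit the three-bin area mixture by EM.

    Initialisation is deterministic (means at the 1/6, 3/6, 5/6 sample
    quantiles, equal weights, common sample sd), so ``seed`` is accepted
    for interface symmetry but has no effect on the result.
    """
    x = np.sort(np.asarray(log2_areas, dtype=float))
    if np.unique(x).size < 3:
        raise DegenerateDataError(
            "need at least 3 distinct log2 areas to fit three bins")
    means0 = np.quantile(x, [1 / 6, 3 / 6, 5 / 6])
    if np.unique(means0).size < 3:  # heavy ties: spread initial means
        means0 = np.unique(x)[:3].astype(float)
    sd0 = max(float(np.std(x)), 1e-3)
    w, mu, sd, ll, _ = _em_gmm_1d(x, means0, np.full(3, sd0),
                                  np.full(3, 1 / 3))
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    if not (mu[0] < mu[1] < mu[2]):  # collapsed components: nudge apart
        eps = 1e-9 * max(1.0, abs(mu[1]))
        mu = np.array([mu[0] - eps, mu[1], mu[2] + eps])
    return AreaBinModel(weights=tuple(w), means=tuple(mu), sds=tuple(sd),
                        fitted_n=x.size, log_likelihood=ll)


def em_loglik_trace(log2_areas: np.ndarray | list[float]) -> list[float]:
    """Log-likelihood per EM iteration (diagnostic; nondecreasing)."""
    x = np.sort(np.asarray(log2_areas, dtype=float))
    means0 = np.quantile(x, [1 / 6, 3 / 6, 5 / 6])
    sd0 = max(float(np.std(x)), 1e-3)
    return _em_gmm_1d(x, means0, np.full(3, sd0), np.full(3, 1 / 3))[4]


def assign_area_bin(log2_area: float | np.ndarray,
                    model: AreaBinModel) -> np.ndarray:
    """Maximum-posterior bin index (0=small, 1=medium, 2=large); exact
    posterior ties break towards the smaller bin."""
    post = model.posteriors(np.atleast_1d(np.asarray(log2_area, dtype=float)))
    # argmax returns the first (smallest-index) maximum, which is the
    # required tie-break since components are sorted by mean
    return post.argmax(axis=1)


@dataclass(frozen=True)
class LengthGroupModel:
    """k-means (k = 3) centers on neurite segment length (µm), sorted
    ascending (short < medium < long)."""

    centers: tuple[float, float, float]
    fitted_n: int

    def __post_init__(self) -> None:
        if not (0 < self.centers[0] < self.centers[1] < self.centers[2]):
            raise ValidationError("centers must be positive and strictly "
                                  "increasing")

    def assign(self, lengths: np.ndarray | list[float]) -> np.ndarray:
        """Nearest-center group index; midpoint ties go to the shorter
        group (argmin returns the first minimum)."""
        x = np.atleast_1d(np.asarray(lengths, dtype=float))
        return np.abs(x[:, None] - np.array(self.centers)).argmin(axis=1)


def fit_length_groups(lengths: np.ndarray | list[float],
                      seed: int | None = None) -> LengthGroupModel:
    """Group neurite segment lengths into short/medium/long by Lloyd's
    k-means, deterministically initialised at the 10th/50th/90th sample
    percentiles."""
    x = np.sort(np.asarray(lengths, dtype=float))
    if np.unique(x).size < 3:
        raise DegenerateDataError(
            "need at least 3 distinct lengths to fit three groups")
    init = np.quantile(x, [0.10, 0.50, 0.90])
    if np.unique(init).size < 3:
        init = np.unique(x)[:3].astype(float)
    km = KMeans(n_clusters=3, init=init[:, None], n_init=1, tol=1e-6,
                max_iter=300)
    km.fit(x[:, None])
    centers = np.sort(km.cluster_centers_.ravel())
    return LengthGroupModel(centers=tuple(centers), fitted_n=x.size)


@dataclass(frozen=True)
class FeatureVector:
    """The eight-metric morphology profile of one field."""

    pct_small_neuromere: float
    pct_medium_neuromere: float
    pct_large_neuromere: float
    mean_neuromere_area: float
    pct_short_neurite: float
    pct_medium_neurite: float
    pct_long_neurite: float
    mean_neurite_length: float
    zero_neurites: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def compute_features(seg: SegmentationResult, area_model: AreaBinModel,
                     length_model: LengthGroupModel) -> FeatureVector:
    """Eight-entry feature vector for one segmented field.

    Requires at least one neuromere (fields without cells are excluded
    upstream by QC). Fields without any neurite segment get zero-valued
    neurite features and are flagged ``zero_neurites``.
    """
    if seg.neuromere_count == 0:
        raise ValidationError("compute_features requires >= 1 neuromere; "
                              "cell-free fields are excluded by QC")
    areas = np.asarray(seg.neuromere_areas_um2, dtype=float)
    bins = assign_area_bin(np.log2(areas), area_model)
    bin_pct = 100.0 * np.bincount(bins, minlength=3) / areas.size

    lengths = np.asarray(seg.neurite_segment_lengths_um, dtype=float)
    if lengths.size:
        groups = length_model.assign(lengths)
        grp_pct = 100.0 * np.bincount(groups, minlength=3) / lengths.size
        mean_len = float(lengths.mean())
        zero = False
    else:
        grp_pct = np.zeros(3)
        mean_len = 0.0
        zero = True
    return FeatureVector(
        pct_small_neuromere=float(bin_pct[0]),
        pct_medium_neuromere=float(bin_pct[1]),
        pct_large_neuromere=float(bin_pct[2]),
        mean_neuromere_area=float(areas.mean()),
        pct_short_neurite=float(grp_pct[0]),
        pct_medium_neurite=float(grp_pct[1]),
        pct_long_neurite=float(grp_pct[2]),
        mean_neurite_length=mean_len,
        zero_neurites=zero,
    )


def reporter_distribution_ratio(reporter_positive_pixels: int,
                                neuromere_pixels: int,
                                neurite_pixels: int) -> float:
    """Soluble-reporter distribution measure: reporter-positive pixels per
    neuronal-mask pixel (neuromere + neurite GFP pixels)."""
    denom = neuromere_pixels + neurite_pixels
    if denom <= 0:
        raise UndefinedRatioError("zero neuronal area: ratio undefined")
    if reporter_positive_pixels < 0:
        raise ValidationError("reporter-positive pixel count must be >= 0")
    return reporter_positive_pixels / denom


# ---------------------------------------------------------------------------
# model (de)serialisation
# ---------------------------------------------------------------------------

def save_models(area_model: AreaBinModel, length_model: LengthGroupModel,
                path: str | Path, provenance: dict | None = None) -> Path:
    payload = {
        "area_bins": {"weights": list(area_model.weights),
                      "means": list(area_model.means),
                      "sds": list(area_model.sds),
                      "fitted_n": area_model.fitted_n},
        "length_groups": {"centers": list(length_model.centers),
                          "fitted_n": length_model.fitted_n},
        "provenance": provenance or {},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_models(path: str | Path) -> tuple[AreaBinModel, LengthGroupModel]:
    payload = json.loads(Path(path).read_text())
    ab = payload["area_bins"]
    lg = payload["length_groups"]
    return (AreaBinModel(weights=tuple(ab["weights"]), means=tuple(ab["means"]),
                         sds=tuple(ab["sds"]), fitted_n=ab["fitted_n"]),
            LengthGroupModel(centers=tuple(lg["centers"]),
                             fitted_n=lg["fitted_n"]))
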