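"""Image quantification: projections, noise thresholds, marker metrics,
THP-1 counting and migration distances.

Implements the study's analysis procedure for 8-bit immunofluorescence
z-stacks of an engineered vessel:

- z-projection (maximum for nucleus/marker channels; average offered for
  bleed-prone actin);
- noise floor from secondary-antibody-only "dummy" controls: the smallest
  gray level ``T`` such that at most the top 1% of pooled dummy pixels are
  >= T; pixels >= T count as signal (the published "0-9 excluded" /
  "0-14 excluded" rules correspond to dummy 99th percentiles of 9 and 14);
- ICAM-1 positive-area ratio and normalized mean intensity, VE-cadherin
  junction-area ratio;
- tracker-channel THP-1 detection by connected components, classification
  against the endothelial wall line, and closest-pixel migration distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology
from scipy import ndimage

from .imaging import ImageStack

logger = logging.getLogger(__name__)


class QuantifyError(ValueError):
    """Invalid quantification input."""


METRICS = ("icam1_area_ratio_pct", "icam1_norm_intensity",
           "vecad_area_ratio_pct", "n_adhered", "n_transmigrated",
           "migration_distance_um")


@dataclass(frozen=True)
class Threshold:
    """Integer noise threshold: intensities >= value are signal."""

    value: int
    top_fraction: float = 0.01
    dummy_set: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 256:
            raise QuantifyError("threshold must be an 8-bit gray level")


@dataclass
class QuantRecord:
    """One scalar measurement for one image."""

    image_id: str
    condition: str
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise QuantifyError(f"unknown metric {self.metric!r}")


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project(stack: ImageStack, channel: str, mode: str = "max") -> np.ndarray:
    """Project one channel of a z-stack to a 2D uint8 image.

    ``mode="max"`` takes the per-pixel maximum across z; ``mode="average"``
    the per-pixel mean rounded half-up. A single-slice stack projects to
    itself (logged as a warning).
    """
    if mode not in ("max", "average"):
        raise QuantifyError(f"unknown projection mode {mode!r}")
    sub = stack.channel(channel)
    if sub.shape[0] == 1:
        logger.warning("projecting a single-slice stack is the identity")
        return sub[0].copy()
    if mode == "max":
        return sub.max(axis=0)
    return np.floor(sub.mean(axis=0, dtype=np.float64) + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# noise threshold (top-1% dummy rule)
# ---------------------------------------------------------------------------

def noise_threshold(dummy_images: list, top_fraction: float = 0.01,
                    dummy_set: str = "") -> Threshold:
    """Noise floor from pooled dummy (secondary-antibody-only) images.

    Returns the smallest integer gray level T such that the fraction of
    pooled dummy pixels with intensity >= T is at most ``top_fraction``.
    With a dummy 99th percentile of 9 this yields T = 10 (gray levels 0-9
    treated as noise); an all-zero dummy yields T = 1 (every nonzero pixel
    is signal).
    """
    if not dummy_images:
        raise QuantifyError("need at least one dummy image")
    if not 0 < top_fraction < 1:
        raise QuantifyError("top_fraction must be in (0, 1)")
    counts = np.zeros(256, dtype=np.int64)
    total = 0
    for img in dummy_images:
        img = np.asarray(img)
        if img.dtype != np.uint8:
            raise QuantifyError("dummy images must be uint8")
        counts += np.bincount(img.ravel(), minlength=256)
        total += img.size
    # fraction of pixels >= T for T = 0..256
    tail = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]]) / total
    t = int(np.argmax(tail <= top_fraction))
    return Threshold(value=t, top_fraction=top_fraction, dummy_set=dummy_set)


# ---------------------------------------------------------------------------
# endothelial cell-area mask
# ---------------------------------------------------------------------------

def cell_area_mask(nucleus: np.ndarray, actin: np.ndarray,
                   min_object_px: int = 64,
                   noise_floor: int = 10) -> np.ndarray:
    """Endothelial cell-area mask from projected nucleus and actin images.

    Otsu-thresholds the actin image, unions a dilated Otsu nucleus mask,
    closes small gaps, removes specks and fills enclosed holes. When a
    confluent monolayer leaves Otsu no real background class to separate
    (the "background" side of the split still looks signal-like), the actin
    threshold falls back to ``noise_floor`` — the same dummy-derived gray
    level used for marker signal. Degenerate inputs (blank or saturated)
    map to the empty or full mask.
    """
    nucleus = np.asarray(nucleus)
    actin = np.asarray(actin)
    if nucleus.shape != actin.shape:
        raise QuantifyError("nucleus and actin images must be co-registered")

    def segment(img: np.ndarray) -> np.ndarray:
        lo, hi = int(img.min()), int(img.max())
        if hi == lo:
            return np.full(img.shape, hi > 0, dtype=bool)
        if hi - lo < 10:  # essentially flat: background-only or saturated
            return np.full(img.shape, lo > 30, dtype=bool)
        m = img >= filters.threshold_otsu(img)
        bg, fg = img[~m], img[m]
        if bg.size and bg.mean() > 0.25 * fg.mean():
            m = img >= noise_floor
        return m

    mask = segment(actin)
    mask |= morphology.dilation(segment(nucleus), morphology.disk(2))
    mask = morphology.closing(mask, morphology.disk(2))
    mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        logger.warning("empty cell-area mask; downstream metrics undefined")
    return mask


# ---------------------------------------------------------------------------
# marker metrics
# ---------------------------------------------------------------------------

def icam1_area_ratio(marker: np.ndarray, cell_mask: np.ndarray,
                     threshold: Threshold) -> float:
    """ICAM-1 positive area as a percentage of the endothelial cell area.

    100 * |{pixels in cell mask with intensity >= T}| / |cell mask|;
    NaN when the cell mask is empty.
    """
    marker = np.asarray(marker)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n_cell = int(cell_mask.sum())
    if n_cell == 0:
        return float("nan")
    n_pos = int((marker[cell_mask] >= threshold.value).sum())
    return 100.0 * n_pos / n_cell


def mean_signal_intensity(marker: np.ndarray, threshold: Threshold) -> float:
    """Mean intensity over signal pixels (>= T); NaN if none qualify."""
    marker = np.asarray(marker)
    sig = marker[marker >= threshold.value]
    if sig.size == 0:
        return float("nan")
    return float(sig.mean(dtype=np.float64))


def icam1_norm_intensity(marker_images_by_condition: dict,
                         threshold: Threshold,
                         normal_condition: str = "normal") -> dict:
    """Per-image mean signal intensity normalized to the normal condition.

    Each image's mean over pixels >= T is divided by the mean of those
    per-image means across the designated normal group, so the normal
    group's normalized values average exactly 1.
    """
    if normal_condition not in marker_images_by_condition:
        raise QuantifyError(f"no normal condition {normal_condition!r} present")
    means = {cond: [mean_signal_intensity(img, threshold) for img in imgs]
             for cond, imgs in marker_images_by_condition.items()}
    normal = [m for m in means[normal_condition] if np.isfinite(m)]
    if not normal:
        raise QuantifyError("normal condition has no qualifying pixels")
    ref = float(np.mean(normal))
    return {cond: [m / ref for m in ms] for cond, ms in means.items()}


def vecad_area_ratio(marker: np.ndarray, cell_mask: np.ndarray,
                     threshold: Threshold, denominator: str = "union") -> float:
    """VE-cadherin area as a percentage of the total endothelial area.

    VE+ pixels are those >= T. The denominator is the union
    ``|cell mask ∪ VE+|`` by default (bounded by 100%); a strict
    ``"sum"`` mode (``|cell mask| + |VE+|``) is available for sensitivity
    analysis. NaN when the denominator is empty.
    """
    if denominator not in ("union", "sum"):
        raise QuantifyError(f"unknown denominator mode {denominator!r}")
    marker = np.asarray(marker)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    pos = marker >= threshold.value
    n_pos = int(pos.sum())
    if denominator == "union":
        denom = int((cell_mask | pos).sum())
    else:
        denom = int(cell_mask.sum()) + n_pos
    if denom == 0:
        return float("nan")
    return 100.0 * n_pos / denom


# ---------------------------------------------------------------------------
# THP-1 detection, classification, migration distance
# ---------------------------------------------------------------------------

def detect_thp1(tracker: np.ndarray, threshold: Threshold,
                min_area_px: int = 20) -> list:
    """Connected components (8-connectivity) of the thresholded tracker
    channel with area >= ``min_area_px``; returns one boolean mask per cell.

    A one-pixel binary opening suppresses speckle: isolated supra-threshold
    noise pixels would otherwise attach to a cell's silhouette and shift
    its closest-pixel distance. Cell-sized blobs are unaffected.
    """
    if min_area_px <= 0:
        raise QuantifyError("min_area_px must be positive")
    tracker = np.asarray(tracker)
    binary = tracker >= threshold.value
    binary = morphology.opening(binary, morphology.disk(1))
    labels = measure.label(binary, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if region.area >= min_area_px:
            out.append(labels == region.label)
    return out


def classify_and_measure(cells: list, wall_x_px: float,
                         pixel_size_um: float) -> list:
    """Classify each detected THP-1 cell and measure its migration distance.

    The endothelial wall is the vertical line ``x = wall_x_px`` (0-based
    pixel coordinates); the gel side is ``x > wall_x_px``. A cell with any
    pixel strictly on the gel side is ``"transmigrated"`` with distance
    ``pixel_size * min(x - wall)`` over its gel-side pixels; all other
    cells are ``"adhered"`` with distance 0.
    """
    if pixel_size_um <= 0:
        raise QuantifyError("pixel_size_um must be positive")
    results = []
    for mask in cells:
        xs = np.nonzero(np.asarray(mask, dtype=bool))[1]
        gel = xs[xs > wall_x_px]
        if gel.size:
            dist = float((gel.min() - wall_x_px) * pixel_size_um)
            results.append(("transmigrated", dist))
        else:
            results.append(("adhered", 0.0))
    return results


# ---------------------------------------------------------------------------
# per-stack drivers
# ---------------------------------------------------------------------------

def quantify_marker_stack(stack: ImageStack, threshold: Threshold,
                          metric: str = "icam1",
                          image_id: str = "") -> list:
    """Project a stack and compute its area-ratio record(s)."""
    if metric not in ("icam1", "vecad"):
        raise QuantifyError(f"unknown marker metric {metric!r}")
    nucleus = project(stack, "nucleus", "max")
    actin = project(stack, "actin", "average")  # bleed-prone channel
    marker = project(stack, "marker", "max")
    mask = cell_area_mask(nucleus, actin, noise_floor=threshold.value)
    condition = stack.metadata.get("condition", "unknown")
    records = []
    if metric == "icam1":
        records.append(QuantRecord(image_id, condition, "icam1_area_ratio_pct",
                                   icam1_area_ratio(marker, mask, threshold)))
    else:
        records.append(QuantRecord(image_id, condition, "vecad_area_ratio_pct",
                                   vecad_area_ratio(marker, mask, threshold)))
    return records


def quantify_thp1_stack(stack: ImageStack, threshold: Threshold,
                        wall_x_px: float, min_area_px: int = 20,
                        image_id: str = "") -> list:
    """Detect, classify and measure THP-1 cells in one scene."""
    tracker = project(stack, "tracker", "max")
    cells = detect_thp1(tracker, threshold, min_area_px=min_area_px)
    classified = classify_and_measure(cells, wall_x_px, stack.pixel_size_um)
    condition = stack.metadata.get("condition", "unknown")
    n_adh = sum(1 for k, _ in classified if k == "adhered")
    n_mig = sum(1 for k, _ in classified if k == "transmigrated")
    records = [
        QuantRecord(image_id, condition, "n_adhered", float(n_adh)),
        QuantRecord(image_id, condition, "n_transmigrated", float(n_mig)),
    ]
    for k, d in classified:
        if k == "transmigrated":
            records.append(QuantRecord(image_id, condition,
                                       "migration_distance_um", d))
    return records


def records_to_frame(records: list) -> pd.DataFrame:
    """Tidy DataFrame, one row per QuantRecord."""
    return pd.DataFrame([{"image_id": r.image_id, "condition": r.condition,
                          "metric": r.metric, "value": r.value}
                         for r in records])
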