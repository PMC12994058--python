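"""c-Fos+ nuclei counting and regional activation scores.

The counting workflow mirrors a standard two-channel immunofluorescence
pipeline: each channel (nuclear stain, c-Fos) is smoothed, thresholded and
split into nuclei by seeded watershed on local maxima; the nuclear and
c-Fos masks are then combined (logical AND at the object level) so that
only c-Fos-positive *nuclei* are counted.  Counts are assigned to regions
of interest by object centroid and converted to densities per mm^2; the
per-animal regional value is the median over up to three adjacent slices.

Regional activation is scored 0-3 against the control (No-FS) density
distribution of the same region, and related regions are summed into 0-6
combined scores: BLA = BA + LA, CeA = CeL + CeM, and the dorsal/ventral
periaqueductal gray combine their anterior and posterior levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .scoring import Direction, Rule, VariableSpec, assign_score, build_thresholds

__all__ = [
    "SpotDetectionParams",
    "COMBINED_REGIONS",
    "detect_nuclei",
    "combine_masks",
    "count_in_roi",
    "region_median",
    "activation_scores",
]


@dataclass
class SpotDetectionParams:
    """Parameters of the nucleus detector.

    ``intensity_threshold`` is either an absolute intensity or, when
    ``threshold_mode="quantile"``, a quantile of the smoothed image (the
    default, since absolute intensities are acquisition-dependent).
    """

    smoothing_sigma: float = 2.0
    maxima_min_distance: int = 5
    intensity_threshold: float = 0.95
    threshold_mode: str = "quantile"  # "quantile" | "absolute"
    min_object_area: int = 16  # px^2

    def __post_init__(self):
        if self.smoothing_sigma < 0 or self.maxima_min_distance < 0 or self.min_object_area < 0:
            raise ValueError("detection parameters must be non-negative")
        if self.threshold_mode not in ("quantile", "absolute"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_mode == "quantile" and not 0.0 <= self.intensity_threshold <= 1.0:
            raise ValueError("quantile threshold must be in [0, 1]")


def detect_nuclei(channel: np.ndarray, params: SpotDetectionParams | None = None) -> np.ndarray:
    """Segment nuclei in a single-channel 2-D image.

    Pipeline: Gaussian smoothing -> intensity threshold -> local maxima as
    watershed seeds -> watershed over the binary mask -> drop objects below
    the minimum area.  Returns an int label image (0 = background).
    """
    params = params or SpotDetectionParams()
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_nuclei expects a single-channel 2-D image")
    if img.size == 0 or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    smoothed = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    if params.threshold_mode == "quantile":
        thr = float(np.quantile(smoothed, params.intensity_threshold))
    else:
        thr = float(params.intensity_threshold)
    binary = smoothed > thr
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    peaks = peak_local_max(
        smoothed,
        min_distance=params.maxima_min_distance,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smoothed, markers=markers, mask=binary)
    # area filter, then relabel contiguously
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < params.min_object_area)
    labels[np.isin(labels, small[small > 0])] = 0
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def combine_masks(
    nuclear_labels: np.ndarray,
    cfos_mask: np.ndarray,
    overlap_fraction: float = 0.0,
) -> np.ndarray:
    """Keep nuclear objects whose footprint overlaps the c-Fos mask.

    ``cfos_mask`` may be binary or labelled (any non-zero pixel counts).
    With the default ``overlap_fraction=0`` a single shared pixel suffices
    (object-level logical AND); larger values require that fraction of the
    nucleus area to be c-Fos positive.  Never increases the object count.
    """
    nuclear_labels = np.asarray(nuclear_labels)
    cfos = np.asarray(cfos_mask) > 0
    if nuclear_labels.shape != cfos.shape:
        raise ValueError("mask shapes differ")
    out = np.zeros_like(nuclear_labels)
    if nuclear_labels.max() == 0:
        return out
    ids = np.arange(1, nuclear_labels.max() + 1)
    areas = ndi.sum_labels(np.ones_like(cfos, dtype=float), nuclear_labels, ids)
    overlaps = ndi.sum_labels(cfos.astype(float), nuclear_labels, ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(areas > 0, overlaps / areas, 0.0)
    if overlap_fraction <= 0.0:
        keep = overlaps > 0
    else:
        keep = frac >= overlap_fraction
    new_id = 0
    for obj_id, k in zip(ids, keep):
        if k:
            new_id += 1
            out[nuclear_labels == obj_id] = new_id
    return out


def count_in_roi(
    object_labels: np.ndarray,
    roi_labels: np.ndarray,
    pixel_size_um: float,
    roi_legend: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Count objects per ROI (by centroid) and convert to density per mm^2.

    ``roi_labels`` is an integer label mask aligned with the image
    (0 = outside any ROI); ``roi_legend`` maps ROI labels to region names.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    object_labels = np.asarray(object_labels)
    roi_labels = np.asarray(roi_labels)
    if object_labels.shape != roi_labels.shape:
        raise ValueError("ROI mask must be aligned with the image")
    px_area_mm2 = (pixel_size_um / 1000.0) ** 2
    counts: dict[int, int] = {}
    for prop in regionprops(object_labels):
        r, c = (int(round(x)) for x in prop.centroid)
        r = min(max(r, 0), roi_labels.shape[0] - 1)
        c = min(max(c, 0), roi_labels.shape[1] - 1)
        roi = int(roi_labels[r, c])
        if roi > 0:
            counts[roi] = counts.get(roi, 0) + 1
    rows = []
    for roi in np.unique(roi_labels):
        roi = int(roi)
        if roi == 0:
            continue
        area_mm2 = float(np.count_nonzero(roi_labels == roi)) * px_area_mm2
        if area_mm2 == 0:
            raise ValueError(f"ROI {roi} has zero area")
        n = counts.get(roi, 0)
        rows.append(
            {
                "roi_label": roi,
                "region": roi_legend.get(roi, str(roi)) if roi_legend else str(roi),
                "count": n,
                "area_mm2": area_mm2,
                "density_per_mm2": n / area_mm2,
            }
        )
    return pd.DataFrame.from_records(rows)


def region_median(per_slice_densities: Sequence[float]) -> tuple[float, bool]:
    """Median density over up to three slices; flags fewer than three.

    Returns ``(median, complete)`` where ``complete`` is True when the full
    three slices were available.
    """
    arr = np.asarray(per_slice_densities, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("region_median requires at least one slice density")
    return float(np.median(arr)), arr.size >= 3


#: Combined 0-6 activation scores and their components.
COMBINED_REGIONS: dict[str, tuple[str, str]] = {
    "BLA": ("BA", "LA"),
    "CeA": ("CeL", "CeM"),
    "dPAG": ("dPAG_anterior", "dPAG_posterior"),
    "vPAG": ("vPAG_anterior", "vPAG_posterior"),
}


def activation_scores(
    densities: Mapping[str, float],
    control_densities: Mapping[str, Sequence[float]],
    combined: Mapping[str, tuple[str, str]] = COMBINED_REGIONS,
) -> dict[str, float]:
    """Score one animal's regional c-Fos densities against the controls.

    Each region scores 0-3 along the higher-is-more-activated direction with
    cuts at the control median, 75th percentile and maximum, then component
    regions are summed into the combined 0-6 scores.
    """
    scores: dict[str, float] = {}
    for region, value in densities.items():
        ref = np.asarray(control_densities.get(region, ()), dtype=float)
        ref = ref[np.isfinite(ref)]
        if ref.size < 4:
            raise ValueError(f"undersampled controls for region {region!r}")
        spec = VariableSpec(region, "cfos", 28, Rule.CONTROL_PERCENTILE, Direction.HIGHER_IS_WORSE)
        ts = build_thresholds(spec, ref)
        s = assign_score(value, ts)
        scores[region] = float("nan") if s is None else float(s)
    for name, (a, b) in combined.items():
        if a in scores and b in scores:
            scores[name] = scores[a] + scores[b]
    return scores
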