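"""Cell segmentation on band-pass-filtered frames.

A cell is a local intensity peak in the filtered image whose footprint is
the connected region above a fixed fraction (the *contour cutoff*) of the
peak level — an isohypse contour. The cell position is the unweighted
centroid of that footprint. Selection filters on area and inter-cell
distance remove debris, conglomerates and cells too close to be tracked
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .filtering import FilterParams, bandpass_filter

__all__ = [
    "SegmentationParams",
    "Detection",
    "find_peaks",
    "region_from_peak",
    "footprint_centroid",
    "apply_selection_filters",
    "interpolate_params",
    "segment_frame",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation settings.

    peak_threshold : minimal filtered-image brightness of a peak for
        inclusion on the object list.
    contour_cutoff : fraction in (0, 1) of the peak level defining the
        isohypse footprint contour.
    min_area, max_area : allowed footprint area range, px^2.
    min_separation : minimal centroid distance between cells, px; closer
        pairs are dropped entirely so only independent cells remain.
    weighted_centroid : use intensity-weighted instead of binary centroid.
    """

    peak_threshold: float = 1.0
    contour_cutoff: float = 0.5
    min_area: float = 50.0
    max_area: float = 5000.0
    min_separation: float = 25.0
    weighted_centroid: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.contour_cutoff < 1.0:
            raise ValueError(f"contour_cutoff must be in (0,1), got {self.contour_cutoff}")
        if not 0 <= self.min_area < self.max_area:
            raise ValueError("need 0 <= min_area < max_area")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass
class Detection:
    """One segmented object in one frame.

    Coordinates are 0-based with x = column, y = row; pixel centers at
    integer coordinates; `centroid` is sub-pixel.
    """

    frame_index: int
    centroid: tuple[float, float]
    peak_position: tuple[int, int]
    peak_value: float
    area: int
    footprint: frozenset[tuple[int, int]] = field(repr=False)


def find_peaks(filtered: np.ndarray, peak_threshold: float) -> list[tuple[tuple[int, int], float]]:
    """Local maxima (8-neighborhood) with value >= peak_threshold.

    Returns ``[((x, y), value), ...]`` sorted by descending value; each
    plateau of equal-valued touching maxima is reported once, at its
    lexicographically smallest (x, y) coordinate.
    """
    img = np.asarray(filtered, dtype=float)
    if img.size == 0:
        return []
    footprint = np.ones((3, 3), bool)
    local_max = img == ndimage.maximum_filter(img, footprint=footprint, mode="reflect")
    candidates = local_max & (img >= peak_threshold)
    if not candidates.any():
        return []
    # collapse plateaus: label 8-connected candidate regions of equal value
    labels, n = ndimage.label(candidates, structure=footprint)
    peaks: list[tuple[tuple[int, int], float]] = []
    for sl in ndimage.find_objects(labels):
        region = labels[sl]
        for lab in np.unique(region):
            if lab == 0:
                continue
            rows, cols = np.nonzero(region == lab)
            rows = rows + sl[0].start
            cols = cols + sl[1].start
            xy = sorted(zip(cols.tolist(), rows.tolist()))
            x, y = xy[0]
            peaks.append(((x, y), float(img[y, x])))
    # label slices can repeat labels when bounding boxes overlap; dedupe
    peaks = list(dict.fromkeys(peaks))
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return peaks


def region_from_peak(
    filtered: np.ndarray, peak: tuple[int, int], contour_cutoff: float
) -> frozenset[tuple[int, int]]:
    """Isohypse footprint: 8-connected component >= cutoff * peak value.

    `peak` is an (x, y) pixel position of a detected maximum.
    """
    if not 0.0 < contour_cutoff < 1.0:
        raise ValueError(f"contour_cutoff must be in (0,1), got {contour_cutoff}")
    img = np.asarray(filtered, dtype=float)
    x, y = peak
    level = contour_cutoff * img[y, x]
    mask = img >= level
    labels = measure.label(mask, connectivity=2)
    lab = labels[y, x]
    rows, cols = np.nonzero(labels == lab)
    return frozenset(zip(cols.tolist(), rows.tolist()))


def footprint_centroid(footprint: frozenset[tuple[int, int]]) -> tuple[float, float]:
    """Unweighted (binary) centroid of the footprint pixels, sub-pixel (x, y)."""
    if not footprint:
        raise ValueError("empty footprint has no centroid")
    pts = np.asarray(sorted(footprint), dtype=float)
    cx, cy = pts.mean(axis=0)
    return float(cx), float(cy)


def _weighted_centroid(
    filtered: np.ndarray, footprint: frozenset[tuple[int, int]]
) -> tuple[float, float]:
    pts = np.asarray(sorted(footprint))
    w = np.asarray([filtered[y, x] for x, y in pts], dtype=float)
    w = np.clip(w, 0.0, None)
    if w.sum() == 0:
        return footprint_centroid(footprint)
    cx, cy = (pts * w[:, None]).sum(axis=0) / w.sum()
    return float(cx), float(cy)


def apply_selection_filters(
    detections: list[Detection], params: SegmentationParams
) -> list[Detection]:
    """Select independent, cell-sized detections from one frame.

    Steps, in order: (1) detections sharing the same footprint keep only the
    brightest peak; (2) area filter ``min_area <= area <= max_area``; (3) any
    pair closer than `min_separation` (centroid distance) is removed
    entirely, both members, so only independent cells survive.
    """
    # (1) merged footprints -> brighter peak wins (ties: earlier in list)
    by_fp: dict[frozenset, Detection] = {}
    for det in detections:
        prev = by_fp.get(det.footprint)
        if prev is None or det.peak_value > prev.peak_value:
            by_fp[det.footprint] = det
    kept = [d for d in detections if by_fp[d.footprint] is d]

    # (2) area limits
    kept = [d for d in kept if params.min_area <= d.area <= params.max_area]

    # (3) drop BOTH members of close pairs
    if params.min_separation > 0 and len(kept) > 1:
        pos = np.asarray([d.centroid for d in kept])
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        ok = dist.min(axis=1) >= params.min_separation
        kept = [d for d, keep in zip(kept, ok) if keep]
    return kept


def interpolate_params(
    first: SegmentationParams,
    last: SegmentationParams,
    frame_index: int,
    n_frames: int,
) -> SegmentationParams:
    """Per-frame settings between user-tuned first/last-frame endpoints.

    The peak threshold is linearly interpolated across the movie (slow drifts
    in background or object brightness); the contour cutoff is the constant
    mean of the two endpoint cutoffs; all other fields come from `first`.
    """
    if n_frames < 2:
        raise ValueError("interpolation needs n_frames >= 2")
    if not 0 <= frame_index < n_frames:
        raise ValueError(f"frame_index {frame_index} out of range [0, {n_frames})")
    t = frame_index / (n_frames - 1)
    thr = (1.0 - t) * first.peak_threshold + t * last.peak_threshold
    cut = 0.5 * (first.contour_cutoff + last.contour_cutoff)
    return replace(first, peak_threshold=thr, contour_cutoff=cut)


def segment_frame(
    image: np.ndarray,
    fparams: FilterParams,
    sparams: SegmentationParams,
    frame_index: int = 0,
) -> list[Detection]:
    """Full single-frame segmentation: filter, peaks, footprints, selection."""
    filtered = bandpass_filter(image, fparams)
    peaks = find_peaks(filtered, sparams.peak_threshold)
    detections: list[Detection] = []
    for (x, y), value in peaks:
        fp = region_from_peak(filtered, (x, y), sparams.contour_cutoff)
        if sparams.weighted_centroid:
            centroid = _weighted_centroid(filtered, fp)
        else:
            centroid = footprint_centroid(fp)
        detections.append(
            Detection(
                frame_index=frame_index,
                centroid=centroid,
                peak_position=(x, y),
                peak_value=value,
                area=len(fp),
                footprint=fp,
            )
        )
    return apply_selection_filters(detections, sparams)
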