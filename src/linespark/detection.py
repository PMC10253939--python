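"""Ca2+ spark detection in confocal line scans.

The detection chain, applied to a raw space x time fluorescence grid:

1. :func:`smooth` — separable boxcar (moving-average) filter with
   user-set spatial and temporal cutoffs, edges handled by reflection.
2. :func:`normalize_time` — each pixel is divided by the running mean of
   its temporal neighbours (``half_window`` lines before and after, the
   centre excluded), yielding an F/F0 image whose grand mean is ~1 and
   whose global standard deviation sets the noise scale.  Edge columns use
   the available one-sided neighbours.
3. :func:`binarize` — a pixel is marked iff its normalized value exceeds
   the mean of 1 by more than ``n`` global standard deviations.  The
   multiplier ``n`` is the detection threshold (typical sweep values:
   0.5, 0.6, 0.7, 1.0, 1.5 above background noise).
4. :func:`erode` — morphological erosion with a 3x3 cross to suppress
   salt-and-pepper noise (isolated threshold crossings).
5. :func:`localize` — 8-connected components above a minimum area become
   spark candidates, each with its convex hull and bounding box.
6. :func:`centroid` — intensity-weighted centre of mass of each
   candidate, used as the spark coordinate.

:func:`detect` composes the chain; every stage is shape-preserving and
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from linespark.io import LineScanImage

__all__ = [
    "DetectionParams",
    "NormalizedScan",
    "BinaryMask",
    "SparkCandidate",
    "DetectionResult",
    "smooth",
    "normalize_time",
    "binarize",
    "erode",
    "localize",
    "centroid",
    "detect",
    "detect_from_normalized",
]

#: 3x3 cross (4-neighbourhood plus centre) used by the erosion stage.
CROSS = ndimage.generate_binary_structure(2, 1)

#: 8-connectivity used for candidate labeling: sparks are diagonal-elongated
#: in (x, t), and 4-connectivity fragments them.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionParams:
    """User-set parameters of the detection chain.

    ``threshold_n`` is the multiplier on the global SD of the normalized
    image; ``half_window`` is the one-sided width (in lines) of the running
    temporal baseline and must be long relative to the events being
    detected, or the baseline tracks the event itself.
    """

    space_cutoff: int = 3  # boxcar width along space (odd, pixels)
    time_cutoff: int = 3  # boxcar width along time (odd, lines)
    half_window: int = 5  # one-sided F0 window (lines)
    threshold_n: float = 0.5  # SD multiplier above the normalized mean
    erosion_iterations: int = 1
    min_area_px: int = 12

    def __post_init__(self) -> None:
        for name in ("space_cutoff", "time_cutoff"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {v}")
        if self.half_window < 1:
            raise ValueError(f"half_window must be >= 1, got {self.half_window}")
        if not self.threshold_n > 0:
            raise ValueError(f"threshold_n must be > 0, got {self.threshold_n}")
        if self.erosion_iterations < 0:
            raise ValueError(
                f"erosion_iterations must be >= 0, got {self.erosion_iterations}"
            )
        if self.min_area_px < 1:
            raise ValueError(f"min_area_px must be >= 1, got {self.min_area_px}")

    def to_dict(self) -> dict:
        return {
            "space_cutoff": self.space_cutoff,
            "time_cutoff": self.time_cutoff,
            "half_window": self.half_window,
            "threshold_n": self.threshold_n,
            "erosion_iterations": self.erosion_iterations,
            "min_area_px": self.min_area_px,
        }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DetectionParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown detection parameter(s): {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class NormalizedScan:
    """F/F0-normalized scan: mean ~1, with the global SD as noise scale."""

    values: np.ndarray  # (n_space, n_time) float64
    global_sd: float
    pixel_size: float  # um
    line_period: float  # s
    source_id: str = ""

    @property
    def n_space(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryMask:
    """Thresholded scan: 1 where the normalized value exceeds 1 + n*SD."""

    bits: np.ndarray  # (n_space, n_time) uint8 in {0, 1}
    threshold_n: float


@dataclass
class SparkCandidate:
    """A connected component of the eroded mask, a potential spark.

    ``pixels`` holds the member coordinates as an (n, 2) integer array of
    (space index, time index); ``bbox`` is (i_min, i_max, j_min, j_max),
    inclusive; ``centroid`` is the intensity-weighted centre of mass in
    fractional (space, time) indices, filled in by :func:`detect`.
    """

    pixels: np.ndarray
    hull_vertices: list[tuple[int, int]]
    area_px: int
    bbox: tuple[int, int, int, int]
    threshold_n: float
    centroid: Optional[tuple[float, float]] = None


@dataclass
class DetectionResult:
    """Candidates plus the intermediate images they were derived from."""

    candidates: list[SparkCandidate]
    normalized: NormalizedScan
    mask: BinaryMask  # pre-erosion
    eroded: BinaryMask
    params: DetectionParams

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def smooth(
    image: LineScanImage, space_cutoff: int = 3, time_cutoff: int = 3
) -> LineScanImage:
    """Separable boxcar filter: width ``space_cutoff`` along rows then
    ``time_cutoff`` along columns, reflecting at the edges."""
    for name, c in (("space_cutoff", space_cutoff), ("time_cutoff", time_cutoff)):
        if c < 1 or c % 2 == 0:
            raise ValueError(f"{name} must be an odd positive integer, got {c}")
    out = ndimage.uniform_filter(
        image.pixels, size=(space_cutoff, time_cutoff), mode="reflect"
    )
    # boxcar of non-negative data stays non-negative up to rounding
    np.clip(out, 0.0, None, out=out)
    return LineScanImage(out, image.pixel_size, image.line_period, image.source_id)


def normalize_time(
    image: LineScanImage, half_window: int = 5, floor_eps: float = 1e-6
) -> NormalizedScan:
    """Divide each pixel by the mean of its ``2*half_window`` temporal
    neighbours, the centre excluded; edge columns use the available
    one-sided neighbours (shrunken window).

    Non-positive pixels are floored at ``floor_eps`` (with a warning) so
    the running mean can never vanish.
    """
    h = int(half_window)
    if h < 1:
        raise ValueError(f"half_window must be >= 1, got {half_window}")
    n_time = image.n_time
    if n_time <= 2 * h:
        raise ValueError(
            f"scan too short for normalization: need n_time > {2 * h}, got {n_time}"
        )
    px = image.pixels
    if px.min() < floor_eps:
        warnings.warn(
            f"scan {image.source_id or '<unnamed>'} contains pixels below "
            f"{floor_eps}; flooring before normalization",
            RuntimeWarning,
            stacklevel=2,
        )
        px = np.maximum(px, floor_eps)
    cs = np.zeros((px.shape[0], n_time + 1), dtype=np.float64)
    np.cumsum(px, axis=1, out=cs[:, 1:])
    j = np.arange(n_time)
    lo = np.maximum(j - h, 0)
    hi = np.minimum(j + h, n_time - 1)
    window_sum = cs[:, hi + 1] - cs[:, lo]
    n_neighbors = (hi - lo).astype(np.float64)  # window size minus the centre
    baseline = (window_sum - px) / n_neighbors
    values = px / baseline
    return NormalizedScan(
        values=values,
        global_sd=float(np.std(values)),
        pixel_size=image.pixel_size,
        line_period=image.line_period,
        source_id=image.source_id,
    )


def binarize(norm: NormalizedScan, threshold_n: float) -> BinaryMask:
    """Mark pixels whose normalized value deviates above the mean of 1 by
    more than ``threshold_n`` times the global SD."""
    if not threshold_n > 0:
        raise ValueError(f"threshold_n must be > 0, got {threshold_n}")
    if norm.global_sd == 0:
        warnings.warn(
            "normalized scan has zero standard deviation (constant input); "
            "binarization yields an empty mask",
            RuntimeWarning,
            stacklevel=2,
        )
        bits = np.zeros_like(norm.values, dtype=np.uint8)
    else:
        bits = (norm.values - 1.0 > threshold_n * norm.global_sd).astype(np.uint8)
    return BinaryMask(bits=bits, threshold_n=float(threshold_n))


def erode(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Morphological erosion with a 3x3 cross; out-of-grid neighbours count
    as 0.  ``iterations=0`` returns the mask unchanged."""
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    if iterations == 0:
        return BinaryMask(bits=mask.bits.copy(), threshold_n=mask.threshold_n)
    out = ndimage.binary_erosion(
        mask.bits.astype(bool), structure=CROSS, iterations=iterations, border_value=0
    )
    return BinaryMask(bits=out.astype(np.uint8), threshold_n=mask.threshold_n)


def _hull_vertices(coords: np.ndarray) -> list[tuple[int, int]]:
    """Convex hull vertices of integer pixel coordinates; collinear and
    single-pixel components fall back to their lexicographic extremes."""
    pts = coords.astype(np.float64)
    if len(coords) >= 3:
        try:
            hull = ConvexHull(pts)
            return [tuple(int(v) for v in coords[k]) for k in hull.vertices]
        except QhullError:
            pass  # degenerate (collinear) component
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    lo, hi = coords[order[0]], coords[order[-1]]
    verts = [tuple(int(v) for v in lo)]
    if not np.array_equal(lo, hi):
        verts.append(tuple(int(v) for v in hi))
    return verts


def localize(mask: BinaryMask, min_area: int = 12) -> list[SparkCandidate]:
    """8-connected components of the mask with area >= ``min_area``,
    ordered by (earliest time line, lowest spatial index)."""
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    labels, n_labels = ndimage.label(mask.bits, structure=EIGHT_CONNECTED)
    candidates: list[SparkCandidate] = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        local = np.argwhere(labels[sl] == lab)
        if len(local) < min_area:
            continue
        coords = local + np.array([sl[0].start, sl[1].start])
        bbox = (
            int(coords[:, 0].min()),
            int(coords[:, 0].max()),
            int(coords[:, 1].min()),
            int(coords[:, 1].max()),
        )
        candidates.append(
            SparkCandidate(
                pixels=coords,
                hull_vertices=_hull_vertices(coords),
                area_px=int(len(coords)),
                bbox=bbox,
                threshold_n=mask.threshold_n,
            )
        )
    candidates.sort(key=lambda c: (c.bbox[2], c.bbox[0]))
    return candidates


def centroid(
    candidate: SparkCandidate, norm: NormalizedScan
) -> tuple[float, float]:
    """Intensity-weighted centre of mass of the candidate's member pixels,
    weights ``max(value - 1, 0)``; unweighted mean if all weights vanish."""
    coords = candidate.pixels
    if len(coords) == 0:
        raise ValueError("candidate has no member pixels")
    w = np.clip(norm.values[coords[:, 0], coords[:, 1]] - 1.0, 0.0, None)
    total = w.sum()
    if total <= 0:
        ci, cj = coords.mean(axis=0)
    else:
        ci = float((w * coords[:, 0]).sum() / total)
        cj = float((w * coords[:, 1]).sum() / total)
    return float(ci), float(cj)


def detect_from_normalized(
    norm: NormalizedScan, params: DetectionParams
) -> DetectionResult:
    """Threshold, erode and localize an already-normalized scan.

    Split out from :func:`detect` so threshold sweeps can reuse one
    normalization across thresholds (smoothing and normalization do not
    depend on ``threshold_n``).
    """
    mask = binarize(norm, params.threshold_n)
    eroded = erode(mask, params.erosion_iterations)
    candidates = localize(eroded, params.min_area_px)
    for cand in candidates:
        cand.centroid = centroid(cand, norm)
    return DetectionResult(
        candidates=candidates, normalized=norm, mask=mask, eroded=eroded, params=params
    )


def detect(image: LineScanImage, params: Optional[DetectionParams] = None) -> DetectionResult:
    """Run the full detection chain on a raw line scan."""
    if params is None:
        params = DetectionParams()
    smoothed = smooth(image, params.space_cutoff, params.time_cutoff)
    norm = normalize_time(smoothed, params.half_window)
    return detect_from_normalized(norm, params)
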