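"""Evaluation of detections and filters against ground truth.

The basic currency is the confusion triple (TP, FP, FN) from which the
standard detection statistics follow:

* positive predictive value  PPV = TP / (TP + FP)
* sensitivity                     = TP / (TP + FN)
* false discovery rate       FDR = FP / (TP + FP) = 1 - PPV

A zero denominator flags the statistic as undefined (``None``), never 0:
0/0 precision is not 0% performance.

Spark detections are matched to truth sparks one-to-one by a greedy pass
in ascending order of the normalized distance
``d = max(|dx| / tol_x, |dt| / tol_t)``; pairs with d <= 1 are true
positives, unmatched detections false positives, unmatched truths false
negatives.  The firing fraction is the share of scans with at least one
event.  :func:`threshold_sweep` repeats detection and matching across a
threshold ladder, reusing one normalization per scan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from linespark.detection import (
    DetectionParams,
    detect_from_normalized,
    normalize_time,
    smooth,
)
from linespark.filtering import OscillationEvent
from linespark.io import LineScanImage

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "MatchResult",
    "compute_metrics",
    "confusion_from_filter",
    "match_sparks",
    "firing_fraction",
    "threshold_sweep",
    "SWEEP_COLUMNS",
]

SWEEP_COLUMNS = (
    "threshold",
    "n_events",
    "tp",
    "fp",
    "fn",
    "ppv",
    "sensitivity",
    "fdr",
    "firing_fraction",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    """PPV / sensitivity / FDR; ``None`` marks an undefined ratio."""

    ppv: Optional[float]
    sensitivity: Optional[float]
    fdr: Optional[float]

    def to_dict(self) -> dict:
        return {"ppv": self.ppv, "sensitivity": self.sensitivity, "fdr": self.fdr}


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Derive PPV, sensitivity and FDR from a confusion triple."""
    pos = counts.tp + counts.fp
    rel = counts.tp + counts.fn
    ppv = counts.tp / pos if pos > 0 else None
    fdr = counts.fp / pos if pos > 0 else None
    sens = counts.tp / rel if rel > 0 else None
    return Metrics(ppv=ppv, sensitivity=sens, fdr=fdr)


def confusion_from_filter(
    kept: Sequence[OscillationEvent], removed: Sequence[OscillationEvent]
) -> ConfusionCounts:
    """Confusion counts of a filtering pass on a fully labeled table.

    TP = true positives kept, FP = false positives kept, FN = true
    positives removed (the detector is presumed to have found every real
    event, so filtering is the only source of false negatives).
    """
    for ev in list(kept) + list(removed):
        if ev.truth is None:
            raise ValueError(f"event {ev.roi_id!r} has no truth label")
    tp = sum(1 for ev in kept if ev.truth)
    fp = sum(1 for ev in kept if not ev.truth)
    fn = sum(1 for ev in removed if ev.truth)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


@dataclass(frozen=True)
class MatchResult:
    counts: ConfusionCounts
    pairs: list[tuple[int, int]]  # (detected index, truth index)


def match_sparks(
    detected: np.ndarray,
    truth: np.ndarray,
    tol_x: float = 2.0,
    tol_t: float = 0.1,
) -> MatchResult:
    """Greedy one-to-one matching of detected to truth spark coordinates.

    ``detected`` and ``truth`` are (n, 2) arrays of (x um, t s).  Candidate
    pairs with normalized distance ``max(|dx|/tol_x, |dt|/tol_t) <= 1``
    are taken in ascending distance order (ties broken by truth then
    detection index, so the result is deterministic).
    """
    if not (tol_x > 0 and tol_t > 0):
        raise ValueError("matching tolerances must be positive")
    det = np.asarray(detected, dtype=np.float64).reshape(-1, 2)
    tru = np.asarray(truth, dtype=np.float64).reshape(-1, 2)
    if det.size and tru.size:
        dx = np.abs(det[:, None, 0] - tru[None, :, 0]) / tol_x
        dt = np.abs(det[:, None, 1] - tru[None, :, 1]) / tol_t
        dist = np.maximum(dx, dt)
        cand = np.argwhere(dist <= 1.0)
        order = sorted(
            range(len(cand)),
            key=lambda k: (dist[cand[k, 0], cand[k, 1]], cand[k, 1], cand[k, 0]),
        )
        det_used = np.zeros(len(det), dtype=bool)
        tru_used = np.zeros(len(tru), dtype=bool)
        pairs: list[tuple[int, int]] = []
        for k in order:
            di, ti = int(cand[k, 0]), int(cand[k, 1])
            if det_used[di] or tru_used[ti]:
                continue
            det_used[di] = True
            tru_used[ti] = True
            pairs.append((di, ti))
    else:
        pairs = []
    tp = len(pairs)
    counts = ConfusionCounts(tp=tp, fp=len(det) - tp, fn=len(tru) - tp)
    return MatchResult(counts=counts, pairs=pairs)


def firing_fraction(n_events_per_scan: Sequence[int]) -> float:
    """Share of scans with at least one event."""
    scans = list(n_events_per_scan)
    if not scans:
        raise ValueError("firing_fraction needs at least one scan")
    return sum(1 for n in scans if n >= 1) / len(scans)


def threshold_sweep(
    images: Sequence[LineScanImage],
    truths: Sequence[np.ndarray],
    thresholds: Sequence[float],
    params: Optional[DetectionParams] = None,
    tol_x: float = 2.0,
    tol_t: float = 0.1,
) -> pd.DataFrame:
    """Detection performance across a ladder of thresholds.

    ``truths[k]`` is the (m, 2) array of true (x um, t s) peak coordinates
    of scan ``k`` (possibly empty).  Returns one row per threshold with the
    pooled confusion counts, derived metrics and firing fraction.
    Smoothing and normalization are computed once per scan and shared
    across thresholds.
    """
    if len(images) != len(truths):
        raise ValueError("images and truths must have equal length")
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be ascending")
    if params is None:
        params = DetectionParams()
    normed = [
        normalize_time(
            smooth(img, params.space_cutoff, params.time_cutoff), params.half_window
        )
        for img in images
    ]
    rows = []
    for thr in thresholds:
        p = replace(params, threshold_n=thr)
        counts = ConfusionCounts()
        n_events = 0
        per_scan = []
        for norm, truth in zip(normed, truths):
            result = detect_from_normalized(norm, p)
            coords = np.array(
                [
                    (
                        (c.centroid[0] + 0.5) * norm.pixel_size,
                        (c.centroid[1] + 0.5) * norm.line_period,
                    )
                    for c in result.candidates
                ],
                dtype=np.float64,
            ).reshape(-1, 2)
            match = match_sparks(coords, np.asarray(truth).reshape(-1, 2), tol_x, tol_t)
            counts = counts + match.counts
            n_events += len(result.candidates)
            per_scan.append(len(result.candidates))
        m = compute_metrics(counts)
        rows.append(
            {
                "threshold": thr,
                "n_events": n_events,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "ppv": m.ppv,
                "sensitivity": m.sensitivity,
                "fdr": m.fdr,
                "firing_fraction": firing_fraction(per_scan),
            }
        )
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
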