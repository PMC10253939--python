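"""Curation of whole-cell Ca2+ oscillation event tables.

ROI-based detectors for full-frame Ca2+ recordings (LCPro and similar)
over-report: their event tables mix genuine oscillations with erroneous
detections.  This module implements the statistical curation applied to
such tables: events are first triaged by duration (events shorter than 4 s
are subcellular sparks, events longer than 40 s are slow drifts; only the
4-40 s band is treated as oscillations), and the oscillation band is then
filtered on five kinetic parameters — amplitude (F/F0), duration (s), rise
time (s), decay time (s) and area under the curve (F*s/F0) — using one of:

* ``raw`` — no filtering (keeps everything);
* ``gold_standard`` — keep only events labeled true-positive by a trained
  observer (requires truth labels);
* ``percentile:p`` — per-parameter two-sided band between the (100-p)th and
  pth percentile of a training set, p in {80, 90, 95, 99};
* ``fence:n`` — per-parameter interquartile outlier fence
  [Q1 - n*IQR, Q3 + n*IQR], n in {1.5, 3.0, 5.0};
* ``datamined`` — a fixed box of plausible smooth-muscle oscillation
  kinetics derived from histogram inspection of curated data
  (:data:`DATA_MINED_BOUNDS`).

An event is kept iff **every** bounded parameter lies inside its
[lower, upper] interval (inclusive).  Percentiles and quartiles use the
linear-interpolation convention of mainstream statistics software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "PARAMETERS",
    "OscillationEvent",
    "FilterSpec",
    "DATA_MINED_BOUNDS",
    "DurationTriage",
    "triage_by_duration",
    "compute_percentile_bounds",
    "compute_fence_bounds",
    "apply_filter",
    "datamined_spec",
    "raw_spec",
    "gold_standard_spec",
    "standard_method_specs",
    "parse_method",
]

#: The five kinetic parameters every filter operates on, in canonical order.
PARAMETERS = ("amplitude", "duration", "rise_time", "decay_time", "area")

#: Allowed percentile levels for the percentile filters.
PERCENTILE_LEVELS = (80, 90, 95, 99)

#: Allowed fence multipliers for the named outlier-fence filters.
FENCE_MULTIPLIERS = (1.5, 3.0, 5.0)

#: Duration below which an event is classed as a subcellular spark (s).
SPARK_DURATION_MAX_S = 4.0

#: Duration above which an event is classed as a long/drift event (s).
OSCILLATION_DURATION_MAX_S = 40.0


@dataclass(frozen=True)
class OscillationEvent:
    """One row of an ROI-detector event table.

    ``truth`` is ``True`` for a gold-standard true positive, ``False`` for a
    known erroneous detection, and ``None`` when the table is unlabeled.
    """

    roi_id: str
    amplitude: float  # peak F/F0
    duration: float  # s
    rise_time: float  # s
    decay_time: float  # s
    area: float  # F*s/F0
    truth: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (self.amplitude > 0):
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        for name in ("rise_time", "decay_time", "area"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be >= 0, got {v}")

    def parameters(self) -> dict[str, float]:
        """The five filterable kinetic parameters as a dict."""
        return {name: getattr(self, name) for name in PARAMETERS}


@dataclass(frozen=True)
class FilterSpec:
    """A named filtering method with per-parameter [lower, upper] bounds.

    ``bounds`` maps parameter name -> (lower, upper); a parameter absent
    from the map is unconstrained, and -inf/+inf express open-ended bounds.
    The ``raw`` and ``gold_standard`` methods carry no bounds.
    """

    method: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if name not in PARAMETERS:
                raise ValueError(f"unknown parameter {name!r}")
            if not lo < hi:
                raise ValueError(
                    f"bound for {name!r} must satisfy lower < upper, got ({lo}, {hi})"
                )

    def contains(self, event: OscillationEvent) -> bool:
        """True iff every bounded parameter lies inside its interval."""
        return all(
            lo <= getattr(event, name) <= hi for name, (lo, hi) in self.bounds.items()
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "bounds": {k: [float(lo), float(hi)] for k, (lo, hi) in self.bounds.items()},
        }


#: Fixed plausibility box for smooth-muscle Ca2+ oscillations, obtained by
#: data mining (histogram inspection) of manually curated event tables.
DATA_MINED_BOUNDS: dict[str, tuple[float, float]] = {
    "rise_time": (0.78, 30.0),
    "decay_time": (0.78, 36.72),
    "amplitude": (1.25, 3.7),
    "area": (6.74, 108.5),
    "duration": (4.7, 40.0),
}


def raw_spec() -> FilterSpec:
    return FilterSpec("raw")


def gold_standard_spec() -> FilterSpec:
    return FilterSpec("gold_standard")


def datamined_spec() -> FilterSpec:
    return FilterSpec("datamined", dict(DATA_MINED_BOUNDS))


@dataclass(frozen=True)
class DurationTriage:
    """Events partitioned by duration into sparks / oscillations / long."""

    sparks: list[OscillationEvent]
    oscillations: list[OscillationEvent]
    long: list[OscillationEvent]


def triage_by_duration(events: Iterable[OscillationEvent]) -> DurationTriage:
    """Partition events into duration classes [0, 4), [4, 40], (40, inf).

    Only the middle class (oscillations) proceeds to filtering; sub-4 s
    events are rapid ryanodine-receptor-mediated sparks and >40 s events
    are slow drifts outside the oscillation band.
    """
    sparks: list[OscillationEvent] = []
    oscillations: list[OscillationEvent] = []
    long: list[OscillationEvent] = []
    for ev in events:
        if ev.duration < SPARK_DURATION_MAX_S:
            sparks.append(ev)
        elif ev.duration <= OSCILLATION_DURATION_MAX_S:
            oscillations.append(ev)
        else:
            long.append(ev)
    return DurationTriage(sparks, oscillations, long)


def _training_matrix(training: Sequence[OscillationEvent]) -> np.ndarray:
    if len(training) < 5:
        raise ValueError(
            f"need at least 5 training events to derive bounds, got {len(training)}"
        )
    return np.array([[getattr(ev, p) for p in PARAMETERS] for ev in training], float)


def compute_percentile_bounds(
    training: Sequence[OscillationEvent], p: int
) -> FilterSpec:
    """Two-sided percentile band per parameter: [(100-p)th, pth] percentile.

    Percentiles use linear interpolation between order statistics.
    """
    if p not in PERCENTILE_LEVELS:
        raise ValueError(f"percentile level must be one of {PERCENTILE_LEVELS}, got {p}")
    mat = _training_matrix(training)
    lows = np.percentile(mat, 100 - p, axis=0)
    highs = np.percentile(mat, p, axis=0)
    bounds = {}
    for k, name in enumerate(PARAMETERS):
        lo, hi = float(lows[k]), float(highs[k])
        if lo == hi:  # degenerate training column: keep exactly that value
            bounds[name] = (math.nextafter(lo, -math.inf), hi)
        else:
            bounds[name] = (lo, hi)
    return FilterSpec(f"percentile:{p}", bounds)


def compute_fence_bounds(training: Sequence[OscillationEvent], n: float) -> FilterSpec:
    """Interquartile outlier fence per parameter: [Q1 - n*IQR, Q3 + n*IQR].

    Quartiles use linear interpolation; any positive multiplier is accepted
    (the conventional presets are 1.5, 3.0 and 5.0).
    """
    if not n > 0:
        raise ValueError(f"fence multiplier must be > 0, got {n}")
    mat = _training_matrix(training)
    q1 = np.percentile(mat, 25, axis=0)
    q3 = np.percentile(mat, 75, axis=0)
    iqr = q3 - q1
    bounds = {}
    for k, name in enumerate(PARAMETERS):
        lo = float(q1[k] - n * iqr[k])
        hi = float(q3[k] + n * iqr[k])
        if lo == hi:  # zero IQR: degenerate fence collapses to a point
            bounds[name] = (math.nextafter(lo, -math.inf), hi)
        else:
            bounds[name] = (lo, hi)
    name_n = ("%g" % n)
    return FilterSpec(f"fence:{name_n}", bounds)


def apply_filter(
    events: Sequence[OscillationEvent], spec: FilterSpec
) -> tuple[list[OscillationEvent], list[OscillationEvent]]:
    """Partition ``events`` into (kept, removed) under ``spec``.

    ``raw`` keeps everything; ``gold_standard`` keeps events labeled
    true-positive and raises on an unlabeled table; every other method
    keeps an event iff all its bounded parameters fall inside their
    intervals (inclusive comparisons at both ends).
    """
    if spec.method == "raw":
        return list(events), []
    if spec.method == "gold_standard":
        if any(ev.truth is None for ev in events):
            raise ValueError(
                "gold_standard filtering requires truth labels on every event"
            )
        kept = [ev for ev in events if ev.truth]
        removed = [ev for ev in events if not ev.truth]
        return kept, removed
    kept, removed = [], []
    for ev in events:
        (kept if spec.contains(ev) else removed).append(ev)
    return kept, removed


def violation_counts(
    events: Sequence[OscillationEvent], spec: FilterSpec
) -> dict[str, int]:
    """Number of events falling outside each parameter's bounds.

    An event violating several parameters is counted once per parameter, so
    the values need not sum to the number removed.
    """
    counts = {name: 0 for name in spec.bounds}
    for ev in events:
        for name, (lo, hi) in spec.bounds.items():
            if not lo <= getattr(ev, name) <= hi:
                counts[name] += 1
    return counts


def standard_method_specs(
    training: Optional[Sequence[OscillationEvent]] = None,
) -> dict[str, FilterSpec]:
    """The ten standard curation methods, in presentation order.

    Percentile and fence bounds are derived from ``training`` when given;
    methods needing a training set are omitted otherwise.
    """
    specs: dict[str, FilterSpec] = {
        "raw": raw_spec(),
        "gold_standard": gold_standard_spec(),
    }
    if training is not None:
        for p in PERCENTILE_LEVELS:
            spec = compute_percentile_bounds(training, p)
            specs[spec.method] = spec
        for n in FENCE_MULTIPLIERS:
            spec = compute_fence_bounds(training, n)
            specs[spec.method] = spec
    specs["datamined"] = datamined_spec()
    return specs


def parse_method(
    method: str, training: Optional[Sequence[OscillationEvent]] = None
) -> FilterSpec:
    """Resolve a method string such as ``fence:1.5`` or ``percentile:95``.

    Recognised forms: ``raw``, ``gold`` / ``gold_standard``, ``datamined``,
    ``percentile:p`` for p in {80, 90, 95, 99}, ``fence:n`` for n in
    {1.5, 3, 5}, and ``fence:custom=<n>`` for an arbitrary multiplier.
    """
    m = method.strip().lower()
    if m == "raw":
        return raw_spec()
    if m in ("gold", "gold_standard"):
        return gold_standard_spec()
    if m == "datamined":
        return datamined_spec()
    if m.startswith("percentile:"):
        try:
            p = int(m.split(":", 1)[1])
        except ValueError:
            raise ValueError(f"unknown filtering method {method!r}") from None
        if p not in PERCENTILE_LEVELS:
            raise ValueError(
                f"unknown filtering method {method!r}: percentile level must be "
                f"one of {PERCENTILE_LEVELS}"
            )
        if training is None:
            raise ValueError(f"method {method!r} requires a training set")
        return compute_percentile_bounds(training, p)
    if m.startswith("fence:"):
        arg = m.split(":", 1)[1]
        if arg.startswith("custom="):
            n = float(arg.split("=", 1)[1])
        else:
            try:
                n = float(arg)
            except ValueError:
                raise ValueError(f"unknown filtering method {method!r}") from None
            if n not in FENCE_MULTIPLIERS:
                raise ValueError(
                    f"unknown filtering method {method!r}: registered fence "
                    f"multipliers are {FENCE_MULTIPLIERS}; use fence:custom=<n> "
                    f"for other values"
                )
        if training is None:
            raise ValueError(f"method {method!r} requires a training set")
        return compute_fence_bounds(training, n)
    raise ValueError(f"unknown filtering method {method!r}")
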