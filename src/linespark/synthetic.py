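"""Seeded synthetic data: line scans with ground-truth sparks and labeled
oscillation event tables.

The simulated spark is the same shape family the morphometry stage fits —
separable in space and time, Gaussian in space, linear rise followed by
exponential decay in time:

    F(x, t) = 1 + sum_k (A_k - 1) * exp(-(x - x_k)^2 / (2 sigma_k^2)) * g_k(t)

with ``sigma = fwhm / 2.3548`` and ``g(t)`` rising linearly from 0 to 1
over ``rise_s`` after ``t_start`` and decaying as ``exp(-dt / tau)``
afterwards.  Pixels are ``baseline * (1 + drift * j / n_time) * F`` plus
Gaussian read noise, clipped at zero.  SNR is defined as
``(amplitude - 1) * baseline / noise_sd``.

Defaults emulate smooth-muscle line-scan recordings: 128 pixels at
0.1 um, 10,000 lines at 1.89 ms (an 18.9 s scan), with sparks of
amplitude 2.0 F/F0, FWHM 2.0 um, 25 ms rise and 25 ms decay constant.
Everything is deterministic given the seed; a single root seed streams
independent per-scan seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from linespark.filtering import DATA_MINED_BOUNDS, PARAMETERS, OscillationEvent
from linespark.io import LineScanImage, write_linescan
from linespark.morphometry import GAUSSIAN_FWHM_FACTOR

__all__ = [
    "SparkTruth",
    "ScanSimConfig",
    "simulate_linescan",
    "simulate_event_table",
    "make_benchmark_suite",
    "load_benchmark_suite",
    "truth_to_frame",
    "read_truth_table",
    "TRUTH_COLUMNS",
]

ScalarOrRange = Union[float, tuple[float, float]]

#: Columns of a ground-truth spark CSV.
TRUTH_COLUMNS = ("x_center_um", "t_start_s", "amplitude_f_f0", "fwhm_um", "rise_s", "tau_s")


@dataclass(frozen=True)
class SparkTruth:
    """Ground-truth parameters of one simulated spark."""

    x_center_um: float
    t_start_s: float
    amplitude: float  # peak F/F0, > 1
    fwhm_um: float
    rise_s: float
    tau_s: float

    def __post_init__(self) -> None:
        if not self.amplitude > 1:
            raise ValueError(f"amplitude must be > 1 F/F0, got {self.amplitude}")
        for name in ("fwhm_um", "rise_s", "tau_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def t_peak_s(self) -> float:
        """Time of peak fluorescence (end of the rise)."""
        return self.t_start_s + self.rise_s

    @property
    def sigma_um(self) -> float:
        return self.fwhm_um / GAUSSIAN_FWHM_FACTOR

    @property
    def fdhm_s(self) -> float:
        """Analytic FDHM of the rise/decay shape: rise/2 + tau*ln(2)."""
        return self.rise_s / 2.0 + self.tau_s * math.log(2.0)


@dataclass(frozen=True)
class ScanSimConfig:
    """Everything that determines one simulated line scan.

    Spark parameters may be scalars or (lo, hi) ranges sampled uniformly.
    With ``well_separated`` (the default), spark onset times are spread
    over disjoint slots of the recording so consecutive events are several
    decay constants apart.
    """

    n_space: int = 128
    n_time: int = 10_000
    pixel_size_um: float = 0.1
    line_period_s: float = 0.00189
    baseline: float = 100.0  # raw detector units
    noise_sd: float = 20.0  # raw units; 20 -> SNR 5 at amplitude 2.0
    drift: float = 0.05  # fractional baseline change over the scan
    n_sparks: int = 0
    sparks: Optional[tuple[SparkTruth, ...]] = None  # explicit truth overrides n_sparks
    amplitude: ScalarOrRange = 2.0  # peak F/F0
    fwhm_um: ScalarOrRange = 2.0
    rise_s: ScalarOrRange = 0.025
    tau_s: ScalarOrRange = 0.025
    well_separated: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_space < 8 or self.n_time < 32:
            raise ValueError("scan must be at least 8 pixels x 32 lines")
        if not (self.pixel_size_um > 0 and self.line_period_s > 0):
            raise ValueError("calibration must be strictly positive")
        if not self.baseline > 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_sparks < 0:
            raise ValueError(f"n_sparks must be >= 0, got {self.n_sparks}")

    @property
    def snr(self) -> float:
        """(amplitude - 1) * baseline / noise_sd for scalar amplitude."""
        amp = self.amplitude if np.isscalar(self.amplitude) else np.mean(self.amplitude)
        if self.noise_sd == 0:
            return math.inf
        return (float(amp) - 1.0) * self.baseline / self.noise_sd


def _sample(rng: np.random.Generator, value: ScalarOrRange) -> float:
    if np.isscalar(value):
        return float(value)
    lo, hi = value
    return float(rng.uniform(lo, hi))


def _draw_sparks(config: ScanSimConfig, rng: np.random.Generator) -> list[SparkTruth]:
    duration = config.n_time * config.line_period_s
    extent = config.n_space * config.pixel_size_um
    sparks: list[SparkTruth] = []
    n = config.n_sparks
    if n == 0:
        return sparks
    # usable time band, excluding the edges where the running baseline and
    # the decay tail would be clipped
    t_lo, t_hi = 0.05 * duration, 0.90 * duration
    slot = (t_hi - t_lo) / n
    for k in range(n):
        fwhm = _sample(rng, config.fwhm_um)
        margin = min(fwhm, extent / 4)
        x_c = rng.uniform(margin, extent - margin)
        if config.well_separated:
            t_start = t_lo + slot * (k + rng.uniform(0.1, 0.6))
        else:
            t_start = rng.uniform(t_lo, t_hi)
        sparks.append(
            SparkTruth(
                x_center_um=float(x_c),
                t_start_s=float(t_start),
                amplitude=_sample(rng, config.amplitude),
                fwhm_um=fwhm,
                rise_s=_sample(rng, config.rise_s),
                tau_s=_sample(rng, config.tau_s),
            )
        )
    return sparks


def spark_field(
    config: ScanSimConfig, sparks: Sequence[SparkTruth]
) -> np.ndarray:
    """The noiseless relative-fluorescence grid F(x, t) (mean-1 baseline)."""
    x = (np.arange(config.n_space) + 0.5) * config.pixel_size_um
    t = (np.arange(config.n_time) + 0.5) * config.line_period_s
    F = np.ones((config.n_space, config.n_time), dtype=np.float64)
    for sp in sparks:
        g = np.zeros_like(t)
        dt = t - sp.t_start_s
        rising = (dt >= 0) & (dt < sp.rise_s)
        g[rising] = dt[rising] / sp.rise_s
        decaying = dt >= sp.rise_s
        g[decaying] = np.exp(-(dt[decaying] - sp.rise_s) / sp.tau_s)
        spatial = np.exp(-((x - sp.x_center_um) ** 2) / (2.0 * sp.sigma_um**2))
        F += (sp.amplitude - 1.0) * np.outer(spatial, g)
    return F


def simulate_linescan(
    config: ScanSimConfig,
) -> tuple[LineScanImage, list[SparkTruth]]:
    """Generate one line scan and its ground-truth spark list."""
    rng = np.random.default_rng(config.seed)
    sparks = list(config.sparks) if config.sparks is not None else _draw_sparks(
        config, rng
    )
    F = spark_field(config, sparks)
    ramp = 1.0 + config.drift * np.arange(config.n_time) / config.n_time
    pixels = config.baseline * ramp[None, :] * F
    if config.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sd, size=pixels.shape)
    np.clip(pixels, 0.0, None, out=pixels)
    image = LineScanImage(
        pixels=pixels,
        pixel_size=config.pixel_size_um,
        line_period=config.line_period_s,
        source_id=f"sim_seed{config.seed}",
    )
    return image, sparks


# --- oscillation event tables -------------------------------------------------

#: Sampling bands used when a parameter of a contaminating event violates the
#: plausibility box: (below-band, above-band); None where violating on that
#: side is not meaningful (a duration above 40 s would leave the oscillation
#: class entirely at triage).
_VIOLATION_BANDS: dict[str, tuple[Optional[tuple[float, float]], Optional[tuple[float, float]]]] = {
    "amplitude": ((1.0, 1.25), (3.7, 6.0)),
    "duration": ((4.0, 4.7), None),
    "rise_time": ((0.0, 0.78), (30.0, 40.0)),
    "decay_time": ((0.0, 0.78), (36.72, 50.0)),
    "area": ((0.0, 6.74), (108.5, 150.0)),
}

#: Default per-parameter violation probabilities for contaminating events:
#: erroneous ROI detections typically have implausible amplitude and/or
#: duration while the remaining kinetics may look ordinary.
DEFAULT_VIOLATION_PROBS = {"amplitude": 0.5, "duration": 0.5}


def _draw_inside(rng: np.random.Generator, name: str) -> float:
    lo, hi = DATA_MINED_BOUNDS[name]
    return float(rng.uniform(lo, hi))


def _draw_outside(rng: np.random.Generator, name: str) -> float:
    below, above = _VIOLATION_BANDS[name]
    sides = [b for b in (below, above) if b is not None]
    band = sides[int(rng.integers(len(sides)))] if len(sides) > 1 else sides[0]
    lo, hi = band
    # stay strictly outside the box at the shared edge
    v = float(rng.uniform(lo, hi))
    box_lo, box_hi = DATA_MINED_BOUNDS[name]
    if box_lo <= v <= box_hi:
        v = math.nextafter(box_lo, -math.inf) if band is below else math.nextafter(
            box_hi, math.inf
        )
    return v


def simulate_event_table(
    n_true: int = 75,
    n_false: int = 25,
    seed: int = 0,
    violation_probs: Optional[dict[str, float]] = None,
) -> list[OscillationEvent]:
    """A labeled oscillation event table: a mixture of genuine events and
    contaminating detections.

    True events are drawn uniformly inside the data-mined plausibility box
    (so the box filter keeps all of them).  For each contaminating event,
    every parameter is independently drawn outside the box with its
    violation probability (default: amplitude and duration each 0.5) and
    inside otherwise — so some contaminants look entirely plausible,
    emulating the ~75% PPV regime of raw ROI-detector output when true
    events make up 75% of the table.
    """
    if n_true < 0 or n_false < 0:
        raise ValueError("event counts must be non-negative")
    probs = DEFAULT_VIOLATION_PROBS if violation_probs is None else violation_probs
    for name in probs:
        if name not in PARAMETERS:
            raise ValueError(f"unknown parameter {name!r} in violation_probs")
    rng = np.random.default_rng(seed)
    events: list[OscillationEvent] = []
    for k in range(n_true):
        params = {name: _draw_inside(rng, name) for name in PARAMETERS}
        events.append(
            OscillationEvent(
                roi_id=f"roi{k:04d}",
                truth=True,
                **{
                    "amplitude": params["amplitude"],
                    "duration": params["duration"],
                    "rise_time": params["rise_time"],
                    "decay_time": params["decay_time"],
                    "area": params["area"],
                },
            )
        )
    for k in range(n_false):
        params = {}
        for name in PARAMETERS:
            p = probs.get(name, 0.0)
            if p > 0 and rng.random() < p:
                params[name] = _draw_outside(rng, name)
            else:
                params[name] = _draw_inside(rng, name)
        events.append(
            OscillationEvent(
                roi_id=f"roi{n_true + k:04d}",
                truth=False,
                amplitude=params["amplitude"],
                duration=params["duration"],
                rise_time=params["rise_time"],
                decay_time=params["decay_time"],
                area=params["area"],
            )
        )
    return events


# --- benchmark suite ----------------------------------------------------------

#: Condition grid of the benchmark suite: SNR x sparks per scan.
SUITE_SNR_LEVELS = (2.0, 5.0, 10.0)
SUITE_SPARK_COUNTS = (0, 2, 5)


def truth_to_frame(sparks: Sequence[SparkTruth]) -> pd.DataFrame:
    rows = {
        "x_center_um": [sp.x_center_um for sp in sparks],
        "t_start_s": [sp.t_start_s for sp in sparks],
        "amplitude_f_f0": [sp.amplitude for sp in sparks],
        "fwhm_um": [sp.fwhm_um for sp in sparks],
        "rise_s": [sp.rise_s for sp in sparks],
        "tau_s": [sp.tau_s for sp in sparks],
    }
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def read_truth_table(path: Union[str, Path]) -> list[SparkTruth]:
    frame = pd.read_csv(path)
    for col in TRUTH_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"truth table {path} is missing column {col!r}")
    return [
        SparkTruth(
            x_center_um=float(r.x_center_um),
            t_start_s=float(r.t_start_s),
            amplitude=float(r.amplitude_f_f0),
            fwhm_um=float(r.fwhm_um),
            rise_s=float(r.rise_s),
            tau_s=float(r.tau_s),
        )
        for r in frame.itertuples()
    ]


def _child_seed(root_seed: int, k: int) -> int:
    """Deterministic per-scan seed derived from the root seed."""
    return int(np.random.SeedSequence([root_seed, k]).generate_state(1)[0] % (2**31))


def make_benchmark_suite(
    out_dir: Union[str, Path],
    n_scans: int = 50,
    seed: int = 0,
    base_config: Optional[ScanSimConfig] = None,
) -> dict:
    """Write ``n_scans`` TIFF + calibration-sidecar + truth-CSV triples
    spanning the SNR x spark-count grid, plus a JSON manifest.

    The grid (SNR in {2, 5, 10}, sparks per scan in {0, 2, 5}) is cycled
    until ``n_scans`` scans exist.  Noise is set per condition from
    ``noise_sd = (amplitude - 1) * baseline / SNR``.  Re-running with the
    same seed reproduces every file byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if base_config is None:
        base_config = ScanSimConfig()
    conditions = [
        (snr, n_sp) for snr in SUITE_SNR_LEVELS for n_sp in SUITE_SPARK_COUNTS
    ]
    amp = base_config.amplitude if np.isscalar(base_config.amplitude) else float(
        np.mean(base_config.amplitude)
    )
    entries = []
    for k in range(n_scans):
        snr, n_sp = conditions[k % len(conditions)]
        child = _child_seed(seed, k)
        config = replace(
            base_config,
            n_sparks=n_sp,
            noise_sd=(float(amp) - 1.0) * base_config.baseline / snr,
            seed=child,
        )
        image, sparks = simulate_linescan(config)
        stem = f"scan{k:03d}"
        tif_path = out / f"{stem}.tif"
        write_linescan(image, tif_path)
        truth_path = out / f"{stem}_truth.csv"
        truth_to_frame(sparks).to_csv(truth_path, index=False)
        entries.append(
            {
                "scan": tif_path.name,
                "calibration": tif_path.with_suffix(".json").name,
                "truth": truth_path.name,
                "seed": child,
                "snr": snr,
                "n_sparks": n_sp,
            }
        )
    manifest = {
        "seed": seed,
        "n_scans": n_scans,
        "config": {
            "n_space": base_config.n_space,
            "n_time": base_config.n_time,
            "pixel_size_um": base_config.pixel_size_um,
            "line_period_s": base_config.line_period_s,
            "baseline": base_config.baseline,
            "drift": base_config.drift,
            "amplitude": amp,
            "fwhm_um": base_config.fwhm_um
            if np.isscalar(base_config.fwhm_um)
            else list(base_config.fwhm_um),
            "rise_s": base_config.rise_s
            if np.isscalar(base_config.rise_s)
            else list(base_config.rise_s),
            "tau_s": base_config.tau_s
            if np.isscalar(base_config.tau_s)
            else list(base_config.tau_s),
        },
        "scans": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def load_benchmark_suite(suite_dir: Union[str, Path]) -> list[dict]:
    """Read a suite manifest and resolve file paths.

    Returns one record per scan with ``scan`` / ``truth`` paths and the
    generation parameters; images are not loaded eagerly.
    """
    suite_dir = Path(suite_dir)
    manifest_path = suite_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {suite_dir}")
    manifest = json.loads(manifest_path.read_text())
    records = []
    for entry in manifest["scans"]:
        rec = dict(entry)
        rec["scan"] = suite_dir / entry["scan"]
        rec["truth"] = suite_dir / entry["truth"]
        records.append(rec)
    return records
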