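"""Spark morphometry: amplitude, FWHM, FDHM and decay time constant.

Each detected candidate is reduced to two 1-D profiles of the normalized
(F/F0) image:

* a **time profile** — the mean over the candidate's spatial rows at each
  line of a padded window around the event, baseline-equalized by
  subtracting the straight line through its first and last points (so both
  endpoints are exactly 1).  FDHM is the width between the half-maximum
  crossings (linear interpolation between samples); tau comes from a
  bounded least-squares fit of ``A*exp(-(t - t_peak)/tau) + 1`` to the
  decay limb.
* a **space profile** — the mean over the candidate's time lines at each
  spatial row, equalized the same way.  A Gaussian
  ``A*exp(-(x - mu)^2 / (2 sigma^2)) + 1`` is fitted and
  FWHM = 2*sqrt(2 ln 2)*sigma = 2.3548 sigma, converted to um.

Fits are guarded against spurious values: tau capped at 10x the profile
window, sigma at the window width; a capped or non-convergent fit sets the
corresponding ``fit_ok`` flag to False and reports the value as missing
rather than wild.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from linespark.detection import NormalizedScan, SparkCandidate, centroid

__all__ = [
    "GAUSSIAN_FWHM_FACTOR",
    "SparkEvent",
    "SparkBounds",
    "SparkFilterResult",
    "Profile1D",
    "time_profile",
    "space_profile",
    "measure_fdhm_tau",
    "space_profile_fwhm",
    "measure_spark",
    "measure_all",
    "filter_sparks",
    "spark_events_to_frame",
    "SPARK_TABLE_COLUMNS",
]

#: FWHM of a Gaussian in units of sigma: 2*sqrt(2 ln 2).
GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Exact column order of the spark event CSV.
SPARK_TABLE_COLUMNS = (
    "source_id",
    "x_peak_um",
    "t_peak_s",
    "amplitude_f_f0",
    "fwhm_um",
    "fdhm_s",
    "tau_s",
    "area_px",
    "threshold_n",
    "fit_ok_fwhm",
    "fit_ok_fdhm",
    "fit_ok_tau",
)


@dataclass(frozen=True)
class SparkEvent:
    """One measured Ca2+ spark.

    ``amplitude`` is the peak F/F0 ratio (>= 1 by construction; the
    fractional increase is ``amplitude - 1``).  Descriptors whose fit
    failed are NaN with the matching ``fit_ok`` flag cleared.
    """

    source_id: str
    x_peak_um: float
    t_peak_s: float
    amplitude_f_f0: float
    fwhm_um: float
    fdhm_s: float
    tau_s: float
    area_px: int
    threshold_n: float
    fit_ok_fwhm: bool
    fit_ok_fdhm: bool
    fit_ok_tau: bool

    @property
    def all_fits_ok(self) -> bool:
        return self.fit_ok_fwhm and self.fit_ok_fdhm and self.fit_ok_tau


@dataclass(frozen=True)
class SparkBounds:
    """Per-descriptor [lower, upper] acceptance box for measured sparks.

    Values are user-supplied (typically mined from previously curated
    datasets); there are no universal defaults because the plausible box
    depends on tissue, indicator and the analysis version that produced
    the training data.
    """

    amplitude: tuple[float, float]
    fwhm: tuple[float, float]  # um
    fdhm: tuple[float, float]  # s
    tau: tuple[float, float]  # s

    def __post_init__(self) -> None:
        for name in ("amplitude", "fwhm", "fdhm", "tau"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(
                    f"bound for {name!r} must satisfy lower < upper, got ({lo}, {hi})"
                )

    def to_dict(self) -> dict:
        return {
            name: [float(v) for v in getattr(self, name)]
            for name in ("amplitude", "fwhm", "fdhm", "tau")
        }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SparkBounds":
        return cls(**{k: tuple(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class SparkFilterResult:
    """Partition of measured sparks by a :class:`SparkBounds` box."""

    kept: list[SparkEvent]
    removed: list[SparkEvent]
    n_fit_failed: int  # events removed because a fit failed, not a bound


@dataclass(frozen=True)
class Profile1D:
    """A baseline-equalized 1-D profile plus its start index in the scan."""

    values: np.ndarray
    start: int  # index (line or row) of values[0] in the full grid


def _equalize(raw: np.ndarray) -> np.ndarray:
    """Subtract the straight line through the endpoints, re-anchoring at 1."""
    base = np.linspace(raw[0], raw[-1], raw.size)
    return raw - base + 1.0


def time_profile(
    candidate: SparkCandidate, norm: NormalizedScan, pad: int = 10
) -> Profile1D:
    """Mean normalized fluorescence over the candidate's spatial rows at
    each line of the bounding box extended by ``pad`` lines, endpoint-
    equalized so the first and last points are exactly 1."""
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    i0, i1, j0, j1 = candidate.bbox
    lo = max(0, j0 - pad)
    hi = min(norm.n_time - 1, j1 + pad)
    raw = norm.values[i0 : i1 + 1, lo : hi + 1].mean(axis=0)
    return Profile1D(values=_equalize(raw), start=lo)


def space_profile(
    candidate: SparkCandidate, norm: NormalizedScan, pad: int = 3
) -> Profile1D:
    """Mean normalized fluorescence over the candidate's time lines at each
    spatial row of the bounding box extended by ``pad`` rows, endpoint-
    equalized as in :func:`time_profile`."""
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    i0, i1, j0, j1 = candidate.bbox
    lo = max(0, i0 - pad)
    hi = min(norm.n_space - 1, i1 + pad)
    raw = norm.values[lo : hi + 1, j0 : j1 + 1].mean(axis=1)
    return Profile1D(values=_equalize(raw), start=lo)


def _half_crossings(values: np.ndarray, peak_idx: int) -> Optional[tuple[float, float]]:
    """Fractional indices where the profile crosses half-maximum on either
    side of the peak (nearest crossing moving outward), or None."""
    peak = values[peak_idx]
    if peak <= 1.0:
        return None
    half = 1.0 + (peak - 1.0) / 2.0
    left = None
    for k in range(peak_idx - 1, -1, -1):
        if values[k] < half:
            # crossing between k and k+1
            left = k + (half - values[k]) / (values[k + 1] - values[k])
            break
    right = None
    for k in range(peak_idx + 1, values.size):
        if values[k] < half:
            right = k - (half - values[k]) / (values[k - 1] - values[k])
            break
    if left is None or right is None:
        return None
    return float(left), float(right)


@dataclass(frozen=True)
class FdhmTauResult:
    fdhm_s: float
    tau_s: float
    peak_index: int  # argmax within the profile
    fit_ok_fdhm: bool
    fit_ok_tau: bool


def measure_fdhm_tau(values: np.ndarray, line_period: float) -> FdhmTauResult:
    """FDHM from interpolated half-maximum crossings and tau from an
    exponential fit to the decay limb of a time profile.

    The tau fit is ``A*exp(-t/tau) + 1`` over the segment from the peak to
    the window end; it is flagged not-ok when the optimiser fails, the
    segment is shorter than 4 samples, or tau exceeds 10x the window
    duration (a spurious-fit guard).
    """
    values = np.asarray(values, dtype=np.float64)
    if not line_period > 0:
        raise ValueError(f"line_period must be > 0, got {line_period}")
    peak_idx = int(np.argmax(values))
    peak = values[peak_idx]

    fdhm = math.nan
    fdhm_ok = False
    crossings = _half_crossings(values, peak_idx) if peak > 1.0 else None
    if crossings is not None:
        fdhm = (crossings[1] - crossings[0]) * line_period
        fdhm_ok = fdhm > 0

    tau = math.nan
    tau_ok = False
    seg = values[peak_idx:]
    if peak > 1.0 and seg.size >= 4:
        t = np.arange(seg.size, dtype=np.float64) * line_period
        window_s = values.size * line_period
        tau0 = fdhm if fdhm_ok else window_s / 4.0
        try:
            popt, _ = curve_fit(
                lambda tt, a, ta: a * np.exp(-tt / ta) + 1.0,
                t,
                seg,
                p0=[max(peak - 1.0, 1e-6), max(tau0, line_period)],
                bounds=([0.0, line_period * 1e-3], [np.inf, np.inf]),
                maxfev=5000,
            )
            tau_hat = float(popt[1])
            if tau_hat <= 10.0 * window_s:
                tau = tau_hat
                tau_ok = True
        except (RuntimeError, ValueError):
            pass
    return FdhmTauResult(
        fdhm_s=float(fdhm),
        tau_s=float(tau),
        peak_index=peak_idx,
        fit_ok_fdhm=bool(fdhm_ok),
        fit_ok_tau=bool(tau_ok),
    )


@dataclass(frozen=True)
class FwhmResult:
    fwhm_um: float
    mu_index: float  # fitted centre, fractional index within the profile
    fit_ok: bool


def space_profile_fwhm(
    values: np.ndarray, pixel_size: float, min_rows: int = 3
) -> FwhmResult:
    """Gaussian-fit FWHM of a space profile, in um.

    Flagged not-ok when the profile spans fewer than ``min_rows`` samples,
    the fit does not converge, the fitted amplitude is non-positive, or
    sigma exceeds the window width (spurious-fit guard).
    """
    values = np.asarray(values, dtype=np.float64)
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    if values.size < min_rows:
        return FwhmResult(math.nan, math.nan, False)
    peak_idx = int(np.argmax(values))
    peak = values[peak_idx]
    if peak <= 1.0:
        return FwhmResult(math.nan, math.nan, False)
    crossings = _half_crossings(values, peak_idx)
    if crossings is not None:
        sigma0 = max((crossings[1] - crossings[0]) / GAUSSIAN_FWHM_FACTOR, 0.25)
    else:
        sigma0 = values.size / 4.0
    x = np.arange(values.size, dtype=np.float64)
    try:
        popt, _ = curve_fit(
            lambda xx, a, mu, s: a * np.exp(-((xx - mu) ** 2) / (2.0 * s**2)) + 1.0,
            x,
            values,
            p0=[peak - 1.0, float(peak_idx), sigma0],
            bounds=([0.0, -values.size, 1e-3], [np.inf, 2.0 * values.size, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return FwhmResult(math.nan, math.nan, False)
    a_hat, mu_hat, sigma_hat = (float(v) for v in popt)
    if a_hat <= 0 or sigma_hat > values.size:
        return FwhmResult(math.nan, math.nan, False)
    return FwhmResult(
        fwhm_um=GAUSSIAN_FWHM_FACTOR * sigma_hat * pixel_size,
        mu_index=mu_hat,
        fit_ok=True,
    )


def measure_spark(
    candidate: SparkCandidate,
    norm: NormalizedScan,
    pad_time: int = 10,
    pad_space: int = 3,
) -> SparkEvent:
    """Assemble the full descriptor set for one candidate.

    Amplitude is the maximum normalized value over member pixels; the peak
    coordinate is the intensity-weighted centroid converted to physical
    units (pixel centres).  Fit failures are recorded in the ``fit_ok``
    flags, never raised.
    """
    coords = candidate.pixels
    amplitude = float(norm.values[coords[:, 0], coords[:, 1]].max())
    ci, cj = candidate.centroid if candidate.centroid is not None else centroid(
        candidate, norm
    )
    tprof = time_profile(candidate, norm, pad=pad_time)
    tres = measure_fdhm_tau(tprof.values, norm.line_period)
    i0, i1 = candidate.bbox[0], candidate.bbox[1]
    if i1 - i0 + 1 >= 3:
        sprof = space_profile(candidate, norm, pad=pad_space)
        sres = space_profile_fwhm(sprof.values, norm.pixel_size)
    else:  # too narrow for a spatial fit
        sres = FwhmResult(math.nan, math.nan, False)
    return SparkEvent(
        source_id=norm.source_id,
        x_peak_um=(ci + 0.5) * norm.pixel_size,
        t_peak_s=(cj + 0.5) * norm.line_period,
        amplitude_f_f0=amplitude,
        fwhm_um=sres.fwhm_um,
        fdhm_s=tres.fdhm_s,
        tau_s=tres.tau_s,
        area_px=candidate.area_px,
        threshold_n=candidate.threshold_n,
        fit_ok_fwhm=sres.fit_ok,
        fit_ok_fdhm=tres.fit_ok_fdhm,
        fit_ok_tau=tres.fit_ok_tau,
    )


def measure_all(
    candidates: Sequence[SparkCandidate],
    norm: NormalizedScan,
    pad_time: int = 10,
    pad_space: int = 3,
) -> list[SparkEvent]:
    """Measure every candidate of a scan."""
    return [measure_spark(c, norm, pad_time, pad_space) for c in candidates]


def filter_sparks(
    events: Sequence[SparkEvent], bounds: SparkBounds
) -> SparkFilterResult:
    """Keep events whose descriptors all lie inside the bounds box.

    Events with any failed fit are removed (and counted in
    ``n_fit_failed``): a descriptor that could not be measured cannot be
    certified in-bounds.
    """
    kept: list[SparkEvent] = []
    removed: list[SparkEvent] = []
    n_fit_failed = 0
    for ev in events:
        if not ev.all_fits_ok:
            removed.append(ev)
            n_fit_failed += 1
            continue
        inside = (
            bounds.amplitude[0] <= ev.amplitude_f_f0 <= bounds.amplitude[1]
            and bounds.fwhm[0] <= ev.fwhm_um <= bounds.fwhm[1]
            and bounds.fdhm[0] <= ev.fdhm_s <= bounds.fdhm[1]
            and bounds.tau[0] <= ev.tau_s <= bounds.tau[1]
        )
        (kept if inside else removed).append(ev)
    return SparkFilterResult(kept=kept, removed=removed, n_fit_failed=n_fit_failed)


def spark_events_to_frame(events: Sequence[SparkEvent]) -> pd.DataFrame:
    """Spark events as a DataFrame with the canonical CSV column order."""
    rows = [
        {col: getattr(ev, col) for col in SPARK_TABLE_COLUMNS} for ev in events
    ]
    frame = pd.DataFrame(rows, columns=list(SPARK_TABLE_COLUMNS))
    for col in ("fit_ok_fwhm", "fit_ok_fdhm", "fit_ok_tau"):
        frame[col] = frame[col].astype(bool)
    return frame
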