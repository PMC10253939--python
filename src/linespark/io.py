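"""Calibrated line-scan image and event-table I/O.

Conventions owned by this module and relied on everywhere else:

* orientation — rows are space, columns are time (a transposed file must be
  transposed by the caller, e.g. via the CLI ``--transpose`` flag);
* indices are 0-based; the physical coordinate of spatial index ``i`` is
  ``(i + 0.5) * pixel_size`` um and of time index ``j`` is
  ``(j + 0.5) * line_period`` s (pixel centres);
* calibration travels in a JSON sidecar (same basename, ``.json``) rather
  than in TIFF tags, which are dialect-ridden across acquisition software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from linespark.filtering import OscillationEvent

__all__ = [
    "Calibration",
    "LineScanImage",
    "read_linescan",
    "write_linescan",
    "read_calibration",
    "write_calibration",
    "read_event_table",
    "write_event_table",
    "EVENT_TABLE_COLUMNS",
]

PathLike = Union[str, Path]

#: Mandatory columns of an oscillation event table, in file order.
EVENT_TABLE_COLUMNS = ("roi_id", "amplitude", "duration_s", "rise_s", "decay_s", "area")


@dataclass(frozen=True)
class Calibration:
    """Physical scale of a line scan: um per spatial pixel, s per line."""

    pixel_size_um: float
    line_period_s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (np.isfinite(self.line_period_s) and self.line_period_s > 0):
            raise ValueError(f"line_period_s must be > 0, got {self.line_period_s}")

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": float(self.pixel_size_um),
            "line_period_s": float(self.line_period_s),
        }


@dataclass
class LineScanImage:
    """A calibrated line-scan recording: raw fluorescence on a space x time grid."""

    pixels: np.ndarray  # (n_space, n_time), float64, raw detector units
    pixel_size: float  # um per spatial pixel
    line_period: float  # s per time line
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D (space x time), got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 32:
            raise ValueError(
                f"line scan too small: need at least 8 spatial pixels and 32 time "
                f"lines, got {px.shape[0]} x {px.shape[1]}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must all be finite")
        if px.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        # validate calibration through the shared type
        Calibration(self.pixel_size, self.line_period)
        self.pixels = px

    @property
    def n_space(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_time(self) -> int:
        return self.pixels.shape[1]

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size, self.line_period)

    @property
    def duration_s(self) -> float:
        return self.n_time * self.line_period

    @property
    def extent_um(self) -> float:
        return self.n_space * self.pixel_size

    def space_coord_um(self, i) -> np.ndarray:
        """Physical position (um) of spatial index ``i`` (pixel centre)."""
        return (np.asarray(i, float) + 0.5) * self.pixel_size

    def time_coord_s(self, j) -> np.ndarray:
        """Physical time (s) of line index ``j`` (line centre)."""
        return (np.asarray(j, float) + 0.5) * self.line_period


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_calibration(calibration: Calibration, path: PathLike) -> None:
    Path(path).write_text(json.dumps(calibration.to_dict(), indent=2) + "\n")


def read_calibration(path: PathLike) -> Calibration:
    data = json.loads(Path(path).read_text())
    return Calibration(
        pixel_size_um=float(data["pixel_size_um"]),
        line_period_s=float(data["line_period_s"]),
    )


def read_linescan(
    path: PathLike,
    calibration: Optional[Calibration] = None,
    *,
    transpose: bool = False,
) -> LineScanImage:
    """Read a single-page grayscale TIFF line scan.

    When ``calibration`` is omitted, it is loaded from the JSON sidecar
    (same basename, ``.json``).  ``transpose=True`` swaps the axes of files
    exported with the rows-are-time layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"line scan file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if n_pages != 1:
            raise ValueError(
                f"expected single-page line scan, got {n_pages} pages in {path}"
            )
        arr = tif.pages[0].asarray()
    if arr.ndim != 2:
        raise ValueError(
            f"expected single-channel grayscale line scan, got array of shape "
            f"{arr.shape} in {path}"
        )
    if calibration is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no calibration given and sidecar {sidecar} not found"
            )
        calibration = read_calibration(sidecar)
    if transpose:
        arr = arr.T
    return LineScanImage(
        pixels=arr.astype(np.float64),
        pixel_size=calibration.pixel_size_um,
        line_period=calibration.line_period_s,
        source_id=path.stem,
    )


def write_linescan(image: LineScanImage, path: PathLike) -> None:
    """Write a single-page float32 TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    if not np.all(np.isfinite(image.pixels)) or image.pixels.min() < 0:
        raise ValueError("refusing to write invalid pixels (non-finite or negative)")
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    write_calibration(image.calibration, _sidecar_path(path))


def read_event_table(path: PathLike) -> list[OscillationEvent]:
    """Read an oscillation event table CSV.

    Mandatory columns: roi_id, amplitude, duration_s, rise_s, decay_s,
    area.  An optional ``truth`` column (1/0) maps to true/false-positive
    labels.  Rows come back in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event table not found: {path}")
    frame = pd.read_csv(path, dtype={"roi_id": str})
    for col in EVENT_TABLE_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"event table {path} is missing column {col!r}")
    numeric_cols = [c for c in EVENT_TABLE_COLUMNS if c != "roi_id"]
    has_truth = "truth" in frame.columns
    if has_truth:
        numeric_cols.append("truth")
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {frame[col].iloc[row]!r} in column {col!r}, "
                f"data row {row} of {path}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {col!r}, data row {row} of {path}")
        frame[col] = coerced
    events = []
    for _, rec in frame.iterrows():
        truth = bool(int(rec["truth"])) if has_truth else None
        events.append(
            OscillationEvent(
                roi_id=str(rec["roi_id"]),
                amplitude=float(rec["amplitude"]),
                duration=float(rec["duration_s"]),
                rise_time=float(rec["rise_s"]),
                decay_time=float(rec["decay_s"]),
                area=float(rec["area"]),
                truth=truth,
            )
        )
    return events


def events_to_frame(events: Sequence[OscillationEvent]) -> pd.DataFrame:
    """Oscillation events as a DataFrame with the canonical CSV columns."""
    rows = {
        "roi_id": [ev.roi_id for ev in events],
        "amplitude": [ev.amplitude for ev in events],
        "duration_s": [ev.duration for ev in events],
        "rise_s": [ev.rise_time for ev in events],
        "decay_s": [ev.decay_time for ev in events],
        "area": [ev.area for ev in events],
    }
    frame = pd.DataFrame(rows)
    if events and all(ev.truth is not None for ev in events):
        frame["truth"] = [int(ev.truth) for ev in events]
    return frame


def write_event_table(events: Sequence[OscillationEvent], path: PathLike) -> None:
    """Write events as CSV (truth column included when every event is labeled)."""
    events_to_frame(events).to_csv(path, index=False)
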