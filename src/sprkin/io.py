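"""Sensorgram reading, writing, response conversion and phase segmentation.

A sensorgram is a strictly-increasing time series of biosensor
responses in RU.  Raw instrument output may instead be a refractive
index series; :func:`ri_to_ru` applies the linear conversion
RU = (1.334 − RIx) × 30000 (1.334 is the refractive index of deionized
water, 30000 a sensitivity factor).

Phase segmentation splits a sensorgram into baseline, association and
dissociation sub-series using half-open time windows [start, start+duration),
re-zeroes each kinetic phase to its own start, and subtracts the
baseline-window mean so the binding model's R(0) = 0 assumption holds.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Sensorgram",
    "PhaseWindows",
    "Phases",
    "SensorgramParseError",
    "SegmentationError",
    "ri_to_ru",
    "read_sensorgram",
    "write_sensorgram",
    "segment_phases",
]

WATER_RI = 1.334
RI_SENSITIVITY = 30000.0


class SensorgramParseError(ValueError):
    """A sensorgram file failed validation; message names the offending row."""


class SegmentationError(ValueError):
    """A phase window produced an empty or invalid sub-series."""

    def __init__(self, phase: str, message: str):
        self.phase = phase
        super().__init__(f"{phase}: {message}")


def ri_to_ru(RIx) -> np.ndarray | float:
    """Convert refractive index to response units: RU = (1.334 − RIx) × 30000."""
    RIx = np.asarray(RIx, dtype=float)
    out = (WATER_RI - RIx) * RI_SENSITIVITY
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Sensorgram:
    """Paired time (s) / response (RU) series.

    Invariants: equal lengths, strictly increasing finite times, finite
    responses.
    """

    time: np.ndarray
    response: np.ndarray
    channel: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        if t.ndim != 1 or r.ndim != 1 or len(t) != len(r):
            raise ValueError("time and response must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("sensorgram values must be finite")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(
                f"time must be strictly increasing; violation at row {bad[0] + 1} "
                f"(t = {t[bad[0] + 1]!r} after {t[bad[0]]!r})"
            )

    def __len__(self) -> int:
        return len(self.time)

    def window(self, start: float, end: float) -> "Sensorgram":
        """Sub-series with start <= t < end (half-open on time values)."""
        mask = (self.time >= start) & (self.time < end)
        return Sensorgram(self.time[mask], self.response[mask], self.channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "response_RU": self.response})


@dataclass(frozen=True)
class PhaseWindows:
    """Timing of the three sensorgram phases, in seconds.

    Defaults follow the reference HBsAg/HBsAb run: 250 s baseline,
    251 s association starting at 250 s, 38 s dissociation immediately
    after.  Windows are half-open [start, start + duration) on time
    values, so the sampling need not be uniform.
    """

    baseline_end: float = 250.0
    assoc_start: float = 250.0
    assoc_duration: float = 251.0
    dissoc_start: float = 501.0
    dissoc_duration: float = 38.0

    def __post_init__(self) -> None:
        if self.assoc_start < self.baseline_end:
            raise ValueError("assoc_start must be >= baseline_end")
        if self.dissoc_start < self.assoc_start + self.assoc_duration:
            raise ValueError("dissoc_start must be >= assoc_start + assoc_duration")
        if not (self.assoc_duration > 0 and self.dissoc_duration > 0):
            raise ValueError("phase durations must be > 0")

    @property
    def assoc_end(self) -> float:
        return self.assoc_start + self.assoc_duration

    @property
    def dissoc_end(self) -> float:
        return self.dissoc_start + self.dissoc_duration


class Phases(NamedTuple):
    baseline: Sensorgram
    association: Sensorgram
    dissociation: Sensorgram


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_sensorgram(
    path,
    *,
    time_col: str = "time_s",
    response_col: str = "response_RU",
    ri: bool = False,
    ri_col: str = "ri",
    delimiter: str | None = None,
    channel: str | None = None,
) -> Sensorgram:
    """Read a delimited-text sensorgram (CSV or TSV; '#' starts a comment).

    With ``ri=True`` the response is read from ``ri_col`` as refractive
    index and converted via :func:`ri_to_ru`.

    Raises
    ------
    SensorgramParseError
        On missing columns, non-numeric cells, fewer than 3 rows, or
        duplicate / decreasing timestamps — naming the offending row.
    """
    path = Path(path)
    sep = delimiter or _detect_delimiter(path)
    value_col = ri_col if ri else response_col
    try:
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed file
        raise SensorgramParseError(f"{path}: cannot parse: {exc}") from exc
    for col in (time_col, value_col):
        if col not in df.columns:
            raise SensorgramParseError(
                f"{path}: missing column {col!r} (found {list(df.columns)})"
            )
    if len(df) < 3:
        raise SensorgramParseError(f"{path}: need at least 3 rows, found {len(df)}")
    for col in (time_col, value_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise SensorgramParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r} at data row {bad[0] + 1}"
            )
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 1
            raise SensorgramParseError(f"{path}: missing value in {col!r} at data row {row}")
        df[col] = vals
    response = ri_to_ru(df[value_col].to_numpy()) if ri else df[value_col].to_numpy()
    try:
        return Sensorgram(df[time_col].to_numpy(), response, channel)
    except ValueError as exc:
        raise SensorgramParseError(f"{path}: {exc}") from exc


def write_sensorgram(s: Sensorgram, path, *, delimiter: str = ",") -> None:
    """Write a sensorgram as delimited text at full float precision."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"time_s{delimiter}response_RU\n")
    for t, r in zip(s.time, s.response):
        buf.write(f"{float(t)!r}{delimiter}{float(r)!r}\n")
    path.write_text(buf.getvalue())


def segment_phases(
    s: Sensorgram, w: PhaseWindows, *, subtract_baseline: bool = True
) -> Phases:
    """Split a sensorgram into (baseline, association, dissociation).

    The baseline window is [t[0], baseline_end); the kinetic phases use
    their half-open [start, start + duration) windows.  Association and
    dissociation times are re-zeroed to their own phase start.  With
    ``subtract_baseline`` (default) the baseline-window mean is
    subtracted from both kinetic phases, so the fitted models start
    from R = 0 at injection; the subtraction is idempotent on a series
    whose baseline is already zero-mean.

    Raises
    ------
    SegmentationError
        If any phase window is empty after slicing.
    """
    t0 = float(s.time[0]) if len(s) else 0.0
    baseline = s.window(t0, w.baseline_end)
    if len(baseline) == 0:
        raise SegmentationError("baseline", "window is empty")
    assoc = s.window(w.assoc_start, w.assoc_end)
    if len(assoc) == 0:
        raise SegmentationError("association", "window is empty")
    dissoc = s.window(w.dissoc_start, w.dissoc_end)
    if len(dissoc) == 0:
        raise SegmentationError("dissociation", "window is empty")
    offset = float(np.mean(baseline.response)) if subtract_baseline else 0.0
    assoc = Sensorgram(assoc.time - w.assoc_start, assoc.response - offset, s.channel)
    dissoc = Sensorgram(dissoc.time - w.dissoc_start, dissoc.response - offset, s.channel)
    return Phases(baseline, assoc, dissoc)
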