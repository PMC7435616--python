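"""Readers and writers for the package's plain-text formats.

Formats (all comma-delimited UTF-8 with headers, times in seconds from
session start, intervals half-open [start, end)):

* accelerometer CSV: ``t_s,ax_g,ay_g,az_g``, one row per sample;
* connectivity CSV: ``start_s,end_s``, one row per connected interval;
* 15-second epoch CSV: ``epoch_start_s,sitting_s,standing_s,stepping_s``;
* paired CSV: ``subject_id,behavior,test_min,criterion_min``;
* timeline CSV: ``start_s,end_s,label``; totals JSON with the six minute keys.

Readers validate and reject rather than silently repair; parse failures name
the first offending line (1-based, counting the header).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (
    BEHAVIORS,
    UNMONITORED,
    ActivityTimeline,
    ActivityTotals,
    SensorStream,
    TimelineInterval,
)

__all__ = [
    "EpochRecord",
    "ParseError",
    "read_accel_csv",
    "write_accel_csv",
    "read_connectivity_csv",
    "write_connectivity_csv",
    "read_epoch_csv",
    "write_epoch_csv",
    "timeline_to_epochs",
    "read_paired_csv",
    "write_paired_csv",
    "read_timeline_csv",
    "write_timeline_csv",
    "write_totals_json",
    "read_totals_json",
]

EPOCH_S = 15.0


class ParseError(ValueError):
    """A file failed validation; the message names the offending line."""


@dataclass(frozen=True)
class EpochRecord:
    """Behavior seconds within one 15-second criterion-device epoch."""

    epoch_start_s: float
    sitting_s: float
    standing_s: float
    stepping_s: float

    def __post_init__(self) -> None:
        total = self.sitting_s + self.standing_s + self.stepping_s
        if min(self.sitting_s, self.standing_s, self.stepping_s) < 0:
            raise ValueError("epoch behavior seconds must be non-negative")
        if total > EPOCH_S + 1e-9:
            raise ValueError(f"epoch behavior seconds sum to {total} > {EPOCH_S}")


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: not parseable as CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _first_bad_numeric(df: pd.DataFrame, columns: list[str]) -> int | None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            return int(bad.idxmax())
    return None


# -- accelerometer ----------------------------------------------------------

def read_accel_csv(path, connectivity_path=None, sampling_rate_hz: float = 6.25) -> SensorStream:
    cols = ["t_s", "ax_g", "ay_g", "az_g"]
    df = _read_table(path, cols)
    bad = _first_bad_numeric(df, cols)
    if bad is not None:
        raise ParseError(f"{path}: non-numeric value at line {bad + 2}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise ParseError(f"{path}: non-increasing timestamp at line {i + 3}")
    connected = None
    if connectivity_path is not None:
        connected = read_connectivity_csv(connectivity_path)
    return SensorStream(
        t=t,
        acc=df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        sampling_rate_hz=sampling_rate_hz,
        connected=connected,
    )


def write_accel_csv(stream: SensorStream, path) -> None:
    df = pd.DataFrame(
        {
            "t_s": stream.t,
            "ax_g": stream.acc[:, 0],
            "ay_g": stream.acc[:, 1],
            "az_g": stream.acc[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_connectivity_csv(path) -> list[tuple[float, float]]:
    df = _read_table(path, ["start_s", "end_s"])
    bad = _first_bad_numeric(df, ["start_s", "end_s"])
    if bad is not None:
        raise ParseError(f"{path}: non-numeric value at line {bad + 2}")
    out = list(zip(df["start_s"].astype(float), df["end_s"].astype(float)))
    prev_end = -math.inf
    for i, (a, b) in enumerate(out):
        if b <= a or a < prev_end:
            raise ParseError(f"{path}: invalid or overlapping interval at line {i + 2}")
        prev_end = b
    return out


def write_connectivity_csv(intervals, path) -> None:
    pd.DataFrame(intervals, columns=["start_s", "end_s"]).to_csv(
        path, index=False, float_format="%.17g"
    )


# -- epochs ------------------------------------------------------------------

def read_epoch_csv(path) -> tuple[list[EpochRecord], ActivityTotals]:
    """Read 15-second epoch records and derive per-behavior minute totals.

    Requires sorted, gapless 15-second spacing; an empty file yields zero
    totals with a warning.
    """
    cols = ["epoch_start_s", "sitting_s", "standing_s", "stepping_s"]
    df = _read_table(path, cols)
    if df.empty:
        import warnings

        warnings.warn(f"{path}: empty epoch file; totals are zero", stacklevel=2)
        return [], ActivityTotals(0.0, 0.0, 0.0)
    bad = _first_bad_numeric(df, cols)
    if bad is not None:
        raise ParseError(f"{path}: non-numeric value at line {bad + 2}")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    gaps = np.diff(starts)
    off = np.flatnonzero(~np.isclose(gaps, EPOCH_S, atol=1e-6))
    if off.size:
        raise ParseError(
            f"{path}: epochs must be contiguous at {EPOCH_S}-second spacing "
            f"(violated at epoch index {int(off[0]) + 1})"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                EpochRecord(
                    float(row.epoch_start_s),
                    float(row.sitting_s),
                    float(row.standing_s),
                    float(row.stepping_s),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: invalid epoch at index {i}: {exc}") from exc
    totals = ActivityTotals(
        sitting_min=float(df["sitting_s"].sum()) / 60.0,
        standing_min=float(df["standing_s"].sum()) / 60.0,
        stepping_min=float(df["stepping_s"].sum()) / 60.0,
    )
    return records, totals


def write_epoch_csv(records, path) -> None:
    pd.DataFrame(
        [
            {
                "epoch_start_s": r.epoch_start_s,
                "sitting_s": r.sitting_s,
                "standing_s": r.standing_s,
                "stepping_s": r.stepping_s,
            }
            for r in records
        ],
        columns=["epoch_start_s", "sitting_s", "standing_s", "stepping_s"],
    ).to_csv(path, index=False, float_format="%.17g")


def timeline_to_epochs(timeline: ActivityTimeline, epoch_s: float = EPOCH_S) -> list[EpochRecord]:
    """Tally a labeled timeline into fixed 15-second epochs (criterion-device
    style export); unmonitored time contributes to no behavior."""
    if not timeline.intervals:
        return []
    start = timeline.intervals[0].start_s
    end = timeline.intervals[-1].end_s
    n_epochs = int(math.ceil((end - start) / epoch_s - 1e-9))
    records = []
    for k in range(n_epochs):
        e0, e1 = start + k * epoch_s, start + (k + 1) * epoch_s
        sums = {b: 0.0 for b in BEHAVIORS}
        for iv in timeline.intervals:
            if iv.label == UNMONITORED:
                continue
            lo, hi = max(iv.start_s, e0), min(iv.end_s, e1)
            if hi > lo:
                sums[iv.label] += hi - lo
        records.append(
            EpochRecord(e0, sums["sitting"], sums["standing"], sums["stepping"])
        )
    return records


# -- paired measurements -----------------------------------------------------

def read_paired_csv(path) -> pd.DataFrame:
    cols = ["subject_id", "behavior", "test_min", "criterion_min"]
    df = _read_table(path, cols)
    bad = _first_bad_numeric(df, ["test_min", "criterion_min"])
    if bad is not None:
        raise ParseError(f"{path}: non-numeric value at line {bad + 2}")
    unknown = set(df["behavior"].unique()) - set(BEHAVIORS)
    if unknown:
        raise ParseError(f"{path}: unknown behaviors {sorted(unknown)}")
    if (df[["test_min", "criterion_min"]] < 0).any().any():
        raise ParseError(f"{path}: negative minutes")
    return df[cols]


def write_paired_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


# -- timeline and totals -----------------------------------------------------

def write_timeline_csv(timeline: ActivityTimeline, path) -> None:
    pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.label) for iv in timeline.intervals],
        columns=["start_s", "end_s", "label"],
    ).to_csv(path, index=False, float_format="%.17g")


def read_timeline_csv(path) -> ActivityTimeline:
    df = _read_table(path, ["start_s", "end_s", "label"])
    bad = _first_bad_numeric(df, ["start_s", "end_s"])
    if bad is not None:
        raise ParseError(f"{path}: non-numeric value at line {bad + 2}")
    try:
        return ActivityTimeline(
            [
                TimelineInterval(float(r.start_s), float(r.end_s), str(r.label))
                for r in df.itertuples(index=False)
            ]
        )
    except ValueError as exc:
        raise ParseError(f"{path}: invalid timeline: {exc}") from exc


def write_totals_json(totals: ActivityTotals, path, **meta) -> None:
    payload = dict(totals.as_dict())
    payload.update(meta)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_totals_json(path) -> ActivityTotals:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return ActivityTotals(
        sitting_min=float(payload["sitting_min"]),
        standing_min=float(payload["standing_min"]),
        stepping_min=float(payload["stepping_min"]),
    )
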