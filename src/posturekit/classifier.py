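"""Decision-rule classification of sitting, standing and stepping time from a
thigh-worn triaxial accelerometer.

The classifier reproduces the counter state machine used by thigh-worn
occupational posture monitors.  A normalized gravity-projection index of the
thigh axis (0 = vertical thigh / standing, 1 = horizontal thigh / sitting)
drives two competing reading counters.  Detected acceleration switches the
machine into a stepping state and zeroes both posture counters; whichever
posture counter first accumulates a full run of readings (75 by default)
commits that posture retroactively over the run and ends the stepping
episode.  Readings are only classified inside the configured recording
window and while the sensor is connected; everything else is "unmonitored".

When sensor disconnections make the counted time fall short of the elapsed
recording time by at least a threshold (15 minutes by default), a weighted
reconciliation rescales the per-behavior totals so that they sum exactly to
the elapsed time, using largest-remainder rounding to whole minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SENSOR_RANGE_G",
    "BEHAVIORS",
    "UNMONITORED",
    "AccelSample",
    "SensorStream",
    "RecordingWindow",
    "ClassifierConfig",
    "ActivityTotals",
    "TimelineInterval",
    "ActivityTimeline",
    "InvalidSampleError",
    "StreamValidationError",
    "UnadjustableSessionError",
    "normalized_z",
    "posture_from_z",
    "reading_features",
    "detect_steps",
    "classify_stream",
    "weighted_adjustment",
    "derive_composites",
]

#: Amplitude range of the sensor, in g.
SENSOR_RANGE_G = 16.0

#: Controlled vocabulary of classified behaviors.
BEHAVIORS = ("sitting", "standing", "stepping")

#: Label for time that was inside the recording window but not classifiable
#: (disconnected sensor, or no samples).
UNMONITORED = "unmonitored"

StepMode = Literal["normal", "sensitive", "robust"]

# Tie guard for the posture threshold comparison: a reading at exactly the
# threshold must classify as standing even under floating-point filter noise.
_Z_ATOL = 1e-12

# Internal integer label codes used during classification.
_UNMON, _SIT, _STAND, _STEP = 0, 1, 2, 3
_CODE_TO_LABEL = {_UNMON: UNMONITORED, _SIT: "sitting", _STAND: "standing", _STEP: "stepping"}


class InvalidSampleError(ValueError):
    """A physically invalid accelerometer sample (e.g. zero gravity vector)."""


class StreamValidationError(ValueError):
    """A sensor stream violates its structural invariants."""


class UnadjustableSessionError(ValueError):
    """Reconciliation was required but the session has no counted time."""


@dataclass(frozen=True)
class AccelSample:
    """One triaxial accelerometer reading.

    Parameters
    ----------
    t : float
        Seconds since session start (non-negative).
    ax, ay, az : float
        Acceleration components in g.  ``az`` is the component along the
        sensing direction perpendicular to the thigh's long axis, so that
        gravity projects fully onto it when the thigh is horizontal.
    """

    t: float
    ax: float
    ay: float
    az: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InvalidSampleError(f"negative timestamp {self.t!r}")
        for name in ("ax", "ay", "az"):
            v = getattr(self, name)
            if not math.isfinite(v) or abs(v) > SENSOR_RANGE_G:
                raise InvalidSampleError(
                    f"{name}={v!r} outside the sensor range of +/-{SENSOR_RANGE_G} g"
                )

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass
class SensorStream:
    """An ordered triaxial accelerometer stream with connectivity metadata.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Sample timestamps in seconds since session start, strictly increasing.
    acc : ndarray, shape (n, 3)
        Acceleration in g, columns (ax, ay, az).
    sampling_rate_hz : float
        Nominal sampling rate (6.25 Hz for the target sensor).
    connected : list of (start_s, end_s) or None
        Disjoint, sorted intervals during which the sensor and software were
        linked.  ``None`` means connected for the whole stream.  Samples
        outside connected intervals are never classified.
    """

    t: np.ndarray
    acc: np.ndarray
    sampling_rate_hz: float = 6.25
    connected: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.t.ndim != 1:
            raise StreamValidationError("t must be one-dimensional")
        if self.acc.shape != (self.t.size, 3):
            raise StreamValidationError(
                f"acc must have shape (n, 3) matching t; got {self.acc.shape}"
            )
        if self.t.size:
            if np.any(self.t < 0):
                raise StreamValidationError("timestamps must be non-negative")
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise StreamValidationError(
                    f"timestamps must be strictly increasing (violated at sample {i + 1})"
                )
            if np.any(~np.isfinite(self.acc)) or np.any(np.abs(self.acc) > SENSOR_RANGE_G):
                raise StreamValidationError(
                    f"acceleration outside the sensor range of +/-{SENSOR_RANGE_G} g"
                )
        if self.sampling_rate_hz <= 0:
            raise StreamValidationError("sampling_rate_hz must be positive")
        if self.connected is not None:
            ivs = [(float(a), float(b)) for a, b in self.connected]
            prev_end = -math.inf
            for a, b in ivs:
                if b <= a:
                    raise StreamValidationError(f"empty connectivity interval ({a}, {b})")
                if a < prev_end:
                    raise StreamValidationError("connectivity intervals must be disjoint and sorted")
                prev_end = b
            self.connected = ivs

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_samples(
        cls,
        samples: Iterable[AccelSample],
        sampling_rate_hz: float = 6.25,
        connected: list[tuple[float, float]] | None = None,
    ) -> "SensorStream":
        rows = list(samples)
        t = np.array([s.t for s in rows], dtype=float)
        acc = np.array([[s.ax, s.ay, s.az] for s in rows], dtype=float).reshape(-1, 3)
        return cls(t=t, acc=acc, sampling_rate_hz=sampling_rate_hz, connected=connected)

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return int(self.t.size)

    def samples(self) -> Iterator[AccelSample]:
        for i in range(len(self)):
            yield AccelSample(float(self.t[i]), *map(float, self.acc[i]))

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        if not len(self):
            return 0.0
        return float(self.t[-1] - self.t[0]) + self.dt

    def connected_intervals(self) -> list[tuple[float, float]]:
        """Connectivity intervals, defaulting to the full sample span."""
        if self.connected is not None:
            return list(self.connected)
        if not len(self):
            return []
        return [(float(self.t[0]), float(self.t[-1]) + self.dt)]


@dataclass(frozen=True)
class RecordingWindow:
    """The configured recording period, in seconds since session start.

    The wear protocol this tool targets uses 3-8 working hours; that bound is
    checked only on request (``check_protocol_duration``) so that short test
    sessions remain valid inputs.
    """

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s):
            raise ValueError("recording window must have end > start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def check_protocol_duration(self, min_hours: float = 3.0, max_hours: float = 8.0) -> None:
        hours = self.duration_s / 3600.0
        if not (min_hours <= hours <= max_hours):
            raise ValueError(
                f"recording window of {hours:.2f} h outside the "
                f"{min_hours}-{max_hours} h wear protocol"
            )


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of the decision-rule classifier.

    Attributes
    ----------
    z_threshold : float
        Normalized z-axis cutoff; readings strictly above it count toward
        sitting, readings at or below it toward standing.
    counter_limit : int
        Number of readings a posture counter must reach before the posture is
        committed and any stepping episode ends.
    step_mode : {"normal", "sensitive", "robust"}
        Step-detector sensitivity preset.
    adjustment_threshold_min : float
        Discrepancy (minutes) between counted and elapsed time at which the
        weighted reconciliation triggers.
    sampling_rate_hz : float
        Nominal reading rate.
    gravity_smooth_s : float
        Width (seconds) of the boxcar smoother used to estimate the gravity
        component per axis; the dynamic component is the residual.
    movement_threshold_g : float
        Dynamic-acceleration magnitude (g) above which a reading counts as
        detected movement and enters/extends the stepping state.
    """

    z_threshold: float = 0.8
    counter_limit: int = 75
    step_mode: StepMode = "normal"
    adjustment_threshold_min: float = 15.0
    sampling_rate_hz: float = 6.25
    gravity_smooth_s: float = 2.0
    movement_threshold_g: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.z_threshold < 1.0):
            raise ValueError("z_threshold must lie strictly between 0 and 1")
        if self.counter_limit < 1:
            raise ValueError("counter_limit must be >= 1")
        if self.step_mode not in ("normal", "sensitive", "robust"):
            raise ValueError(f"unknown step mode {self.step_mode!r}")
        if self.adjustment_threshold_min <= 0:
            raise ValueError("adjustment_threshold_min must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


@dataclass(frozen=True)
class ActivityTotals:
    """Per-behavior minute totals with derived composites.

    ``stationary_min`` (sitting + standing), ``upright_min`` (standing +
    stepping) and ``recording_min`` (all three) are derived properties, so the
    additive invariants hold by construction.
    """

    sitting_min: float
    standing_min: float
    stepping_min: float

    def __post_init__(self) -> None:
        for name in ("sitting_min", "standing_min", "stepping_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def stationary_min(self) -> float:
        return self.sitting_min + self.standing_min

    @property
    def upright_min(self) -> float:
        return self.standing_min + self.stepping_min

    @property
    def recording_min(self) -> float:
        return self.sitting_min + self.standing_min + self.stepping_min

    def as_dict(self) -> dict[str, float]:
        return {
            "sitting_min": self.sitting_min,
            "standing_min": self.standing_min,
            "stepping_min": self.stepping_min,
            "stationary_min": self.stationary_min,
            "upright_min": self.upright_min,
            "recording_min": self.recording_min,
        }


@dataclass(frozen=True)
class TimelineInterval:
    start_s: float
    end_s: float
    label: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ActivityTimeline:
    """Contiguous, non-overlapping labeled intervals covering a window."""

    intervals: list[TimelineInterval]

    def __post_init__(self) -> None:
        prev_end = None
        for iv in self.intervals:
            if iv.end_s <= iv.start_s:
                raise ValueError(f"empty timeline interval {iv}")
            if iv.label not in BEHAVIORS and iv.label != UNMONITORED:
                raise ValueError(f"unknown timeline label {iv.label!r}")
            if prev_end is not None and not math.isclose(iv.start_s, prev_end, abs_tol=1e-9):
                raise ValueError("timeline intervals must be contiguous")
            prev_end = iv.end_s

    def duration_s(self, label: str) -> float:
        return sum(iv.duration_s for iv in self.intervals if iv.label == label)

    @property
    def monitored_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals if iv.label != UNMONITORED)

    def totals(self) -> ActivityTotals:
        return ActivityTotals(
            sitting_min=self.duration_s("sitting") / 60.0,
            standing_min=self.duration_s("standing") / 60.0,
            stepping_min=self.duration_s("stepping") / 60.0,
        )


# ---------------------------------------------------------------------------
# Reading-level operations
# ---------------------------------------------------------------------------

def normalized_z(sample: AccelSample) -> float:
    """Gravity-projection index of the thigh axis for a single reading.

    Returns the fraction of the acceleration magnitude carried by the z
    sensing direction, clamped to [0, 1]: 0 for a perfectly vertical thigh
    (standing), 1 for a perfectly horizontal thigh (sitting).

    Raises
    ------
    InvalidSampleError
        If the acceleration vector is (numerically) zero, as in free fall.
    """
    mag = sample.magnitude
    if mag < 1e-6:
        raise InvalidSampleError("zero acceleration vector has no orientation")
    return min(1.0, abs(sample.az) / mag)


def posture_from_z(z: float, threshold: float = 0.8) -> str:
    """Posture decision rule: sitting iff z exceeds the threshold.

    A value at exactly the threshold classifies as standing ("equal to or
    lower" goes to the standing counter); a tiny absolute guard keeps that
    boundary stable under floating-point filtering noise.
    """
    if not (0.0 <= z <= 1.0):
        raise ValueError(f"normalized z must lie in [0, 1]; got {z!r}")
    return "sitting" if z > threshold + _Z_ATOL else "standing"


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge padding (per column)."""
    if width <= 1 or x.shape[0] < 2:
        return x.astype(float, copy=True)
    width = min(width, x.shape[0])
    if width % 2 == 0:
        width -= 1
    if width <= 1:
        return x.astype(float, copy=True)
    kernel = np.full(width, 1.0 / width)
    pad = width // 2
    if x.ndim == 1:
        xp = np.pad(x, pad, mode="edge")
        return np.convolve(xp, kernel, mode="valid")
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        xp = np.pad(x[:, j], pad, mode="edge")
        out[:, j] = np.convolve(xp, kernel, mode="valid")
    return out


def reading_features(
    stream: SensorStream, config: ClassifierConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reading classifier inputs: smoothed normalized z and movement flag.

    The gravity component of each axis is estimated with a centered boxcar
    smoother of width ``gravity_smooth_s``; the normalized z is the smoothed
    |az| over the smoothed gravity magnitude (clamped to [0, 1]) and the
    movement flag is true where the residual (dynamic) acceleration magnitude
    exceeds ``movement_threshold_g``.
    """
    config = config or ClassifierConfig()
    n = len(stream)
    if n == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    width = max(1, int(round(config.gravity_smooth_s * stream.sampling_rate_hz)))
    gravity = _boxcar(stream.acc, width)
    mag = np.linalg.norm(gravity, axis=1)
    if np.any(mag < 1e-6):
        raise InvalidSampleError("gravity estimate vanished; stream has no orientation")
    z = np.clip(np.abs(gravity[:, 2]) / mag, 0.0, 1.0)
    dyn = np.linalg.norm(stream.acc - gravity, axis=1)
    movement = dyn > config.movement_threshold_g
    return z, movement


# ---------------------------------------------------------------------------
# Step detection
# ---------------------------------------------------------------------------

# Peak-prominence presets (g per reading of jerk) for the three sensitivity
# modes.  Candidate peaks are found once with the most permissive preset and
# a common refractory spacing, then filtered by the mode's prominence, which
# makes robust <= normal <= sensitive a structural guarantee.
_STEP_PROMINENCE: dict[str, float] = {"sensitive": 0.12, "normal": 0.25, "robust": 0.40}
_STEP_MIN_SEPARATION_S = 0.3
_STEP_MIN_SAMPLES = 5


def detect_steps(stream: SensorStream, mode: StepMode = "normal",
                 config: ClassifierConfig | None = None) -> np.ndarray:
    """Candidate step-event times from acceleration dynamics.

    The sample-to-sample change of the acceleration vector (a jerk proxy,
    which passes stride impacts and rejects slow gravity reorientation) is
    scanned for peaks with a refractory spacing of ~0.3 s; the mode sets the
    minimum peak prominence.  For any fixed signal the event sets are
    nested: robust is a subset of normal, normal a subset of sensitive.

    Windows shorter than the detector's minimum span yield no events.
    """
    if mode not in _STEP_PROMINENCE:
        raise ValueError(f"unknown step mode {mode!r}")
    if len(stream) < _STEP_MIN_SAMPLES:
        return np.empty(0)
    jerk = np.linalg.norm(np.diff(stream.acc, axis=0), axis=1)
    distance = max(1, int(round(_STEP_MIN_SEPARATION_S * stream.sampling_rate_hz)))
    peaks, props = find_peaks(jerk, prominence=_STEP_PROMINENCE["sensitive"], distance=distance)
    keep = props["prominences"] >= _STEP_PROMINENCE[mode]
    return stream.t[peaks[keep] + 1]


# ---------------------------------------------------------------------------
# The counter state machine
# ---------------------------------------------------------------------------

def _monitored_mask(stream: SensorStream, window: RecordingWindow) -> np.ndarray:
    """A reading is monitored if it lies in the window and its midpoint falls
    inside a connected interval."""
    dt = stream.dt
    t = stream.t
    mon = (t >= window.start_s - 1e-9) & (t + dt <= window.end_s + 1e-9)
    intervals = stream.connected_intervals()
    mid = t + 0.5 * dt
    in_conn = np.zeros(len(stream), dtype=bool)
    for a, b in intervals:
        in_conn |= (mid >= a) & (mid < b)
    return mon & in_conn


def classify_stream(
    stream: SensorStream,
    window: RecordingWindow,
    config: ClassifierConfig | None = None,
) -> tuple[ActivityTimeline, ActivityTotals]:
    """Run the counter state machine over a stream.

    Per monitored reading: a detected movement puts the machine in the
    stepping state and resets both posture counters; otherwise the z rule
    increments exactly one posture counter and zeroes the other.  While
    stepping, readings accrue tentatively as stepping; when a posture counter
    reaches ``counter_limit`` the span covered by that run is committed to the
    posture retroactively and stepping stops.  Disconnection gaps and
    out-of-window time are labeled unmonitored and reset the machine.

    Returns the labeled timeline over the recording window and the per-
    behavior minute totals (before any weighted reconciliation).
    """
    config = config or ClassifierConfig()
    if not math.isclose(stream.sampling_rate_hz, config.sampling_rate_hz, rel_tol=0.01):
        raise StreamValidationError(
            f"stream rate {stream.sampling_rate_hz} Hz does not match the configured "
            f"{config.sampling_rate_hz} Hz"
        )
    n = len(stream)
    if n == 0:
        timeline = ActivityTimeline(
            [TimelineInterval(window.start_s, window.end_s, UNMONITORED)]
        )
        return timeline, ActivityTotals(0.0, 0.0, 0.0)

    z, movement = reading_features(stream, config)
    mon = _monitored_mask(stream, window)
    t = stream.t
    dt = stream.dt
    limit = config.counter_limit
    thr = config.z_threshold

    labels = np.zeros(n, dtype=np.int8)
    sit_c = stand_c = 0
    stepping = False
    prev_t: float | None = None

    for i in range(n):
        if not mon[i]:
            sit_c = stand_c = 0
            stepping = False
            prev_t = None
            continue
        if prev_t is not None and (t[i] - prev_t) > 1.5 * dt:
            # missing samples inside a connected span: treat as a gap
            sit_c = stand_c = 0
            stepping = False
        prev_t = t[i]
        if movement[i]:
            stepping = True
            sit_c = stand_c = 0
            labels[i] = _STEP
            continue
        if z[i] > thr + _Z_ATOL:
            sit_c += 1
            stand_c = 0
            cur, run = _SIT, sit_c
        else:
            stand_c += 1
            sit_c = 0
            cur, run = _STAND, stand_c
        labels[i] = _STEP if stepping else cur
        if run >= limit:
            if stepping:
                labels[i - limit + 1 : i + 1] = cur
                stepping = False
            sit_c = stand_c = 0

    timeline = _build_timeline(t, dt, labels, window)
    return timeline, timeline.totals()


def _build_timeline(
    t: np.ndarray, dt: float, labels: np.ndarray, window: RecordingWindow
) -> ActivityTimeline:
    events: list[list] = []  # [start, end, code]

    def push(start: float, end: float, code: int) -> None:
        if end - start <= 1e-12:
            return
        if events and events[-1][2] == code and math.isclose(events[-1][1], start, abs_tol=1e-9):
            events[-1][1] = end
        else:
            events.append([start, end, code])

    cursor = window.start_s
    for i in range(t.size):
        s = max(float(t[i]), window.start_s)
        e = min(float(t[i]) + dt, window.end_s)
        if e <= s:
            continue
        if s > cursor + 1e-12:
            push(cursor, s, _UNMON)
        push(max(s, cursor), e, int(labels[i]))
        cursor = max(cursor, e)
    if cursor < window.end_s - 1e-12:
        push(cursor, window.end_s, _UNMON)
    intervals = [TimelineInterval(s, e, _CODE_TO_LABEL[c]) for s, e, c in events]
    return ActivityTimeline(intervals)


# ---------------------------------------------------------------------------
# Totals post-processing
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def weighted_adjustment(
    totals: ActivityTotals,
    elapsed_min: float,
    threshold_min: float = 15.0,
) -> ActivityTotals:
    """Reconcile counted behavior totals with the elapsed recording time.

    If the discrepancy between the counted total and ``elapsed_min`` reaches
    ``threshold_min`` (typically caused by temporal sensor disconnections),
    each behavior is rescaled by ``elapsed / counted`` and rounded to whole
    minutes by the largest-remainder rule, so the rounded components sum
    exactly to the elapsed time.  Below the threshold the totals are
    returned unchanged.

    Raises
    ------
    UnadjustableSessionError
        If reconciliation is required but no time was counted at all.
    """
    if elapsed_min <= 0:
        raise ValueError("elapsed_min must be positive")
    counted = totals.recording_min
    if abs(elapsed_min - counted) < threshold_min - 1e-9:
        return totals
    if counted <= 0:
        raise UnadjustableSessionError(
            "cannot redistribute elapsed time over a session with zero counted time"
        )
    target_total = _round_half_up(elapsed_min)
    comps = [totals.sitting_min, totals.standing_min, totals.stepping_min]
    scaled = [c * elapsed_min / counted for c in comps]
    floors = [math.floor(s) for s in scaled]
    short = target_total - sum(floors)
    # distribute leftover minutes to the largest remainders; ties broken by
    # larger scaled value, then by fixed behavior order
    order = sorted(
        range(3), key=lambda i: (-(scaled[i] - floors[i]), -scaled[i], i)
    )
    out = list(map(float, floors))
    for k in range(int(short)):
        out[order[k % 3]] += 1.0
    return ActivityTotals(sitting_min=out[0], standing_min=out[1], stepping_min=out[2])


def derive_composites(totals: ActivityTotals | dict) -> ActivityTotals:
    """Composite behaviors from the base three.

    Stationary = sitting + standing, upright = standing + stepping, recording
    = all three.  Composites are derived properties of :class:`ActivityTotals`
    so this simply normalizes the input into that container.
    """
    if isinstance(totals, ActivityTotals):
        return totals
    return ActivityTotals(
        sitting_min=float(totals["sitting_min"]),
        standing_min=float(totals["standing_min"]),
        stepping_min=float(totals["stepping_min"]),
    )
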