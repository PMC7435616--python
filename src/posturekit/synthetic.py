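"""Ground-truth-scripted synthetic data for the classifier and the
agreement suite.

Two generators are provided:

* :func:`generate_signal` turns an :class:`ActivityScript` (an ordered bout
  schedule of sitting / standing / stepping) into a thigh-orientation
  accelerometer stream: sitting bouts put gravity on the z sensing axis
  (normalized z near 1), standing bouts put it on the thigh's long axis
  (normalized z near 0), and stepping bouts superimpose one dynamic impulse
  per stride at the scripted cadence.  Posture transitions are linear
  orientation ramps; Bluetooth dropouts are carved out by a renewal process.

* :func:`generate_paired_measurements` draws per-subject (test, criterion)
  minute totals per behavior with a controlled between-device error
  structure (additive bias + Gaussian or lognormal disagreement noise),
  emulating the statistical structure of a device-validation study.

The default means, spreads, biases and disagreement noise mirror a 20-subject
occupational validation study (working sessions of roughly 4 hours with about
180 min sitting, 75 min standing and 24 min stepping against the criterion
device); see the methods note for how the spread parameters were derived from
the study's summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .classifier import (
    BEHAVIORS,
    ActivityTimeline,
    ActivityTotals,
    SensorStream,
    TimelineInterval,
)

__all__ = [
    "ActivityScript",
    "NoiseModel",
    "ErrorModel",
    "SyntheticSession",
    "generate_signal",
    "generate_paired_measurements",
    "STUDY_CRITERION_MEANS",
    "STUDY_BETWEEN_SUBJECT_SD",
    "STUDY_ERROR",
]


@dataclass
class ActivityScript:
    """Ground-truth bout schedule.

    Parameters
    ----------
    bouts : sequence of (behavior, duration_s)
        Ordered behaviors from {"sitting", "standing", "stepping"} with
        positive durations in seconds.
    cadence_steps_per_min : float
        Stride rate used for stepping bouts.
    """

    bouts: list[tuple[str, float]]
    cadence_steps_per_min: float = 100.0

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValueError("script must contain at least one bout")
        clean = []
        for behavior, dur in self.bouts:
            if behavior not in BEHAVIORS:
                raise ValueError(f"unknown behavior {behavior!r}")
            if dur <= 0:
                raise ValueError(f"bout duration must be positive; got {dur!r}")
            clean.append((behavior, float(dur)))
        self.bouts = clean
        if self.cadence_steps_per_min <= 0:
            raise ValueError("cadence must be positive")

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.bouts)

    def ground_truth_timeline(self) -> ActivityTimeline:
        intervals, cursor = [], 0.0
        for behavior, dur in self.bouts:
            intervals.append(TimelineInterval(cursor, cursor + dur, behavior))
            cursor += dur
        return ActivityTimeline(intervals)

    def ground_truth_totals(self) -> ActivityTotals:
        sums = {b: 0.0 for b in BEHAVIORS}
        for behavior, dur in self.bouts:
            sums[behavior] += dur
        return ActivityTotals(
            sitting_min=sums["sitting"] / 60.0,
            standing_min=sums["standing"] / 60.0,
            stepping_min=sums["stepping"] / 60.0,
        )

    def stride_count(self) -> int:
        """Scripted number of strides over all stepping bouts."""
        f = self.cadence_steps_per_min / 60.0
        return sum(int(math.floor(d * f)) for b, d in self.bouts if b == "stepping")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-imperfection parameters of the signal generator.

    orientation_jitter_sd is the sd of the (radian) jitter on the thigh
    inclination angle, which is approximately the sd of the normalized-z
    index near the standing orientation.  transition_s is the linear
    orientation-ramp duration at posture changes.  Dropouts follow a renewal
    process: connected spells of mean 3600/disconnect_rate_per_hr seconds
    alternate with disconnected spells of mean disconnect_mean_s seconds
    (rate 0 disables dropouts).
    """

    orientation_jitter_sd: float = 0.02
    dynamic_noise_g: float = 0.03
    transition_s: float = 1.0
    disconnect_rate_per_hr: float = 0.0
    disconnect_mean_s: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "orientation_jitter_sd",
            "dynamic_noise_g",
            "transition_s",
            "disconnect_rate_per_hr",
            "disconnect_mean_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def expected_dropout_fraction(self) -> float:
        """Long-run fraction of time disconnected under the renewal process."""
        if self.disconnect_rate_per_hr <= 0:
            return 0.0
        mean_gap = 3600.0 / self.disconnect_rate_per_hr
        return self.disconnect_mean_s / (self.disconnect_mean_s + mean_gap)


@dataclass(frozen=True)
class ErrorModel:
    """Between-device error structure for paired measurements.

    bias_min and noise_sd_min may be scalars (applied to every behavior) or
    per-behavior mappings.  With the lognormal option the disagreement noise
    is multiplicative with matched mean and sd, producing the skewed regime
    in which nonparametric tests get selected downstream.
    """

    bias_min: float | dict[str, float] = 0.0
    noise_sd_min: float | dict[str, float] = 0.0
    distribution: Literal["normal", "lognormal"] = "normal"

    def __post_init__(self) -> None:
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        for b in BEHAVIORS:
            if self.noise_sd_for(b) < 0:
                raise ValueError("noise_sd_min must be non-negative")

    def bias_for(self, behavior: str) -> float:
        if isinstance(self.bias_min, dict):
            return float(self.bias_min.get(behavior, 0.0))
        return float(self.bias_min)

    def noise_sd_for(self, behavior: str) -> float:
        if isinstance(self.noise_sd_min, dict):
            return float(self.noise_sd_min.get(behavior, 0.0))
        return float(self.noise_sd_min)


#: Criterion-device per-behavior session means (minutes) used as the default
#: study conditions for paired-measurement simulation.
STUDY_CRITERION_MEANS: dict[str, float] = {"sitting": 180.5, "standing": 75.4, "stepping": 24.0}

#: Between-subject spread (minutes) of the criterion totals.
STUDY_BETWEEN_SUBJECT_SD: dict[str, float] = {"sitting": 92.0, "standing": 36.1, "stepping": 10.5}

#: Default between-device error: additive bias and disagreement noise per
#: behavior, on the order observed in thigh-worn monitor validation work.
STUDY_ERROR = ErrorModel(
    bias_min={"sitting": -1.66, "standing": -4.85, "stepping": 1.15},
    noise_sd_min={"sitting": 14.6, "standing": 13.5, "stepping": 8.3},
)


@dataclass
class SyntheticSession:
    """A generated stream together with its ground truth."""

    stream: SensorStream
    script: ActivityScript
    truth_timeline: ActivityTimeline
    seed: int | None = None

    @property
    def truth_totals(self) -> ActivityTotals:
        return self.script.ground_truth_totals()

    def monitored_truth_totals(self) -> ActivityTotals:
        """Ground-truth totals restricted to connected time."""
        connected = self.stream.connected_intervals()
        sums = {b: 0.0 for b in BEHAVIORS}
        for iv in self.truth_timeline.intervals:
            for a, b in connected:
                lo, hi = max(iv.start_s, a), min(iv.end_s, b)
                if hi > lo:
                    sums[iv.label] += hi - lo
        return ActivityTotals(
            sitting_min=sums["sitting"] / 60.0,
            standing_min=sums["standing"] / 60.0,
            stepping_min=sums["stepping"] / 60.0,
        )


# thigh inclination targets: angle from vertical, so sin(angle) is the
# normalized-z index
_ANGLE = {"sitting": math.pi / 2.0, "standing": 0.0, "stepping": 0.0}
_STEP_IMPULSE_G = 0.9
_STEP_SWAY_G = 0.1


def _inclination_profile(script: ActivityScript, t: np.ndarray, transition_s: float) -> np.ndarray:
    angle = np.empty_like(t)
    cursor = 0.0
    prev_angle = _ANGLE[script.bouts[0][0]]
    for behavior, dur in script.bouts:
        target = _ANGLE[behavior]
        sel = (t >= cursor - 1e-12) & (t < cursor + dur - 1e-12)
        seg = np.full(sel.sum(), target)
        if transition_s > 0 and target != prev_angle:
            # linear ramp from the previous orientation at the bout start
            tt = t[sel] - cursor
            ramp = tt < transition_s
            seg[ramp] = prev_angle + (target - prev_angle) * tt[ramp] / transition_s
        angle[sel] = seg
        cursor += dur
        prev_angle = target
    return angle


def _stepping_dynamics(
    script: ActivityScript, t: np.ndarray, rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-stride impulse train plus a small sway sinusoid (n, 3)."""
    dyn = np.zeros((t.size, 3))
    f = script.cadence_steps_per_min / 60.0
    cursor = 0.0
    for behavior, dur in script.bouts:
        if behavior == "stepping":
            n_strides = int(math.floor(dur * f))
            stride_times = cursor + (np.arange(n_strides) + 0.5) / f
            idx = np.clip(np.round(stride_times * rate_hz).astype(int), 0, t.size - 1)
            # raised impulse spread over the nearest samples: one dominant
            # sample per stride at the 6.25 Hz readout
            for off, w in ((-1, 0.25), (0, 1.0), (1, 0.25)):
                j = np.clip(idx + off, 0, t.size - 1)
                np.add.at(dyn[:, 0], j, w * _STEP_IMPULSE_G)
            sel = (t >= cursor) & (t < cursor + dur)
            dyn[sel, 2] += _STEP_SWAY_G * np.sin(2 * math.pi * f * t[sel])
        cursor += dur
    return dyn


def _dropout_intervals(
    total_s: float, noise: NoiseModel, rng: np.random.Generator
) -> list[tuple[float, float]]:
    if noise.disconnect_rate_per_hr <= 0:
        return []
    mean_gap = 3600.0 / noise.disconnect_rate_per_hr
    out: list[tuple[float, float]] = []
    cursor = 0.0
    while True:
        start = cursor + rng.exponential(mean_gap)
        if start >= total_s:
            break
        end = min(start + rng.exponential(noise.disconnect_mean_s), total_s)
        if end > start:
            out.append((start, end))
        cursor = end
    return out


def _complement(intervals: list[tuple[float, float]], total_s: float) -> list[tuple[float, float]]:
    out, cursor = [], 0.0
    for a, b in intervals:
        if a > cursor:
            out.append((cursor, a))
        cursor = b
    if cursor < total_s:
        out.append((cursor, total_s))
    return out


def generate_signal(
    script: ActivityScript,
    noise: NoiseModel | None = None,
    rate_hz: float = 6.25,
    seed: int | None = None,
) -> SyntheticSession:
    """Generate a thigh-accelerometer stream realizing a bout script.

    Returns a :class:`SyntheticSession` whose stream carries connectivity
    intervals (complement of the simulated dropouts) and whose ground-truth
    timeline and totals equal the script exactly.  Identical inputs and seed
    give bit-identical output.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    total = script.total_duration_s
    n = int(round(total * rate_hz))
    if n < 1:
        raise ValueError("script too short for the sampling rate")
    t = np.arange(n) / rate_hz

    angle = _inclination_profile(script, t, noise.transition_s)
    if noise.orientation_jitter_sd > 0:
        angle = angle + rng.normal(0.0, noise.orientation_jitter_sd, n)
    acc = np.zeros((n, 3))
    acc[:, 0] = np.cos(angle)  # thigh long axis
    acc[:, 2] = np.sin(angle)  # anterior (z) sensing axis
    acc += _stepping_dynamics(script, t, rate_hz, rng)
    if noise.dynamic_noise_g > 0:
        acc += rng.normal(0.0, noise.dynamic_noise_g, (n, 3))
    np.clip(acc, -16.0, 16.0, out=acc)

    dropouts = _dropout_intervals(total, noise, rng)
    connected = _complement(dropouts, total)
    stream = SensorStream(t=t, acc=acc, sampling_rate_hz=rate_hz, connected=connected)
    return SyntheticSession(
        stream=stream,
        script=script,
        truth_timeline=script.ground_truth_timeline(),
        seed=seed,
    )


def generate_paired_measurements(
    n_subjects: int = 20,
    behavior_means: dict[str, float] | None = None,
    between_subject_sd: dict[str, float] | None = None,
    error: ErrorModel | None = None,
    seed: int | None = None,
):
    """Draw per-subject paired (test, criterion) minute totals per behavior.

    For each subject the criterion value is drawn around the behavior mean
    with the given between-subject spread (truncated at zero); the test value
    is criterion + bias + disagreement noise (Gaussian, or multiplicative
    lognormal with matched moments), also truncated at zero.

    Returns a long-format :class:`pandas.DataFrame` with columns
    ``subject_id, behavior, test_min, criterion_min``.
    """
    import pandas as pd

    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    means = behavior_means or STUDY_CRITERION_MEANS
    spreads = between_subject_sd or STUDY_BETWEEN_SUBJECT_SD
    error = error if error is not None else STUDY_ERROR
    rng = np.random.default_rng(seed)

    rows = []
    for behavior in BEHAVIORS:
        mu = float(means[behavior])
        sd = float(spreads.get(behavior, 0.0))
        criterion = mu + rng.normal(0.0, 1.0, n_subjects) * sd
        np.maximum(criterion, 0.0, out=criterion)
        bias = error.bias_for(behavior)
        nsd = error.noise_sd_for(behavior)
        if error.distribution == "lognormal" and nsd > 0:
            # multiplicative disagreement with mean 1 and sd nsd/mu
            cv = nsd / max(mu, 1e-9)
            sigma2 = math.log1p(cv * cv)
            factor = rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2), n_subjects)
            test = criterion * factor + bias
        else:
            test = criterion + bias + rng.normal(0.0, 1.0, n_subjects) * nsd
        np.maximum(test, 0.0, out=test)
        for i in range(n_subjects):
            rows.append(
                {
                    "subject_id": f"S{i + 1:03d}",
                    "behavior": behavior,
                    "test_min": float(test[i]),
                    "criterion_min": float(criterion[i]),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "behavior", "test_min", "criterion_min"])
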