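"""PLR metric extraction and participant-level aggregation.

Four metrics are computed per valid trial from the smoothed series:

* baseline pupil diameter A0 — mean smoothed diameter over the 200 ms
  immediately preceding the flash;
* relative constriction amplitude — (A0^2 - A_m^2) / A0^2, where A_m is
  the post-flash minimum diameter;
* absolute constriction amplitude — A0 - A_m, in mm;
* constriction latency — time from flash onset to the point of
  most-negative acceleration (constriction-onset marker).

When both eyes yield clean data on a trial, metrics are averaged across
eyes; participants aggregate metrics over valid trials (means, but the
median for latency) and are included only with four or more valid
trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import preprocess as pp
from .preprocess import EyeTrace, SmoothedTrace, TrialScreenResult

BASELINE_WINDOW_MS = pp.BASELINE_WINDOW_MS
LATENCY_WINDOW_MS = pp.ACCELERATION_TIMING_MS  # metric and QC windows coincide
MIN_VALID_TRIALS = 4

PARADOXICAL_DILATION = "paradoxical_dilation"
SINGLE_EYE = "single_eye"
DEGENERATE_ACCELERATION = "degenerate_acceleration"

_METRIC_FIELDS = ("baseline_mm", "min_mm", "min_time_ms", "relative_amplitude",
                  "absolute_amplitude_mm", "latency_ms")


class DegenerateTrialError(ValueError):
    """Raised when a trial has no identifiable constriction onset."""


@dataclass(frozen=True)
class TrialMetrics:
    """Per-trial PLR quantities for one eye or the eye-combined trial."""

    baseline_mm: float
    min_mm: float
    min_time_ms: float
    relative_amplitude: float
    absolute_amplitude_mm: float
    latency_ms: float
    eye: str  # "left" | "right" | "combined"
    valid: bool
    flags: tuple = ()
    participant_id: str = ""
    trial_id: object = None


@dataclass(frozen=True)
class ParticipantMetrics:
    """Participant-level PLR aggregates over valid trials."""

    participant_id: str
    n_valid_trials: int
    included: bool
    mean_baseline_mm: float = float("nan")
    mean_relative_amplitude: float = float("nan")
    mean_absolute_amplitude_mm: float = float("nan")
    median_latency_ms: float = float("nan")
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.included != (self.n_valid_trials >= MIN_VALID_TRIALS):
            raise ValueError("included must reflect the >=4 valid-trial rule")


def baseline_diameter(smoothed: SmoothedTrace,
                      window_ms: float = BASELINE_WINDOW_MS) -> float:
    """Mean smoothed diameter over [flash - window, flash), i.e. the
    window ending at, and exclusive of, the flash sample."""
    trace = smoothed.source
    k = int(round(window_ms * trace.sampling_rate_hz / 1000.0))
    lo = trace.flash_onset_index - k
    if lo < 0:
        raise ValueError("baseline window precedes trace start")
    if bool(smoothed.unreliable[lo : trace.flash_onset_index].any()):
        raise ValueError("baseline window contains unresolved missing samples")
    return float(smoothed.diameter_mm[lo : trace.flash_onset_index].mean())


def minimum_diameter(smoothed: SmoothedTrace) -> tuple[float, float]:
    """Minimum smoothed diameter in (flash, flash + 1500 ms] and its
    time relative to flash onset (earliest index on ties)."""
    trace = smoothed.source
    lo, hi = trace.window_bounds(pp.MIN_TIMING_MS)
    if hi > trace.n_samples - 1:
        raise ValueError("minimum-search window truncated by trace end")
    if bool(smoothed.unreliable[lo : hi + 1].any()):
        raise ValueError("minimum-search window contains unresolved missing samples")
    i_min = lo + int(np.argmin(smoothed.diameter_mm[lo : hi + 1]))
    return float(smoothed.diameter_mm[i_min]), trace.time_after_flash_ms(i_min)


def relative_amplitude(a0: float, a_m: float) -> float:
    """(A0^2 - A_m^2) / A0^2; negative values signal paradoxical dilation."""
    if a0 <= 0:
        raise ValueError("baseline diameter must be positive")
    return (a0 * a0 - a_m * a_m) / (a0 * a0)


def absolute_amplitude(a0: float, a_m: float) -> float:
    """A0 - A_m, in mm."""
    return a0 - a_m


def constriction_latency(smoothed: SmoothedTrace,
                         window_ms: float = LATENCY_WINDOW_MS) -> float:
    """Time from flash onset to the most-negative smoothed acceleration
    within (flash, flash + 500 ms] (earliest index on ties).

    A flat acceleration profile has no constriction onset and raises
    :class:`DegenerateTrialError` instead of returning a spurious 0.
    """
    trace = smoothed.source
    lo, hi = trace.window_bounds(window_ms)
    if hi > trace.n_samples - 1:
        raise ValueError("latency window truncated by trace end")
    if bool(smoothed.unreliable[lo : hi + 1].any()):
        raise ValueError("latency window contains unresolved missing samples")
    window = smoothed.acceleration_mm_per_s2[lo : hi + 1]
    scale = max(1.0, float(np.abs(window).max()))
    if float(np.ptp(window)) < 1e-9 * scale:
        raise DegenerateTrialError("acceleration is flat; no constriction onset")
    i_acc = lo + int(np.argmin(window))
    return trace.time_after_flash_ms(i_acc)


@dataclass(frozen=True)
class EyeExtraction:
    """One eye-trial's screening decisions and (if valid) metrics."""

    metrics: TrialMetrics | None
    screen_pre: TrialScreenResult
    screen_post: TrialScreenResult | None

    @property
    def valid(self) -> bool:
        return self.metrics is not None and self.metrics.valid


def extract_eye_metrics(trace: EyeTrace) -> EyeExtraction:
    """Run the full per-eye pipeline: screen, interpolate, smooth,
    screen again, and extract metrics."""
    pre = pp.screen_missing(trace)
    if not pre.passed:
        return EyeExtraction(metrics=None, screen_pre=pre, screen_post=None)
    filled = pp.interpolate_gaps(trace)
    smoothed = pp.smooth_trace(filled)
    post = pp.screen_curve(smoothed)
    if not post.passed:
        return EyeExtraction(metrics=None, screen_pre=pre, screen_post=post)
    flags: list[str] = []
    try:
        a0 = baseline_diameter(smoothed)
        a_m, t_min = minimum_diameter(smoothed)
    except ValueError:
        # Metric window unusable despite passing screens (e.g. a long
        # gap reaching past the trace edge); fail as incomplete.
        failed_post = TrialScreenResult(
            passed=False, failed_criteria=(pp.MIN_AFTER_1500MS,),
            stage="post_smoothing", flags=(pp.WINDOW_INCOMPLETE,),
        )
        return EyeExtraction(metrics=None, screen_pre=pre, screen_post=failed_post)
    try:
        latency = constriction_latency(smoothed)
    except DegenerateTrialError:
        metrics = TrialMetrics(
            baseline_mm=a0, min_mm=a_m, min_time_ms=t_min,
            relative_amplitude=relative_amplitude(a0, a_m),
            absolute_amplitude_mm=absolute_amplitude(a0, a_m),
            latency_ms=float("nan"), eye=trace.eye or "unknown", valid=False,
            flags=(DEGENERATE_ACCELERATION,),
            participant_id=trace.participant_id, trial_id=trace.trial_id,
        )
        return EyeExtraction(metrics=metrics, screen_pre=pre, screen_post=post)
    rel = relative_amplitude(a0, a_m)
    if rel < 0:
        flags.append(PARADOXICAL_DILATION)
    metrics = TrialMetrics(
        baseline_mm=a0, min_mm=a_m, min_time_ms=t_min,
        relative_amplitude=rel, absolute_amplitude_mm=absolute_amplitude(a0, a_m),
        latency_ms=latency, eye=trace.eye or "unknown", valid=True,
        flags=tuple(flags),
        participant_id=trace.participant_id, trial_id=trace.trial_id,
    )
    return EyeExtraction(metrics=metrics, screen_pre=pre, screen_post=post)


def combine_eyes(left: TrialMetrics | None, right: TrialMetrics | None) -> TrialMetrics:
    """Average metrics across eyes when both are valid; otherwise carry
    the single valid eye forward with a provenance flag."""
    left_ok = left is not None and left.valid
    right_ok = right is not None and right.valid
    if not left_ok and not right_ok:
        raise ValueError("neither eye is valid; trial is invalid")
    if left_ok and right_ok:
        values = {f: 0.5 * (getattr(left, f) + getattr(right, f)) for f in _METRIC_FIELDS}
        flags = tuple(sorted(set(left.flags) | set(right.flags)))
        return TrialMetrics(eye="combined", valid=True, flags=flags,
                            participant_id=left.participant_id,
                            trial_id=left.trial_id, **values)
    source = left if left_ok else right
    return replace(source, eye="combined",
                   flags=tuple(sorted(set(source.flags) | {SINGLE_EYE})))


def aggregate_participant(trials, participant_id: str = "") -> ParticipantMetrics:
    """Aggregate trial metrics: means over valid trials for baseline and
    amplitudes, the median for latency; inclusion requires >= 4 valid
    trials, and excluded participants carry no aggregates."""
    trials = list(trials)
    valid = [t for t in trials if t.valid]
    if not participant_id and trials:
        participant_id = trials[0].participant_id
    n_valid = len(valid)
    included = n_valid >= MIN_VALID_TRIALS
    if not included:
        return ParticipantMetrics(participant_id=participant_id,
                                  n_valid_trials=n_valid, included=False)
    flags = tuple(sorted({f for t in valid for f in t.flags}))
    return ParticipantMetrics(
        participant_id=participant_id,
        n_valid_trials=n_valid,
        included=True,
        mean_baseline_mm=float(np.mean([t.baseline_mm for t in valid])),
        mean_relative_amplitude=float(np.mean([t.relative_amplitude for t in valid])),
        mean_absolute_amplitude_mm=float(np.mean([t.absolute_amplitude_mm for t in valid])),
        median_latency_ms=float(np.median([t.latency_ms for t in valid])),
        flags=flags,
    )


def participant_table(records) -> pd.DataFrame:
    """Flatten ParticipantMetrics records to a tidy table."""
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "n_valid_trials": r.n_valid_trials,
            "included": r.included,
            "mean_baseline_mm": r.mean_baseline_mm,
            "mean_relative_amplitude": r.mean_relative_amplitude,
            "mean_absolute_amplitude_mm": r.mean_absolute_amplitude_mm,
            "median_latency_ms": r.median_latency_ms,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)
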