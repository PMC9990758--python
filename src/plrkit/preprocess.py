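"""Per-eye trace cleaning, smoothing, and trial-validity screening.

A raw eye-trial goes through two screening stages. The first
(:func:`screen_missing`) operates on the raw samples and rejects trials
with more than 100 ms of missing pupil data inside the 1500 ms
post-flash window, or with a missing sample at flash onset. Surviving
trials have short blink gaps linearly interpolated, are smoothed with a
degree-2, 11-sample Savitzky-Golay filter (yielding smoothed diameter,
velocity and acceleration series) followed by a Gaussian convolution
(SD 5 samples), and then pass through the second stage
(:func:`screen_curve`), which requires the post-flash diameter minimum,
the most-negative velocity, and the most-negative acceleration to occur
within 1500, 750, and 500 ms of the flash respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter

# Filter constants (documented defaults; see docs/methods.md).
SG_WINDOW_SAMPLES = 11
SG_DEGREE = 2
GAUSSIAN_SD_SAMPLES = 5.0
GAUSSIAN_TRUNCATE_SD = 4.0

# QC windows and budgets, in milliseconds post flash onset.
MISSING_WINDOW_MS = 1500.0
MAX_MISSING_MS = 100.0
MIN_TIMING_MS = 1500.0
VELOCITY_TIMING_MS = 750.0
ACCELERATION_TIMING_MS = 500.0
MAX_GAP_SAMPLES = 12  # 100 ms at 120 Hz
BASELINE_WINDOW_MS = 200.0  # pre-flash window used for A0 (shared with metrics)

# Screening failure tokens.
MISSING_GT_100MS = "missing_gt_100ms"
INVALID_AT_FLASH = "invalid_at_flash"
MIN_AFTER_1500MS = "min_after_1500ms"
VELOCITY_AFTER_750MS = "velocity_after_750ms"
ACCELERATION_AFTER_500MS = "acceleration_after_500ms"
WINDOW_INCOMPLETE = "window_incomplete"


@dataclass
class EyeTrace:
    """One eye's sampled pupil-diameter series for a single trial.

    ``diameter_mm`` holds NaN at missing samples; ``missing`` is the
    authoritative boolean mask. ``interpolated`` marks samples filled by
    :func:`interpolate_gaps`.
    """

    timestamps_ms: np.ndarray
    diameter_mm: np.ndarray
    missing: np.ndarray
    flash_onset_index: int
    sampling_rate_hz: float = 120.0
    eye: str = ""
    participant_id: str = ""
    trial_id: object = None
    interpolated: np.ndarray | None = None
    notes: tuple = ()

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = self.timestamps_ms.size
        if self.diameter_mm.size != n or self.missing.size != n:
            raise ValueError("timestamps, diameter and mask must have equal length")
        if n == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (0 <= self.flash_onset_index < n):
            raise ValueError("flash_onset_index out of bounds")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.timestamps_ms.size

    def window_bounds(self, width_ms: float) -> tuple[int, int]:
        """Inclusive index bounds of the half-open post-flash window
        (flash, flash + width]; the flash sample itself is excluded."""
        k = int(round(width_ms * self.sampling_rate_hz / 1000.0))
        return self.flash_onset_index + 1, self.flash_onset_index + k

    def time_after_flash_ms(self, index: int) -> float:
        return (index - self.flash_onset_index) * 1000.0 / self.sampling_rate_hz


@dataclass
class SmoothedTrace:
    """Smoothed diameter plus first and second derivatives of one trial.

    ``unreliable`` carries forward samples that were still missing after
    gap interpolation (long gaps outside the QC window); metric and
    screening windows must not contain such samples.
    """

    diameter_mm: np.ndarray
    velocity_mm_per_s: np.ndarray
    acceleration_mm_per_s2: np.ndarray
    source: EyeTrace
    unreliable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.source.n_samples
        for series in (self.diameter_mm, self.velocity_mm_per_s, self.acceleration_mm_per_s2):
            if np.asarray(series).size != n:
                raise ValueError("smoothed series must match source length")
        if self.unreliable is None:
            self.unreliable = np.zeros(n, dtype=bool)


@dataclass(frozen=True)
class TrialScreenResult:
    """Outcome of one screening stage for one eye-trial."""

    passed: bool
    failed_criteria: tuple
    stage: str  # "pre_smoothing" | "post_smoothing"
    flags: tuple = ()
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed must be equivalent to an empty failure list")


def screen_missing(trace: EyeTrace) -> TrialScreenResult:
    """First-stage inclusion screen on raw samples.

    Fails ``missing_gt_100ms`` when more than 100 ms worth of samples
    (12 at 120 Hz, inclusive bound: exactly 12 passes) are missing in
    the (flash, flash + 1500 ms] window, and ``invalid_at_flash`` when
    the flash-onset sample itself is missing.
    """
    lo, hi = trace.window_bounds(MISSING_WINDOW_MS)
    flags = []
    hi_avail = min(hi, trace.n_samples - 1)
    if hi_avail < hi:
        flags.append("qc_window_truncated")
    budget = int(round(MAX_MISSING_MS * trace.sampling_rate_hz / 1000.0))
    n_missing = int(trace.missing[lo : hi_avail + 1].sum())
    failed = []
    if n_missing > budget:
        failed.append(MISSING_GT_100MS)
    if trace.missing[trace.flash_onset_index]:
        failed.append(INVALID_AT_FLASH)
    return TrialScreenResult(
        passed=not failed,
        failed_criteria=tuple(failed),
        stage="pre_smoothing",
        flags=tuple(flags),
        details={"n_missing_in_window": n_missing, "missing_budget": budget},
    )


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of consecutive missing runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def interpolate_gaps(trace: EyeTrace, max_gap_samples: int = MAX_GAP_SAMPLES) -> EyeTrace:
    """Linearly interpolate short missing runs from flanking valid samples.

    Runs of length <= ``max_gap_samples`` are filled anywhere in the
    trace. Runs intersecting the metric region — the 200 ms pre-flash
    baseline window through the 1500 ms QC window — are filled
    regardless of length, because :func:`screen_missing` has already
    bounded the post-flash missingness and the pre-flash diameter is
    quasi-stationary; longer runs wholly outside that region stay
    missing and are excluded from metric search ranges downstream. Runs
    touching a trace boundary are filled by nearest-value extension and
    flagged.
    """
    if not trace.missing.any():
        return trace
    diameter = trace.diameter_mm.copy()
    missing = trace.missing.copy()
    interpolated = trace.interpolated.copy()
    notes = list(trace.notes)
    _, hi = trace.window_bounds(MISSING_WINDOW_MS)
    k_base = int(round(BASELINE_WINDOW_MS * trace.sampling_rate_hz / 1000.0))
    lo = max(trace.flash_onset_index - k_base, 0)
    valid_idx = np.flatnonzero(~trace.missing)
    if valid_idx.size == 0:
        raise ValueError("trace has no valid samples to interpolate from")
    for start, stop in _missing_runs(trace.missing):
        run_len = stop - start + 1
        in_qc = start <= hi and stop >= lo
        if run_len > max_gap_samples and not in_qc:
            continue
        left = start - 1
        right = stop + 1
        if left < 0 and right >= trace.n_samples:
            continue
        if left < 0:
            diameter[start : stop + 1] = trace.diameter_mm[right]
            notes.append("edge_gap_extended")
        elif right >= trace.n_samples:
            diameter[start : stop + 1] = trace.diameter_mm[left]
            notes.append("edge_gap_extended")
        else:
            xs = np.arange(start, stop + 1, dtype=float)
            diameter[start : stop + 1] = np.interp(
                xs, [float(left), float(right)],
                [trace.diameter_mm[left], trace.diameter_mm[right]],
            )
        missing[start : stop + 1] = False
        interpolated[start : stop + 1] = True
    return replace(
        trace,
        diameter_mm=diameter,
        missing=missing,
        interpolated=interpolated,
        notes=tuple(notes),
    )


def savitzky_golay(
    series: np.ndarray,
    window_samples: int = SG_WINDOW_SAMPLES,
    degree: int = SG_DEGREE,
    derivative_order: int = 0,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation.

    Each output sample is the requested derivative (scaled to per-second
    units by ``dt_s``) of the local least-squares polynomial fit over
    the centred window. Edges use mirror padding.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < window_samples:
        raise ValueError(f"series shorter than filter window ({x.size} < {window_samples})")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values; interpolate gaps first")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if derivative_order not in (0, 1, 2):
        raise ValueError("derivative_order must be 0, 1 or 2")
    return savgol_filter(
        x, window_length=window_samples, polyorder=degree,
        deriv=derivative_order, delta=dt_s, mode="mirror",
    )


def gaussian_kernel(sd_samples: float, truncate_sd: float = GAUSSIAN_TRUNCATE_SD) -> np.ndarray:
    """Discretized, renormalized Gaussian kernel (radius ``truncate_sd`` SDs)."""
    if sd_samples <= 0:
        raise ValueError("sd_samples must be positive")
    radius = int(truncate_sd * float(sd_samples) + 0.5)
    offsets = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (offsets / sd_samples) ** 2)
    return kernel / kernel.sum()


def gaussian_smooth(series: np.ndarray, sd_samples: float = GAUSSIAN_SD_SAMPLES) -> np.ndarray:
    """Convolve with a renormalized Gaussian kernel (mirror edges)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if sd_samples <= 0:
        raise ValueError("sd_samples must be positive")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    return gaussian_filter1d(x, sigma=float(sd_samples), mode="mirror",
                             truncate=GAUSSIAN_TRUNCATE_SD)


def smooth_trace(trace: EyeTrace) -> SmoothedTrace:
    """Produce smoothed diameter, velocity and acceleration series.

    Remaining long gaps (outside the QC window) are bridged by linear
    interpolation for filtering purposes only and kept marked as
    unreliable so downstream windows can refuse them.
    """
    d = trace.diameter_mm.copy()
    unreliable = trace.missing.copy()
    if unreliable.any():
        valid = np.flatnonzero(~unreliable)
        if valid.size == 0:
            raise ValueError("trace has no valid samples")
        d[unreliable] = np.interp(np.flatnonzero(unreliable).astype(float),
                                  valid.astype(float), d[valid])
    dt = 1.0 / trace.sampling_rate_hz
    diameter = gaussian_smooth(savitzky_golay(d, derivative_order=0))
    velocity = gaussian_smooth(savitzky_golay(d, derivative_order=1, dt_s=dt))
    acceleration = gaussian_smooth(savitzky_golay(d, derivative_order=2, dt_s=dt))
    return SmoothedTrace(
        diameter_mm=diameter,
        velocity_mm_per_s=velocity,
        acceleration_mm_per_s2=acceleration,
        source=trace,
        unreliable=unreliable,
    )


def _window_argmin(series: np.ndarray, lo: int, hi: int) -> int:
    """Earliest argmin of ``series[lo:hi+1]``, as an absolute index."""
    return lo + int(np.argmin(series[lo : hi + 1]))


def screen_curve(smoothed: SmoothedTrace) -> TrialScreenResult:
    """Second-stage screen on the smoothed curve shape.

    Locates the diameter minimum, most-negative velocity and
    most-negative acceleration over (flash, flash + 1500 ms] (earliest
    index on ties) and requires them within 1500, 750 and 500 ms of the
    flash. A diameter argmin pinned to the window edge while the series
    is still decreasing means the true minimum lies beyond 1500 ms and
    fails the first criterion. An incomplete search window (trace too
    short, or unresolved missing samples) fails with a flag.
    """
    trace = smoothed.source
    lo, hi = trace.window_bounds(MIN_TIMING_MS)
    if hi > trace.n_samples - 1 or bool(smoothed.unreliable[lo : hi + 1].any()):
        return TrialScreenResult(
            passed=False,
            failed_criteria=(MIN_AFTER_1500MS,),
            stage="post_smoothing",
            flags=(WINDOW_INCOMPLETE,),
        )
    failed = []
    i_min = _window_argmin(smoothed.diameter_mm, lo, hi)
    t_min = trace.time_after_flash_ms(i_min)
    edge_still_falling = (
        i_min == hi
        and i_min + 1 < trace.n_samples
        and smoothed.diameter_mm[i_min + 1] < smoothed.diameter_mm[i_min]
    )
    if t_min > MIN_TIMING_MS or edge_still_falling:
        failed.append(MIN_AFTER_1500MS)
    i_vel = _window_argmin(smoothed.velocity_mm_per_s, lo, hi)
    t_vel = trace.time_after_flash_ms(i_vel)
    if t_vel > VELOCITY_TIMING_MS:
        failed.append(VELOCITY_AFTER_750MS)
    i_acc = _window_argmin(smoothed.acceleration_mm_per_s2, lo, hi)
    t_acc = trace.time_after_flash_ms(i_acc)
    if t_acc > ACCELERATION_TIMING_MS:
        failed.append(ACCELERATION_AFTER_500MS)
    return TrialScreenResult(
        passed=not failed,
        failed_criteria=tuple(failed),
        stage="post_smoothing",
        details={"t_min_ms": t_min, "t_velocity_min_ms": t_vel, "t_acceleration_min_ms": t_acc},
    )
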