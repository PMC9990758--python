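import numpy as np
import pytest

from plrkit import preprocess as pp
from plrkit import simulate as sim


def local_quadratic_oracle(series: np.ndarray, derivative_order: int,
                           dt_s: float = 1.0, window: int = 11) -> np.ndarray:
    """Brute-force Savitzky-Golay oracle: explicit least-squares quadratic
    fit in each centred window, evaluated (with derivatives) at the centre.

    Independent of scipy's filter implementation; interior samples only
    (edges are returned as NaN).
    """
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    design = np.vander(x, 3, increasing=True)  # [1, x, x^2]
    out = np.full(series.size, np.nan)
    for i in range(half, series.size - half):
        coef, *_ = np.linalg.lstsq(design, series[i - half : i + half + 1], rcond=None)
        if derivative_order == 0:
            out[i] = coef[0]
        elif derivative_order == 1:
            out[i] = coef[1] / dt_s
        else:
            out[i] = 2.0 * coef[2] / dt_s**2
    return out


@pytest.fixture
def noiseless_params() -> sim.TrialSimParams:
    return sim.TrialSimParams(
        baseline_diameter_mm=5.0, min_diameter_mm=3.5, latency_ms=250.0,
        noise_sd_mm=0.0, blink_rate_per_trial=0.0,
    )


@pytest.fixture
def noiseless_trial(noiseless_params) -> sim.Trial:
    return sim.simulate_trial(noiseless_params, seed=0)


@pytest.fixture
def noiseless_smoothed(noiseless_trial) -> pp.SmoothedTrace:
    return pp.smooth_trace(noiseless_trial.left)


def make_trace(diameter: np.ndarray, flash_idx: int, missing=None,
               fs: float = 120.0) -> pp.EyeTrace:
    """Build an EyeTrace from a diameter array for QC tests."""
    diameter = np.asarray(diameter, dtype=float)
    n = diameter.size
    if missing is None:
        missing = np.zeros(n, dtype=bool)
    else:
        missing = np.asarray(missing, dtype=bool)
    d = diameter.copy()
    d[missing] = np.nan
    return pp.EyeTrace(
        timestamps_ms=np.arange(n) * 1000.0 / fs, diameter_mm=d,
        missing=missing, flash_onset_index=flash_idx, sampling_rate_hz=fs,
        eye="left",
    )
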