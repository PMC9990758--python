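"""Synthetic flash-locked pupil recordings with known ground truth.

The generator emulates the recording conditions of a 120 Hz binocular
eye-tracking PLR task: 6 s trials with a pre-flash fixation of 1.6, 2.0
or 2.4 s, a 120 ms white flash, a transient constriction from baseline
diameter A0 toward a minimum A_m, blink gaps, and measurement noise.
Cohort-level structure (age distributions, SRS-2 trait T-scores, and
trait-PLR correlations) is injected through a joint latent-normal model
so every downstream stage can be validated against known parameters.

The single-trial curve is a flat baseline followed, after a latency
``L``, by a bi-exponential transient

    d(t) = A0 - (A0 - A_m) * f(t - L),
    f(s) = (exp(-s / tau_r) - exp(-s / tau_c)) / f_peak,   s > 0,

normalized so the noiseless global minimum equals A_m exactly
(``tau_c`` < ``tau_r`` are the constriction and recovery time
constants). The velocity step at the latency kink makes the point of
most-negative acceleration a sharp, recoverable marker of constriction
onset, as in real PLR recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import EyeTrace

PRE_FLASH_CHOICES_MS = (1600.0, 2000.0, 2400.0)

TRAIT_SCALES = ("SRS2_Total_T", "SRS2_SCI_T", "SRS2_RRB_T")
PLR_PARAMS = ("baseline", "rel_amp", "latency")
LATENT_VARS = ("age",) + TRAIT_SCALES + PLR_PARAMS


@dataclass(frozen=True)
class TrialSimParams:
    """Generating parameters for a single two-eye trial."""

    baseline_diameter_mm: float = 5.0
    min_diameter_mm: float = 3.6
    latency_ms: float = 220.0
    constriction_tau_ms: float = 150.0
    recovery_tau_ms: float = 1500.0
    pre_flash_duration_ms: float = 2000.0
    flash_duration_ms: float = 120.0
    trial_duration_ms: float = 6000.0
    sampling_rate_hz: float = 120.0
    noise_sd_mm: float = 0.05
    blink_rate_per_trial: float = 1.0
    blink_gap_ms_range: tuple = (100.0, 300.0)

    def __post_init__(self) -> None:
        if self.baseline_diameter_mm <= 0:
            raise ValueError("baseline_diameter_mm must be positive")
        if not (0 < self.min_diameter_mm < self.baseline_diameter_mm):
            raise ValueError("min_diameter_mm must lie in (0, baseline)")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be non-negative")
        if self.constriction_tau_ms <= 0 or self.recovery_tau_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.constriction_tau_ms >= self.recovery_tau_ms:
            raise ValueError("constriction_tau_ms must be smaller than recovery_tau_ms")
        if self.pre_flash_duration_ms not in PRE_FLASH_CHOICES_MS:
            raise ValueError(f"pre_flash_duration_ms must be one of {PRE_FLASH_CHOICES_MS}")
        if self.pre_flash_duration_ms + self.flash_duration_ms >= self.trial_duration_ms:
            raise ValueError("pre-flash plus flash must fit inside the trial")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.noise_sd_mm < 0 or self.blink_rate_per_trial < 0:
            raise ValueError("noise and blink rate must be non-negative")
        lo, hi = self.blink_gap_ms_range
        if not (0 < lo <= hi):
            raise ValueError("blink_gap_ms_range must be a positive interval")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration_ms * self.sampling_rate_hz / 1000.0))

    @property
    def flash_onset_index(self) -> int:
        return int(round(self.pre_flash_duration_ms * self.sampling_rate_hz / 1000.0))


def plr_curve(time_since_flash_ms, params: TrialSimParams) -> np.ndarray:
    """Noiseless pupil diameter at times relative to flash onset (ms).

    Equals the baseline for t < latency; constricts toward
    ``min_diameter_mm`` and re-dilates toward baseline afterward. The
    global minimum equals ``min_diameter_mm`` by construction.
    """
    t = np.asarray(time_since_flash_ms, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("time values must be finite")
    tau_c, tau_r = params.constriction_tau_ms, params.recovery_tau_ms
    s_peak = math.log(tau_r / tau_c) * tau_c * tau_r / (tau_r - tau_c)
    f_peak = math.exp(-s_peak / tau_r) - math.exp(-s_peak / tau_c)
    s = t - params.latency_ms
    shape = np.zeros_like(s)
    post = s > 0
    with np.errstate(under="ignore"):
        shape[post] = (np.exp(-s[post] / tau_r) - np.exp(-s[post] / tau_c)) / f_peak
    depth = params.baseline_diameter_mm - params.min_diameter_mm
    return params.baseline_diameter_mm - depth * shape


@dataclass
class Trial:
    """A simulated two-eye trial plus its generating parameters."""

    left: EyeTrace
    right: EyeTrace
    params: TrialSimParams


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trial(params: TrialSimParams, seed=None,
                   participant_id: str = "", trial_id=None) -> Trial:
    """Simulate one two-eye trial.

    Both eyes share the noiseless curve and (binocular) blink gaps, with
    independent per-eye measurement noise. A seed (or Generator) is
    required whenever noise or blinks are enabled.
    """
    stochastic = params.noise_sd_mm > 0 or params.blink_rate_per_trial > 0
    if seed is None and stochastic:
        raise ValueError("a seed is required when noise or blinks are enabled")
    rng = _as_rng(seed if seed is not None else 0)
    n = params.n_samples
    fs = params.sampling_rate_hz
    t_ms = np.arange(n) * 1000.0 / fs
    flash_idx = params.flash_onset_index
    flash_ms = t_ms[flash_idx]
    curve = plr_curve(t_ms - flash_ms, params)

    eyes = {}
    for eye in ("left", "right"):
        d = curve.copy()
        if params.noise_sd_mm > 0:
            d = d + rng.normal(0.0, params.noise_sd_mm, size=n)
        eyes[eye] = d
    blink_mask = np.zeros(n, dtype=bool)
    if params.blink_rate_per_trial > 0:
        n_blinks = rng.poisson(params.blink_rate_per_trial)
        lo, hi = params.blink_gap_ms_range
        for _ in range(n_blinks):
            gap = rng.uniform(lo, hi)
            start = rng.uniform(0.0, max(params.trial_duration_ms - gap, 0.0))
            blink_mask |= (t_ms >= start) & (t_ms < start + gap)

    traces = {}
    for eye, d in eyes.items():
        diameter = d.copy()
        diameter[blink_mask] = np.nan
        traces[eye] = EyeTrace(
            timestamps_ms=t_ms.copy(),
            diameter_mm=diameter,
            missing=blink_mask.copy(),
            flash_onset_index=flash_idx,
            sampling_rate_hz=fs,
            eye=eye,
            participant_id=participant_id,
            trial_id=trial_id,
        )
    return Trial(left=traces["left"], right=traces["right"], params=params)


@dataclass(frozen=True)
class GroupSimConfig:
    """Per-group distributions for the latent cohort model.

    Ages use a Gaussian copula: children follow a truncated normal on
    ``age_range``; adults follow ``age_range[0]`` plus a gamma matched
    to the group mean/SD, giving the heavy right tail that produces
    occasional 3-SD age outliers. Trait scores are generated directly on
    the T-score scale. ``correlations`` lists pairwise latent
    correlations among ``age``, the three trait scales, and the PLR
    parameters ``baseline`` (A0, mm), ``rel_amp`` and ``latency`` (ms).
    """

    name: str
    n: int
    age_mean: float
    age_sd: float
    age_range: tuple
    age_model: str  # "truncnorm" | "shifted_gamma"
    baseline_mean_mm: float
    baseline_sd_mm: float
    rel_amp_mean: float
    rel_amp_sd: float
    latency_mean_ms: float
    latency_sd_ms: float
    trait_means: dict = field(default_factory=lambda: {s: 50.0 for s in TRAIT_SCALES})
    trait_sds: dict = field(default_factory=lambda: {s: 10.0 for s in TRAIT_SCALES})
    correlations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        for pair, r in self.correlations.items():
            a, b = pair
            if a not in LATENT_VARS or b not in LATENT_VARS:
                raise ValueError(f"unknown latent variable in pair {pair}")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation for {pair} outside [-1, 1]")

    def latent_correlation_matrix(self) -> np.ndarray:
        m = np.eye(len(LATENT_VARS))
        index = {v: i for i, v in enumerate(LATENT_VARS)}
        for (a, b), r in self.correlations.items():
            i, j = index[a], index[b]
            m[i, j] = m[j, i] = r
        eigmin = float(np.linalg.eigvalsh(m).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"latent correlation structure for group '{self.name}' is not "
                f"positive semi-definite (min eigenvalue {eigmin:.3e}); "
                "relax the target correlations"
            )
        return m


_TRAIT_TRAIT_DEFAULTS = {
    ("SRS2_Total_T", "SRS2_SCI_T"): 0.90,
    ("SRS2_Total_T", "SRS2_RRB_T"): 0.75,
    ("SRS2_SCI_T", "SRS2_RRB_T"): 0.50,
}


def default_child_group(n: int = 65) -> GroupSimConfig:
    corr = dict(_TRAIT_TRAIT_DEFAULTS)
    corr.update({
        ("age", "baseline"): 0.31,
        ("SRS2_RRB_T", "baseline"): -0.32,
        ("rel_amp", "latency"): -0.20,
    })
    return GroupSimConfig(
        name="child", n=n,
        age_mean=6.20, age_sd=2.68, age_range=(2.0, 12.0), age_model="truncnorm",
        baseline_mean_mm=5.5, baseline_sd_mm=0.8,
        rel_amp_mean=0.36, rel_amp_sd=0.07,
        latency_mean_ms=235.0, latency_sd_ms=30.0,
        correlations=corr,
    )


def default_adult_group(n: int = 77) -> GroupSimConfig:
    corr = dict(_TRAIT_TRAIT_DEFAULTS)
    corr.update({
        ("SRS2_Total_T", "rel_amp"): -0.28,
        ("SRS2_Total_T", "latency"): 0.21,
        ("SRS2_SCI_T", "rel_amp"): -0.21,
        ("SRS2_SCI_T", "latency"): 0.10,
        ("SRS2_RRB_T", "rel_amp"): -0.36,
        ("SRS2_RRB_T", "latency"): 0.32,
        ("rel_amp", "latency"): -0.40,
    })
    return GroupSimConfig(
        name="adult", n=n,
        age_mean=20.34, age_sd=4.67, age_range=(18.0, 46.0), age_model="shifted_gamma",
        baseline_mean_mm=4.64, baseline_sd_mm=0.8,
        rel_amp_mean=0.425, rel_amp_sd=0.07,
        latency_mean_ms=235.0, latency_sd_ms=30.0,
        correlations=corr,
    )


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level simulation settings.

    ``target_trait_plr_correlations`` maps (trait scale, PLR parameter)
    pairs to correlations and overrides the matching entries in both
    groups' latent structures.
    """

    child: GroupSimConfig = field(default_factory=default_child_group)
    adult: GroupSimConfig = field(default_factory=default_adult_group)
    trials_per_participant: int = 9
    noise_sd_mm: float = 0.05
    blink_rate_per_trial: float = 1.0
    blink_gap_ms_range: tuple = (100.0, 300.0)
    constriction_tau_ms: float = 150.0
    recovery_tau_ms: float = 1500.0
    rng_seed: int = 0
    target_trait_plr_correlations: dict | None = None

    def __post_init__(self) -> None:
        if self.trials_per_participant < 1:
            raise ValueError("trials_per_participant must be >= 1")
        if self.target_trait_plr_correlations:
            for group_name in ("child", "adult"):
                group = getattr(self, group_name)
                corr = dict(group.correlations)
                for (trait, plr), r in self.target_trait_plr_correlations.items():
                    if trait not in TRAIT_SCALES or plr not in PLR_PARAMS:
                        raise ValueError(f"unknown target pair ({trait}, {plr})")
                    corr[(trait, plr)] = r
                object.__setattr__(self, group_name, replace(group, correlations=corr))
        # Validate PSD eagerly so misconfiguration fails at construction.
        self.child.latent_correlation_matrix()
        self.adult.latent_correlation_matrix()

    @property
    def n_children(self) -> int:
        return self.child.n

    @property
    def n_adults(self) -> int:
        return self.adult.n


def _transform_age(z: np.ndarray, group: GroupSimConfig) -> np.ndarray:
    """Map standard-normal latents to the group's age distribution."""
    u = sps.norm.cdf(z)
    lo, hi = group.age_range
    if group.age_model == "truncnorm":
        a = (lo - group.age_mean) / group.age_sd
        b = (hi - group.age_mean) / group.age_sd
        return sps.truncnorm.ppf(u, a, b, loc=group.age_mean, scale=group.age_sd)
    if group.age_model == "shifted_gamma":
        mean_excess = group.age_mean - lo
        shape = (mean_excess / group.age_sd) ** 2
        scale = group.age_sd**2 / mean_excess
        return lo + sps.gamma.ppf(u, shape, scale=scale)
    raise ValueError(f"unknown age_model {group.age_model!r}")


def draw_group_table(group: GroupSimConfig, rng: np.random.Generator,
                     id_prefix: str = "") -> pd.DataFrame:
    """Draw one group's participant-level ground-truth table."""
    if group.n == 0:
        return pd.DataFrame(columns=["participant_id", "group", "age_years",
                                     *TRAIT_SCALES, "gt_baseline_mm", "gt_rel_amp",
                                     "gt_latency_ms", "gt_min_mm", "gt_abs_amp_mm"])
    corr = group.latent_correlation_matrix()
    z = rng.multivariate_normal(np.zeros(len(LATENT_VARS)), corr,
                                size=group.n, method="eigh")
    cols = {v: z[:, i] for i, v in enumerate(LATENT_VARS)}
    age = _transform_age(cols["age"], group)
    baseline = np.clip(group.baseline_mean_mm + group.baseline_sd_mm * cols["baseline"],
                       1.0, None)
    rel_amp = np.clip(group.rel_amp_mean + group.rel_amp_sd * cols["rel_amp"], 0.02, 0.90)
    latency = np.clip(group.latency_mean_ms + group.latency_sd_ms * cols["latency"],
                      60.0, 480.0)
    min_mm = baseline * np.sqrt(1.0 - rel_amp)
    prefix = id_prefix or group.name[0]
    table = pd.DataFrame({
        "participant_id": [f"{prefix}{i + 1:03d}" for i in range(group.n)],
        "group": group.name,
        "age_years": age,
    })
    for scale in TRAIT_SCALES:
        table[scale] = group.trait_means[scale] + group.trait_sds[scale] * cols[scale]
    table["gt_baseline_mm"] = baseline
    table["gt_rel_amp"] = rel_amp
    table["gt_latency_ms"] = latency
    table["gt_min_mm"] = min_mm
    table["gt_abs_amp_mm"] = baseline - min_mm
    return table


def draw_cohort_table(config: CohortSimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Participant-level ground truth for both groups (no trial traces)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    parts = [draw_group_table(config.child, rng, "c"),
             draw_group_table(config.adult, rng, "a")]
    non_empty = [p for p in parts if not p.empty]
    if not non_empty:
        return parts[0]
    return pd.concat(non_empty, ignore_index=True)


@dataclass
class CohortDataset:
    """Simulated cohort: ground-truth table plus per-participant trials."""

    participants: pd.DataFrame
    trials: dict  # participant_id -> list[Trial]
    config: CohortSimConfig

    @property
    def traits_table(self) -> pd.DataFrame:
        return self.participants[["participant_id", "group", "age_years",
                                  *TRAIT_SCALES]].copy()


def simulate_cohort(config: CohortSimConfig) -> CohortDataset:
    """Simulate the full cohort: ground-truth parameters and trial traces."""
    rng = np.random.default_rng(config.rng_seed)
    table = draw_cohort_table(config, rng)
    trials: dict[str, list[Trial]] = {}
    for row in table.itertuples(index=False):
        participant_trials = []
        for j in range(config.trials_per_participant):
            pre_flash = float(rng.choice(PRE_FLASH_CHOICES_MS))
            params = TrialSimParams(
                baseline_diameter_mm=float(row.gt_baseline_mm),
                min_diameter_mm=float(row.gt_min_mm),
                latency_ms=float(row.gt_latency_ms),
                constriction_tau_ms=config.constriction_tau_ms,
                recovery_tau_ms=config.recovery_tau_ms,
                pre_flash_duration_ms=pre_flash,
                noise_sd_mm=config.noise_sd_mm,
                blink_rate_per_trial=config.blink_rate_per_trial,
                blink_gap_ms_range=config.blink_gap_ms_range,
            )
            participant_trials.append(
                simulate_trial(params, rng, participant_id=row.participant_id,
                               trial_id=j + 1)
            )
        trials[row.participant_id] = participant_trials
    return CohortDataset(participants=table, trials=trials, config=config)
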