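#!/usr/bin/env python
"""Screen, smooth, and extract PLR metrics from the simulated recordings.

Reads scratch/data/samples.csv (written by 01_simulate_cohort.py),
applies both screening stages, extracts the four PLR metrics per eye and
trial, combines eyes, and aggregates to participant level. Writes
results/metrics.csv and results/exclusion_ledger.json and prints the
exclusion accounting.
"""

import json
from pathlib import Path

import pandas as pd

from plrkit.io import extract_cohort, read_samples

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    samples = ROOT / "scratch" / "data" / "samples.csv"
    if not samples.exists():
        raise SystemExit(f"{samples} missing; run analysis/01_simulate_cohort.py first")
    trials, problems = read_samples(samples)
    for problem in problems:
        print(f"warning: {problem}")

    metrics, ledger, _ = extract_cohort(trials)
    traits = pd.read_csv(ROOT / "results" / "traits.csv")
    metrics = metrics.merge(traits[["participant_id", "group"]], on="participant_id")

    results = ROOT / "results"
    metrics.to_csv(results / "metrics.csv", index=False)
    (results / "exclusion_ledger.json").write_text(
        json.dumps(ledger.to_dict(), indent=2) + "\n")

    included = metrics[metrics.included]
    print(f"eye-trials: {ledger.raw_eye_trials} raw, "
          f"{ledger.valid_eye_trials} valid "
          f"({ledger.failed_missing} >100 ms missing, "
          f"{ledger.failed_at_flash} missing at flash, "
          f"{ledger.failed_min_timing + ledger.failed_velocity_timing + ledger.failed_acceleration_timing} curve-shape failures)")
    print(f"participants included (>=4 valid trials): {len(included)}/{len(metrics)}; "
          f"mean valid trials {metrics.n_valid_trials.mean():.2f}")
    print(included.groupby("group")[["mean_baseline_mm", "mean_relative_amplitude",
                                     "median_latency_ms"]].mean().round(3))


if __name__ == "__main__":
    main()
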