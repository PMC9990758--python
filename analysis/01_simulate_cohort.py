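#!/usr/bin/env python
"""Simulate the study cohort and write its raw recordings.

Generates the default cohort — 65 children and 77 adults, nine 6 s
flash trials each at 120 Hz, with measurement noise and binocular blink
gaps — and writes the sample-level recordings (scratch/data/, large),
plus the participant trait table and the generating ground truth
(results/, small).
"""

from pathlib import Path

from plrkit import simulate as sim
from plrkit.io import write_samples, write_traits

ROOT = Path(__file__).resolve().parents[1]
SEED = 20230221


def main() -> None:
    cfg = sim.CohortSimConfig(rng_seed=SEED)
    dataset = sim.simulate_cohort(cfg)

    data_dir = ROOT / "scratch" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    write_samples(dataset.trials, data_dir / "samples.csv")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    write_traits(dataset.traits_table, results / "traits.csv")
    dataset.participants.to_csv(results / "ground_truth.csv", index=False)

    n_trials = sum(len(t) for t in dataset.trials.values())
    print(f"simulated {len(dataset.participants)} participants "
          f"({cfg.n_children} children, {cfg.n_adults} adults), "
          f"{n_trials} trials -> {data_dir / 'samples.csv'}")
    print(f"traits and ground truth -> {results}/")


if __name__ == "__main__":
    main()
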