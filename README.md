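# plrkit

A tested pipeline for **pupil light reflex (PLR)** analysis in
developmental/autonomic psychophysiology. The PLR — the transient pupil
constriction evoked by a brief light flash — is a standard index of
parasympathetic function, and its amplitude and latency are studied in
relation to autistic traits (SRS-2 T-scores) in children and adults.
`plrkit` provides everything needed to run and validate such an
analysis without access to human data:

* **`plrkit.simulate`** — flash-locked 120 Hz binocular pupil
  recordings (6 s trials, 1.6/2.0/2.4 s fixation, 120 ms flash) with
  measurement noise, binocular blink gaps, and a cohort-level
  latent-normal model that injects known trait-PLR correlations and
  group differences as ground truth.
* **`plrkit.preprocess`** — two-stage trial screening (≤ 100 ms missing
  in the 1500 ms post-flash window and a valid sample at the flash;
  diameter/velocity/acceleration minima within 1500/750/500 ms),
  blink-gap interpolation, and smoothing with a degree-2, 11-sample
  Savitzky-Golay filter followed by a Gaussian convolution (SD 5
  samples).
* **`plrkit.metrics`** — per-trial baseline diameter A₀, minimum
  diameter A_m, **relative constriction amplitude**
  (A₀² − A_m²)/A₀², **absolute amplitude** A₀ − A_m, and
  **constriction latency** (time from flash to maximum negative
  acceleration); eye averaging and participant aggregation with the
  ≥ 4-valid-trials rule (means, median for latency).
* **`plrkit.stats`** — single-pass 3-SD age-outlier exclusion,
  Pearson and age-partialled correlations, pooled-variance t-tests with
  Cohen's d, and Bonferroni families (critical p = 0.05/6 = 0.0083 for
  the six metric-metric pairs; 0.05/4 = 0.0125 for trait-metric and
  group-comparison families).
* **`plrkit.io` / `plrkit.cli`** — a plain-CSV sample dialect modeled
  on SMI-style exports, pipeline orchestration with a reconciling
  exclusion ledger, and a `plrkit` command with `simulate`, `extract`,
  `analyze`, and `pipeline` subcommands.

See `docs/methods.md` for the models, conventions, and limitations.

## Worked example

The `analysis/` scripts run the whole study on a simulated cohort of
65 children and 77 adults (nine trials each):

```bash
python analysis/01_simulate_cohort.py   # writes scratch/data/samples.csv (~50 MB)
python analysis/02_extract_metrics.py   # -> results/metrics.csv
python analysis/03_cohort_statistics.py # -> results/stats_report.{txt,json}
python analysis/04_monte_carlo_checks.py
```

With the default seed, step 02 prints:

```
eye-trials: 2556 raw, 1939 valid (570 >100 ms missing, 46 missing at flash, 1 curve-shape failures)
participants included (>=4 valid trials): 141/142; mean valid trials 6.83
       mean_baseline_mm  mean_relative_amplitude  median_latency_ms
group
adult             4.620                    0.426            228.070
child             5.426                    0.366            225.321
```

i.e. blinks cost about a quarter of all eye-trials, participants retain
~6.8 of 9 trials on average, children show larger baseline pupils and
adults stronger relative constriction — exactly the structure the
simulator injected. Step 03 then reports, among others:

```
analyzed groups: {'child': 65, 'adult': 73}; age outliers removed: {'child': 0, 'adult': 3}
  adult:SRS2_RRB_T~mean_relative_amplitude [bivariate]: stat=-0.377 df=71 p=0.0010 (critical 0.0125)
  adult_vs_child:mean_baseline_mm: stat=-5.991 df=136 p=0.0000 (critical 0.0125)
  adult_vs_child:mean_relative_amplitude: stat=5.508 df=136 p=0.0000 (critical 0.0125)
```

three adults are removed as 3-SD age outliers; higher adult RRB scores
go with weaker relative constriction (the injected r = −0.36 effect,
here estimated at −0.38 and surviving the 4-comparison Bonferroni
threshold); and the two group differences survive correction while
latency and absolute amplitude show none (none was injected). Step 04
confirms the statistical layer over 500 replicate n = 66 cohorts:

```
"mean_recovered_r": -0.3555, "power_at_corrected_threshold": 0.67,
"null_fwer_4_comparison_family": 0.054
```

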