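#!/usr/bin/env python
"""Run the cohort statistical plan on the extracted PLR metrics.

Applies the 3-SD age-outlier rule per group, then evaluates three
Bonferroni families: correlations among the four PLR metrics (critical
p = 0.05/6), SRS-2 trait vs PLR correlations (critical p = 0.05/4;
partial correlations controlling for age in children, bivariate in
adults), and four child-vs-adult t-tests with Cohen's d (critical
p = 0.05/4). Writes results/stats_report.{txt,json} and prints the
significant findings.
"""

from pathlib import Path

import pandas as pd

from plrkit.stats import run_analysis_plan

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    metrics = pd.read_csv(results / "metrics.csv")
    traits = pd.read_csv(results / "traits.csv")

    report = run_analysis_plan(metrics, traits)
    (results / "stats_report.json").write_text(report.to_json())
    (results / "stats_report.txt").write_text(report.to_text())

    frame = report.to_frame()
    print(f"analyzed groups: {report.group_ns}; "
          f"age outliers removed: { {g: len(v) for g, v in report.age_outliers.items()} }")
    significant = frame[frame.significant]
    print(f"\n{len(significant)} findings survive their family threshold:")
    for row in significant.itertuples():
        print(f"  {row.test_name}: stat={row.statistic:.3f} df={row.df} "
              f"p={row.p_value:.4f} (critical {row.critical_p:.4f})")
    trends = frame[frame.trend]
    print(f"\n{len(trends)} additional trend(s) (p < 0.10, not significant)")
    print(f"full tables -> {results / 'stats_report.txt'}")


if __name__ == "__main__":
    main()
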