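"""Cohort statistical plan: outlier screening, correlation families with
Bonferroni thresholds, and child-vs-adult group comparisons.

The plan mirrors a two-group (child/adult) psychophysiology design:

* a single-pass 3-SD age-outlier exclusion within each group;
* correlations among the four PLR metrics (6 pairs, Bonferroni
  critical p = alpha / 6), partial correlations controlling for age in
  children and bivariate Pearson correlations in adults;
* trait-PLR correlations (each SRS-2 scale against the four metrics,
  critical p = alpha / 4);
* four independent-samples pooled-variance t-tests comparing groups on
  the metrics (critical p = alpha / 4), with Cohen's d reported as
  adult minus child.

All p-values are two-sided; correlations use pairwise-complete
observations and every result records its effective n. Results with
p < 0.10 that miss the corrected threshold are flagged as trends but
never counted as significant.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

TREND_P = 0.10

PUPIL_METRIC_COLUMNS = (
    "mean_baseline_mm",
    "mean_relative_amplitude",
    "mean_absolute_amplitude_mm",
    "median_latency_ms",
)
TRAIT_COLUMNS = ("SRS2_Total_T", "SRS2_SCI_T", "SRS2_RRB_T")


@dataclass(frozen=True)
class StatsResult:
    """One test's outcome, with its family-wise threshold applied."""

    test_name: str
    family: str
    statistic: float
    df: int
    p_value: float
    effect_size: float
    effect_size_kind: str  # "r" | "d"
    n: int
    critical_p: float
    significant: bool
    trend: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.effect_size_kind == "r" and abs(self.effect_size) > 1.0 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        if self.df < 1:
            raise ValueError("df must be >= 1")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise critical p-value alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if int(m) != m or m < 1:
        raise ValueError("number of comparisons must be a positive integer")
    return alpha / m


def age_outlier_mask(ages, k_sd: float = 3.0) -> np.ndarray:
    """Inclusion mask: True where |age - mean| <= k_sd * SD.

    Mean and sample SD come from the full group in a single pass (no
    iterative re-computation); 'more than k SDs' is strict, so a value
    exactly at mean + k*SD stays included. Zero SD excludes nobody.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValueError("need at least two ages")
    sd = float(np.std(ages, ddof=1))
    if sd == 0.0:
        return np.ones(ages.size, dtype=bool)
    return np.abs(ages - ages.mean()) <= k_sd * sd


def _finish_correlation(r: float, df: int, n: int, test_name: str, family: str,
                        critical_p: float) -> StatsResult:
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatsResult(
        test_name=test_name, family=family, statistic=r, df=df, p_value=p,
        effect_size=r, effect_size_kind="r", n=n, critical_p=critical_p,
        significant=p < critical_p, trend=(critical_p <= p < TREND_P),
    )


def pearson(x, y, test_name: str = "pearson", family: str = "",
            critical_p: float = 0.05) -> StatsResult:
    """Bivariate Pearson correlation; df = n - 2, two-sided p via the
    t transform. Complete pairs only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return _finish_correlation(r, n - 2, n, test_name, family, critical_p)


def partial_pearson(x, y, covariate, test_name: str = "partial_pearson",
                    family: str = "", critical_p: float = 0.05) -> StatsResult:
    """First-order partial correlation controlling for one covariate.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    with df = n - 3 and a two-sided p via the t transform. Complete
    triples only; a covariate collinear with either variable is
    rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    for v in (x, y, z):
        if np.std(v) == 0.0:
            raise ValueError("correlation undefined: zero variance")
    c = np.corrcoef(np.vstack([x, y, z]))
    r_xy, r_xz, r_yz = c[0, 1], c[0, 2], c[1, 2]
    if min(1.0 - r_xz * r_xz, 1.0 - r_yz * r_yz) <= 1e-12:
        raise ValueError("covariate is collinear with a variable")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return _finish_correlation(float(r), n - 3, n, test_name, family, critical_p)


def independent_t(group_a, group_b, test_name: str = "independent_t",
                  family: str = "", critical_p: float = 0.05) -> StatsResult:
    """Pooled-variance Student's t-test with Cohen's d (A minus B)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / df
    if pooled_var == 0.0:
        raise ValueError("zero pooled variance")
    t_stat, p = sps.ttest_ind(a, b, equal_var=True)
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    p = float(p)
    return StatsResult(
        test_name=test_name, family=family, statistic=float(t_stat), df=df,
        p_value=p, effect_size=d, effect_size_kind="d", n=a.size + b.size,
        critical_p=critical_p, significant=p < critical_p,
        trend=(critical_p <= p < TREND_P),
    )


@dataclass(frozen=True)
class AnalysisPlan:
    """Configuration of the statistical plan."""

    alpha: float = 0.05
    outlier_sd_threshold: float = 3.0
    family_sizes: dict = field(default_factory=lambda: {
        "pupil_pupil": 6, "trait_pupil": 4, "group_comparison": 4,
    })
    child_group: str = "child"
    adult_group: str = "adult"
    age_column: str = "age_years"
    metric_columns: tuple = PUPIL_METRIC_COLUMNS
    trait_columns: tuple = TRAIT_COLUMNS

    def critical_p(self, family: str) -> float:
        return bonferroni_threshold(self.alpha, self.family_sizes[family])


@dataclass
class AnalysisReport:
    """Structured output of :func:`run_analysis_plan`."""

    results: tuple
    group_ns: dict
    age_outliers: dict  # group -> excluded participant ids
    orphan_ids: dict
    notes: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def to_dict(self) -> dict:
        return {
            "results": [r.__dict__ for r in self.results],
            "group_ns": self.group_ns,
            "age_outliers": {g: list(ids) for g, ids in self.age_outliers.items()},
            "orphan_ids": {k: list(v) for k, v in self.orphan_ids.items()},
            "notes": list(self.notes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = ["PLR cohort statistics", "=" * 60]
        for g, n in sorted(self.group_ns.items()):
            excluded = len(self.age_outliers.get(g, []))
            lines.append(f"group {g}: n = {n} analyzed ({excluded} age outlier(s) removed)")
        lines.append("")
        header = (f"{'test':<58} {'fam':<14} {'stat':>7} {'df':>4} "
                  f"{'p':>8} {'eff':>7} {'n':>4}  verdict")
        lines.append(header)
        lines.append("-" * len(header))
        for r in self.results:
            verdict = "SIG" if r.significant else ("trend" if r.trend else "ns")
            lines.append(
                f"{r.test_name:<58} {r.family:<14} {r.statistic:>7.3f} {r.df:>4d} "
                f"{r.p_value:>8.4f} {r.effect_size:>7.3f} {r.n:>4d}  {verdict}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def _group_correlation(sub: pd.DataFrame, xcol: str, ycol: str, partial: bool,
                       age_col: str, test_name: str, family: str,
                       critical_p: float) -> StatsResult:
    if partial:
        return partial_pearson(sub[xcol], sub[ycol], sub[age_col],
                               test_name=test_name, family=family,
                               critical_p=critical_p)
    return pearson(sub[xcol], sub[ycol], test_name=test_name, family=family,
                   critical_p=critical_p)


def run_analysis_plan(metrics: pd.DataFrame, traits: pd.DataFrame,
                      plan: AnalysisPlan | None = None) -> AnalysisReport:
    """Run the full statistical plan on a participant metrics table and
    a trait table, both keyed by ``participant_id``.

    Only participants marked ``included`` (>= 4 valid trials) enter;
    each group is cleaned with the single-pass 3-SD age rule; families
    are evaluated with their Bonferroni thresholds. Missing trait
    scores are handled pairwise-complete, with effective n recorded per
    test.
    """
    if plan is None:
        plan = AnalysisPlan()
    metric_ids = set(metrics["participant_id"])
    trait_ids = set(traits["participant_id"])
    orphans = {
        "metrics_only": sorted(metric_ids - trait_ids),
        "traits_only": sorted(trait_ids - metric_ids),
    }
    overlap = (set(metrics.columns) & set(traits.columns)) - {"participant_id"}
    merged = metrics.drop(columns=sorted(overlap)).merge(
        traits, on="participant_id", how="inner")
    if "included" in merged.columns:
        merged = merged[merged["included"].astype(bool)]
    merged = merged.sort_values("participant_id").reset_index(drop=True)

    notes: list[str] = []
    results: list[StatsResult] = []
    group_ns: dict[str, int] = {}
    age_outliers: dict[str, list[str]] = {}
    kept_groups: dict[str, pd.DataFrame] = {}
    for group_name in (plan.child_group, plan.adult_group):
        sub = merged[merged["group"] == group_name]
        if sub.empty:
            continue
        if len(sub) >= 2:
            mask = age_outlier_mask(sub[plan.age_column].to_numpy(),
                                    plan.outlier_sd_threshold)
        else:
            mask = np.ones(len(sub), dtype=bool)
        age_outliers[group_name] = sub.loc[~mask, "participant_id"].tolist()
        sub = sub.loc[mask]
        kept_groups[group_name] = sub
        group_ns[group_name] = len(sub)

    def add(builder, *args, **kwargs):
        try:
            results.append(builder(*args, **kwargs))
        except ValueError as exc:
            notes.append(f"{kwargs.get('test_name', builder.__name__)}: skipped ({exc})")

    # (b) correlations among the four pupil metrics (6 pairs per group).
    crit = plan.critical_p("pupil_pupil")
    for group_name, sub in kept_groups.items():
        partial = group_name == plan.child_group
        mode = "partial|age" if partial else "bivariate"
        for xcol, ycol in itertools.combinations(plan.metric_columns, 2):
            add(_group_correlation, sub, xcol, ycol, partial, plan.age_column,
                test_name=f"{group_name}:{xcol}~{ycol} [{mode}]",
                family="pupil_pupil", critical_p=crit)

    # (c) trait-PLR correlations (one 4-test family per trait scale).
    crit = plan.critical_p("trait_pupil")
    for group_name, sub in kept_groups.items():
        partial = group_name == plan.child_group
        mode = "partial|age" if partial else "bivariate"
        for trait in plan.trait_columns:
            for metric_col in plan.metric_columns:
                add(_group_correlation, sub, trait, metric_col, partial,
                    plan.age_column,
                    test_name=f"{group_name}:{trait}~{metric_col} [{mode}]",
                    family="trait_pupil", critical_p=crit)

    # (d) group comparisons on the four metrics (adult minus child).
    child = kept_groups.get(plan.child_group)
    adult = kept_groups.get(plan.adult_group)
    if child is not None and adult is not None and len(child) >= 2 and len(adult) >= 2:
        crit = plan.critical_p("group_comparison")
        for metric_col in plan.metric_columns:
            add(independent_t,
                adult[metric_col].to_numpy(), child[metric_col].to_numpy(),
                test_name=f"adult_vs_child:{metric_col}",
                family="group_comparison", critical_p=crit)
    elif not kept_groups:
        notes.append("no analyzable participants; statistics skipped")

    return AnalysisReport(results=tuple(results), group_ns=group_ns,
                          age_outliers=age_outliers, orphan_ids=orphans,
                          notes=tuple(notes))
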