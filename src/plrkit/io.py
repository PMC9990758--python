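"""File formats, pipeline orchestration, and exclusion accounting.

The sample-file dialect is a plain comma-delimited table modeled on an
SMI iView-style export after one conversion step: one row per sample
with columns ``participant_id, trial_id, timestamp_ms,
left_diameter_mm, right_diameter_mm, event``. Missing pupil samples are
empty fields; exactly one ``flash_onset`` event row marks the flash in
each trial. Timestamps are milliseconds from trial start.

``run_pipeline`` executes screen -> interpolate -> smooth -> screen ->
metrics -> aggregate -> statistics and reconciles an exclusion ledger:
every raw eye-trial ends in exactly one bucket (first failing criterion
wins), so the failure categories plus valid eye-trials always sum to
the raw count.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, preprocess as pp
from .metrics import (EyeExtraction, aggregate_participant, combine_eyes,
                      extract_eye_metrics, participant_table)
from .preprocess import EyeTrace
from .simulate import TRAIT_SCALES, CohortSimConfig, Trial, simulate_cohort
from .stats import AnalysisPlan, run_analysis_plan

logger = logging.getLogger("plrkit")

SAMPLE_COLUMNS = ("participant_id", "trial_id", "timestamp_ms",
                  "left_diameter_mm", "right_diameter_mm", "event")
TRAITS_COLUMNS = ("participant_id", "group", "age_years", *TRAIT_SCALES)


@dataclass(frozen=True)
class SampleFileDialect:
    """Tabular dialect for sample-level eye-tracker exports."""

    delimiter: str = ","
    missing_token: str = ""
    flash_event: str = "flash_onset"
    none_event: str = ""
    sampling_rate_hz: float = 120.0


@dataclass
class ExclusionLedger:
    """Counts of eye-trials lost at each processing stage."""

    raw_eye_trials: int = 0
    failed_missing: int = 0
    failed_at_flash: int = 0
    failed_min_timing: int = 0
    failed_velocity_timing: int = 0
    failed_acceleration_timing: int = 0
    valid_eye_trials: int = 0
    participants_excluded_lt4: int = 0
    age_outliers: int = 0

    _FAILURE_FIELDS = ("failed_missing", "failed_at_flash", "failed_min_timing",
                       "failed_velocity_timing", "failed_acceleration_timing")

    def check_consistency(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative count for {f.name}")
        total = self.valid_eye_trials + sum(getattr(self, f) for f in self._FAILURE_FIELDS)
        if total != self.raw_eye_trials:
            raise ValueError(
                f"ledger does not reconcile: {total} categorized vs "
                f"{self.raw_eye_trials} raw eye-trials"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def record(self, extraction: EyeExtraction) -> None:
        """Categorize one eye-trial by its first failing criterion."""
        self.raw_eye_trials += 1
        pre = extraction.screen_pre
        if not pre.passed:
            if pp.MISSING_GT_100MS in pre.failed_criteria:
                self.failed_missing += 1
            else:
                self.failed_at_flash += 1
            return
        post = extraction.screen_post
        if post is not None and not post.passed:
            if pp.MIN_AFTER_1500MS in post.failed_criteria:
                self.failed_min_timing += 1
            elif pp.VELOCITY_AFTER_750MS in post.failed_criteria:
                self.failed_velocity_timing += 1
            else:
                self.failed_acceleration_timing += 1
            return
        if extraction.valid:
            self.valid_eye_trials += 1
        else:
            # Extracted but degenerate (e.g. flat acceleration): count
            # with the acceleration-timing failures.
            self.failed_acceleration_timing += 1


def _format_value(value: float, missing: bool, token: str) -> str:
    return token if missing else repr(float(value))


def write_samples(trials, path, dialect: SampleFileDialect | None = None) -> None:
    """Write per-trial two-eye traces in the sample-file dialect.

    ``trials`` maps participant id to a list of :class:`Trial` objects
    (or (left, right) EyeTrace pairs).
    """
    dialect = dialect or SampleFileDialect()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(SAMPLE_COLUMNS)
        for pid in trials:
            for trial_no, trial in enumerate(trials[pid], start=1):
                left, right = (trial.left, trial.right) if isinstance(trial, Trial) else trial
                tid = left.trial_id if left.trial_id is not None else trial_no
                for i in range(left.n_samples):
                    event = (dialect.flash_event if i == left.flash_onset_index
                             else dialect.none_event)
                    writer.writerow([
                        pid, tid, repr(float(left.timestamps_ms[i])),
                        _format_value(left.diameter_mm[i], bool(left.missing[i]),
                                      dialect.missing_token),
                        _format_value(right.diameter_mm[i], bool(right.missing[i]),
                                      dialect.missing_token),
                        event,
                    ])


def read_samples(path, dialect: SampleFileDialect | None = None):
    """Parse a sample file into per-trial (left, right) EyeTrace pairs.

    Returns ``(trials, problems)`` where ``trials`` maps participant id
    to an ordered list of :class:`Trial`-like pairs and ``problems``
    lists rejected trials with diagnostics (zero/multiple flash events,
    non-monotone timestamps). Malformed rows are reported with line
    numbers.
    """
    dialect = dialect or SampleFileDialect()
    groups: dict[tuple, dict] = {}
    problems: list[str] = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        header = next(reader, None)
        if header is None or tuple(header) != SAMPLE_COLUMNS:
            raise ValueError(f"unexpected header {header!r}; expected {SAMPLE_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(SAMPLE_COLUMNS):
                problems.append(f"line {lineno}: wrong field count ({len(row)})")
                continue
            pid, tid, ts, left, right, event = row
            key = (pid, tid)
            entry = groups.setdefault(key, {"t": [], "l": [], "r": [], "ev": []})
            try:
                entry["t"].append(float(ts))
            except ValueError:
                problems.append(f"line {lineno}: bad timestamp {ts!r}")
                entry["t"].append(np.nan)
            for tag, text in (("l", left), ("r", right)):
                if text == dialect.missing_token:
                    entry[tag].append(np.nan)
                else:
                    try:
                        entry[tag].append(float(text))
                    except ValueError:
                        problems.append(f"line {lineno}: bad diameter {text!r}")
                        entry[tag].append(np.nan)
            entry["ev"].append(event)

    trials: dict[str, list] = {}
    for (pid, tid), entry in groups.items():
        t = np.asarray(entry["t"], dtype=float)
        events = entry["ev"]
        flash_rows = [i for i, ev in enumerate(events) if ev == dialect.flash_event]
        if len(flash_rows) != 1:
            problems.append(
                f"trial ({pid}, {tid}): expected exactly one "
                f"{dialect.flash_event!r} event, found {len(flash_rows)}; trial rejected"
            )
            continue
        if not np.isfinite(t).all() or np.any(np.diff(t) <= 0):
            problems.append(f"trial ({pid}, {tid}): non-monotone or invalid "
                            "timestamps; trial rejected")
            continue
        pair = []
        for tag, eye in (("l", "left"), ("r", "right")):
            d = np.asarray(entry[tag], dtype=float)
            pair.append(EyeTrace(
                timestamps_ms=t.copy(), diameter_mm=d, missing=np.isnan(d),
                flash_onset_index=flash_rows[0],
                sampling_rate_hz=dialect.sampling_rate_hz,
                eye=eye, participant_id=pid, trial_id=tid,
            ))
        trials.setdefault(pid, []).append(tuple(pair))
    return trials, problems


def write_traits(traits: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    traits.to_csv(path, index=False, columns=list(TRAITS_COLUMNS))


def read_traits(path) -> pd.DataFrame:
    traits = pd.read_csv(path)
    missing = set(TRAITS_COLUMNS) - set(traits.columns)
    if missing:
        raise ValueError(f"traits table missing columns: {sorted(missing)}")
    return traits


def extract_cohort(trials) -> tuple[pd.DataFrame, ExclusionLedger, list]:
    """Run per-eye extraction and participant aggregation over a cohort.

    ``trials`` maps participant id to a list of :class:`Trial` objects
    or (left, right) pairs. Returns the participant metrics table, the
    exclusion ledger, and the per-participant aggregates.
    """
    ledger = ExclusionLedger()
    records = []
    for pid in trials:
        combined_trials = []
        for trial in trials[pid]:
            left, right = (trial.left, trial.right) if isinstance(trial, Trial) else trial
            ext_l = extract_eye_metrics(left)
            ext_r = extract_eye_metrics(right)
            ledger.record(ext_l)
            ledger.record(ext_r)
            if ext_l.valid or ext_r.valid:
                combined_trials.append(combine_eyes(ext_l.metrics, ext_r.metrics))
            logger.debug("trial (%s, %s): left=%s right=%s", pid, left.trial_id,
                         ext_l.valid, ext_r.valid)
        record = aggregate_participant(combined_trials, participant_id=pid)
        if not record.included:
            ledger.participants_excluded_lt4 += 1
        records.append(record)
    ledger.check_consistency()
    return participant_table(records), ledger, records


def _config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with Path(source).open() as fh:
        return yaml.safe_load(fh) or {}


def _simulation_config(section: dict, seed=None) -> CohortSimConfig:
    from . import simulate as sim

    kwargs = dict(section)
    child_over = kwargs.pop("child", {}) or {}
    adult_over = kwargs.pop("adult", {}) or {}
    targets = kwargs.pop("target_trait_plr_correlations", None)
    if targets:
        targets = {tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
                   for k, v in targets.items()}
    if seed is not None:
        kwargs["rng_seed"] = int(seed)
    child = replace(sim.default_child_group(), **child_over)
    adult = replace(sim.default_adult_group(), **adult_over)
    return CohortSimConfig(child=child, adult=adult,
                           target_trait_plr_correlations=targets, **kwargs)


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    traits: pd.DataFrame
    report: object
    ledger: ExclusionLedger
    out_dir: Path
    provenance: dict = field(default_factory=dict)


def run_pipeline(config, out_dir, seed=None,
                 plan: AnalysisPlan | None = None) -> PipelineResult:
    """Execute the full pipeline from a config mapping (or YAML path).

    The config either carries a ``simulate`` section (cohort simulation
    settings) or an ``inputs`` section with ``samples`` and ``traits``
    paths. Outputs written to ``out_dir``: ``metrics.csv``,
    ``exclusion_ledger.json``, ``stats_report.json``,
    ``stats_report.txt`` and ``provenance.yaml``.
    """
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if "simulate" in config:
        sim_config = _simulation_config(config["simulate"] or {}, seed=seed)
        dataset = simulate_cohort(sim_config)
        trials = dataset.trials
        traits = dataset.traits_table
        dataset.participants.to_csv(out_dir / "ground_truth.csv", index=False)
        if config.get("write_samples", False):
            write_samples(trials, out_dir / "samples.csv")
    elif "inputs" in config:
        inputs = config["inputs"]
        trials, problems = read_samples(inputs["samples"])
        for problem in problems:
            logger.warning("read_samples: %s", problem)
        traits = read_traits(inputs["traits"])
    else:
        raise ValueError("config must contain a 'simulate' or 'inputs' section")

    metrics, ledger, _ = extract_cohort(trials)
    metrics = metrics.merge(traits[["participant_id", "group"]],
                            on="participant_id", how="left")
    metrics.to_csv(out_dir / "metrics.csv", index=False)

    analyzable = metrics[metrics["included"]] if not metrics.empty else metrics
    if analyzable.empty:
        report = None
        (out_dir / "stats_report.txt").write_text(
            "no participants passed quality control; statistics skipped\n")
    else:
        report = run_analysis_plan(metrics, traits, plan=plan)
        ledger.age_outliers = sum(len(v) for v in report.age_outliers.values())
        (out_dir / "stats_report.json").write_text(report.to_json())
        (out_dir / "stats_report.txt").write_text(report.to_text())
    ledger.check_consistency()
    (out_dir / "exclusion_ledger.json").write_text(
        json.dumps(ledger.to_dict(), indent=2) + "\n")

    provenance = {
        "plrkit_version": __version__,
        "seed": seed,
        "config_sha256_16": _config_hash(config),
    }
    (out_dir / "provenance.yaml").write_text(yaml.safe_dump(provenance))
    logger.info("pipeline complete: %s", ledger.to_dict())
    return PipelineResult(metrics=metrics, traits=traits, report=report,
                          ledger=ledger, out_dir=out_dir, provenance=provenance)
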