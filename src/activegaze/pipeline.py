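"""End-to-end orchestration: simulate -> synchronize -> detect -> assign ->
metrics -> stats, as one reproducible run.

A run either simulates a fresh experiment or loads a directory tree in the
simulator's on-disk layout, then produces:

* ``metrics.csv`` — one row per trial with every factor and measure;
* ``stats.json`` — repeated-measures ANOVA results per measure x factor
  plus the binomial mixed model for accuracy;
* ``report.md`` — a markdown summary (measure x factor table);
* stage-level log counts (samples read, dropped, fixations, labels).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assignment import AssignmentConfig, label_trial
from .errors import ActiveGazeError, MissingDesignError, DegenerateDesignError
from .fixations import FixationDetectorConfig, detect_fixations, write_fixations_csv
from .metrics import TrialRecord, metrics_table, summarize_trial
from .simulate import BehaviorParams, TrialSim, generate_design, simulate_experiment
from .stats import AnalysisConfig, EffectResult, fit_accuracy_model, learning_blocks, rm_anova
from .stimuli import load_instances
from .streams import read_streams, read_trial_json, synchronize

__all__ = ["RunConfig", "RunReport", "run_pipeline", "analyze_sim", "analyze_trial_dir",
           "analyze_directory", "stats_report", "load_config"]

log = logging.getLogger(__name__)

#: continuous measures analyzed factor-by-factor with RM ANOVA
DEFAULT_MEASURES = ["response_time_s", "n_fix_obj", "head_path_m", "primary_share"]
DEFAULT_FACTORS = ["complexity", "start_position", "orientation_diff", "same", "block", "correct"]


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "load"
    seed: int = 0
    n_subjects: int = 8
    n_trials: int = 18
    outdir: str = "run_out"
    data_dir: str | None = None  # for load mode
    detector: FixationDetectorConfig = field(default_factory=FixationDetectorConfig)
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    min_step: float = 0.002
    split_on_environment: bool = False
    measures: list = field(default_factory=lambda: list(DEFAULT_MEASURES))
    factors: list = field(default_factory=lambda: list(DEFAULT_FACTORS))


@dataclass
class RunReport:
    metrics_path: Path
    stats_path: Path
    report_path: Path
    n_trials: int
    n_fixations: int
    metrics: pd.DataFrame
    stats: dict


def analyze_sim(sim: TrialSim, detector: FixationDetectorConfig | None = None,
                assignment: AssignmentConfig | None = None, *,
                min_step: float = 0.002, split_on_environment: bool = False):
    """In-memory analysis of one simulated trial.

    Returns ``(record, labelled fixations, metrics)``.
    """
    synced = synchronize(sim.head, sim.gaze)
    fixes = detect_fixations(synced, detector)
    fixes = label_trial(fixes, sim.instances, assignment)
    m = summarize_trial(sim.record, fixes, sim.head, min_step=min_step,
                        split_on_environment=split_on_environment)
    return sim.record, fixes, m


def analyze_trial_dir(tdir: Path, detector: FixationDetectorConfig | None = None,
                      assignment: AssignmentConfig | None = None, *,
                      min_step: float = 0.002, split_on_environment: bool = False):
    """Analyze one trial directory (head.csv / gaze.csv / objects.json /
    trial.json)."""
    head, gaze = read_streams(tdir / "head.csv", tdir / "gaze.csv")
    instances = tuple(load_instances(tdir / "objects.json"))
    tj = read_trial_json(tdir / "trial.json")
    record = TrialRecord(
        subject_id=tj["subject_id"],
        trial_index=int(tj["trial_index"]),
        complexity=tj["complexity"],
        start_position=tj["start_position"],
        orientation_diff=int(tj["orientation_diff_deg"]),
        same=bool(tj["same"]),
        answer=tj["answer"],
        answer_time=float(tj["answer_time_s"]),
    )
    synced = synchronize(head, gaze)
    fixes = detect_fixations(synced, detector)
    fixes = label_trial(fixes, instances, assignment)
    m = summarize_trial(record, fixes, head, min_step=min_step,
                        split_on_environment=split_on_environment)
    return record, fixes, head, m


def analyze_directory(data_dir: Path, cfg: RunConfig) -> tuple[pd.DataFrame, int]:
    """Analyze every trial listed in the manifest; returns (table, n_fix)."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    records, all_metrics = [], []
    n_fix_total = 0
    out_fix_dir = Path(cfg.outdir) / "fixations"
    out_fix_dir.mkdir(parents=True, exist_ok=True)
    for entry in manifest["trials"]:
        tdir = data_dir / entry["dir"]
        record, fixes, head, m = analyze_trial_dir(
            tdir, cfg.detector, cfg.assignment,
            min_step=cfg.min_step, split_on_environment=cfg.split_on_environment,
        )
        write_fixations_csv(out_fix_dir / f"{entry['dir']}.csv", fixes)
        n_fix_total += len(fixes)
        records.append(record)
        all_metrics.append(m)
    log.info("analyzed %d trials, %d fixations", len(records), n_fix_total)
    return metrics_table(records, all_metrics), n_fix_total


def stats_report(metrics: pd.DataFrame, cfg: AnalysisConfig | None = None,
                 measures: list | None = None, factors: list | None = None) -> dict:
    """All factor tests for every measure, plus the accuracy mixed model.

    Factors that break the repeated-measures design (a subject missing a
    level, or no residual variance) yield a flagged entry instead of a
    result — never silent imputation.
    """
    cfg = cfg or AnalysisConfig()
    measures = measures or DEFAULT_MEASURES
    factors = factors or DEFAULT_FACTORS
    df = metrics.copy()
    df["block"] = learning_blocks(df["trial_index"].to_numpy(), cfg.n_trials, cfg.n_blocks)
    out: dict = {"anova": {}, "accuracy_glmm": []}
    for dv in measures:
        out["anova"][dv] = []
        sub = df[df[dv].notna()]
        for factor in factors:
            try:
                res = rm_anova(sub, dv, factor, alpha=cfg.alpha,
                               gg_correction=cfg.gg_correction)
                out["anova"][dv].append(dataclasses.asdict(res))
            except (MissingDesignError, DegenerateDesignError) as exc:
                out["anova"][dv].append(
                    {"effect": factor, "statistic": None, "p_value": None,
                     "significant": None, "warning": str(exc)}
                )
    glmm_factors = [f for f in factors if f != "correct"]
    for res in fit_accuracy_model(df, factors=glmm_factors, alpha=cfg.alpha):
        out["accuracy_glmm"].append(dataclasses.asdict(res))
    return out


def _markdown_report(stats: dict, metrics: pd.DataFrame) -> str:
    lines = ["# Run report", "", f"Trials analyzed: {len(metrics)}", ""]
    lines += ["## Accuracy (binomial mixed model, subject random intercept)", "",
              "| effect | chi2 | df | p | significant |", "|---|---|---|---|---|"]
    for r in stats["accuracy_glmm"]:
        stat = "" if r["statistic"] is None or not np.isfinite(r["statistic"]) else f"{r['statistic']:.3f}"
        p = "" if r["p_value"] is None or not np.isfinite(r["p_value"]) else f"{r['p_value']:.4g}"
        lines.append(f"| {r['effect']} | {stat} | {r['df_num']} | {p} | {r['significant']} |")
    lines.append("")
    for dv, results in stats["anova"].items():
        lines += [f"## {dv} (repeated-measures ANOVA)", "",
                  "| factor | F | df | p | significant |", "|---|---|---|---|---|"]
        for r in results:
            if r.get("statistic") is None:
                lines.append(f"| {r['effect']} | — | — | — | {r.get('warning', '')} |")
            else:
                lines.append(
                    f"| {r['effect']} | {r['statistic']:.3f} | "
                    f"({r['df_num']},{r['df_den']}) | {r['p_value']:.4g} | {r['significant']} |"
                )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute a full run; see the module docstring for outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.mode == "simulate":
        design = generate_design(cfg.n_subjects, cfg.n_trials, cfg.seed)
        data_dir = outdir / "data"
        simulate_experiment(design, cfg.behavior, cfg.seed, data_dir)
    elif cfg.mode == "load":
        if not cfg.data_dir:
            raise ActiveGazeError("load mode requires data_dir")
        data_dir = Path(cfg.data_dir)
    else:
        raise ActiveGazeError(f"unknown mode {cfg.mode!r}")
    metrics, n_fix = analyze_directory(data_dir, cfg)
    metrics_path = outdir / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    stats = stats_report(metrics, cfg.analysis, cfg.measures, cfg.factors)
    stats_path = outdir / "stats.json"
    with open(stats_path, "w") as fh:
        json.dump(stats, fh, indent=1)
    report_path = outdir / "report.md"
    report_path.write_text(_markdown_report(stats, metrics))
    return RunReport(
        metrics_path=metrics_path, stats_path=stats_path, report_path=report_path,
        n_trials=len(metrics), n_fixations=n_fix, metrics=metrics, stats=stats,
    )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    det = FixationDetectorConfig(**raw.pop("detector", {}))
    asg = AssignmentConfig(**raw.pop("assignment", {}))
    ana = AnalysisConfig(**raw.pop("analysis", {}))
    beh_raw = raw.pop("behavior", {})
    from .simulate import ArenaLayout, NoiseParams

    arena = ArenaLayout(**beh_raw.pop("arena", {}))
    noise = NoiseParams(**beh_raw.pop("noise", {}))
    beh = BehaviorParams(arena=arena, noise=noise, **beh_raw)
    return RunConfig(detector=det, assignment=asg, analysis=ana, behavior=beh, **raw)
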