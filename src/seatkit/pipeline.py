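"""End-to-end orchestration: simulate -> detect -> classify -> summarise -> report.

A run is fully reproducible from its configuration and seed: the report
bundle (per-patient CSVs, a cohort JSON, and a markdown report) is
byte-identical across runs with the same ``RunConfig``.  Stage failures
propagate with the stage name and patient id attached, and partial outputs
are removed so a broken run leaves no half-written bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import sys
import time as time_mod
from dataclasses import dataclass, field
from datetime import date, time, timedelta
from pathlib import Path

from . import __version__
from .accelerometry import IntensityCutpoints, detect_nonwear, patient_inclusion, validate_days
from .adherence import adherence_report
from .data_model import (
    Group,
    SeatkitError,
    read_flow_log,
    write_counts_series,
    write_events,
    write_manifest,
    write_posture_series,
)
from .prompts import detect_prompts, unanswered_runs
from .responses import classify_all, stratify_by_setting, summarize_prompts
from .synthetic import SyntheticConfig, generate_cohort
from .trial_metrics import flow_metrics

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("seatkit")


class PipelineError(SeatkitError):
    """A stage failed; the message names the stage (and patient, if any)."""


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    nonwear_window_min: int = 60
    stationary_cut: int = 100
    mvpa_cut: int = 1952
    exclude_nonwear_windows: bool = False
    flow_log_path: str | None = None

    def __post_init__(self) -> None:
        # the run seed overrides the nested generator seed so that one number
        # reproduces the whole bundle
        object.__setattr__(self, "synthetic", dataclasses.replace(self.synthetic, seed=self.seed))

    # -- JSON round trip --------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        syn = d["synthetic"]
        syn["start_date"] = self.synthetic.start_date.isoformat()
        syn["wake_start"] = self.synthetic.wake_start.isoformat("minutes")
        syn["wake_end"] = self.synthetic.wake_end.isoformat("minutes")
        syn["prompt_interval_mix"] = {str(k): v for k, v in self.synthetic.prompt_interval_mix}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        syn = d.get("synthetic", {})
        if "start_date" in syn:
            syn["start_date"] = date.fromisoformat(syn["start_date"])
        for key in ("wake_start", "wake_end"):
            if key in syn:
                syn[key] = time.fromisoformat(syn[key])
        if "prompt_interval_mix" in syn:
            syn["prompt_interval_mix"] = tuple(
                (int(k), float(v)) for k, v in syn["prompt_interval_mix"].items()
            )
        d["synthetic"] = SyntheticConfig(**syn)
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"config references missing file: {path}")
        return cls.from_json(path.read_text())


def _stage(name: str, patient: str | None = None):
    tag = f"{name}[{patient}]" if patient else name
    logger.info("stage %s", tag)
    return tag


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns the cohort summary dict that was written to ``cohort.json``.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    t0 = time_mod.monotonic()
    try:
        return _run(config, out)
    except Exception as exc:
        # leave no partial bundle behind
        if created:
            shutil.rmtree(out, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"{exc}") from exc
    finally:
        logger.info("pipeline finished in %.1fs", time_mod.monotonic() - t0)


def _run(config: RunConfig, out: Path) -> dict:
    stage = _stage("simulate")
    try:
        cohort = generate_cohort(config.synthetic)
    except SeatkitError as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    write_manifest(cohort.manifest, out / "manifest.csv")
    cohort.ground_truth.write(out / "ground_truth_prompts.csv", out / "ground_truth_days.csv")

    cuts = IntensityCutpoints(config.stationary_cut, config.mvpa_cut)
    nonwear_window = timedelta(minutes=config.nonwear_window_min)

    per_patient_summary = {}
    per_patient = {}
    for entry in cohort.manifest:
        pid = entry.patient_id
        series = cohort.series[pid]
        counts = cohort.counts[pid]
        write_posture_series(series, out / f"{pid}_posture.csv")
        write_counts_series(counts, out / f"{pid}_counts.csv")

        stage = _stage("prompts", pid)
        try:
            prompts = (
                detect_prompts(series, entry.prompt_setting)
                if entry.group is Group.EDUCATION_FEEDBACK
                else []
            )
            classifications = classify_all(series, prompts)
            runs = unanswered_runs(prompts, classifications)
            summary = summarize_prompts(
                classifications,
                config.synthetic.n_days,
                exclude_nonwear_windows=config.exclude_nonwear_windows,
            )
        except SeatkitError as exc:
            raise PipelineError(f"{stage}: {exc}") from exc
        write_events(
            [c.to_record() for c in classifications],
            out / f"{pid}_responses.csv",
            columns=[
                "timestamp", "preceding_bout_start", "interval_min", "day_index",
                "responded", "latency_min", "within_5min", "stand_min", "walk_min",
                "steps", "window_truncated", "window_worn_epochs",
            ],
        )

        stage = _stage("wear", pid)
        try:
            flags = detect_nonwear(counts, nonwear_window)
            days = validate_days(flags, cuts)
            inclusion = patient_inclusion(days)
        except SeatkitError as exc:
            raise PipelineError(f"{stage}: {exc}") from exc
        write_events([d.to_record() for d in days], out / f"{pid}_days.csv")

        stage = _stage("adherence", pid)
        try:
            adherence = adherence_report(series)
        except SeatkitError as exc:
            raise PipelineError(f"{stage}: {exc}") from exc

        per_patient_summary[pid] = summary
        per_patient[pid] = {
            "group": entry.group.value,
            "prompt_setting_min": entry.prompt_setting.minutes if entry.prompt_setting else None,
            "prompt_summary": summary.to_dict(),
            "max_unanswered_run": max((r.length for r in runs), default=0),
            "inclusion": inclusion,
            "n_valid_days": sum(d.valid for d in days),
            "adherence": adherence.to_dict(),
        }

    stage = _stage("stratify")
    feedback = {
        pid: s
        for pid, s in per_patient_summary.items()
        if per_patient[pid]["prompt_setting_min"] is not None
    }
    manifest_for = [e for e in cohort.manifest if e.prompt_setting is not None]
    by_setting = stratify_by_setting(feedback, manifest_for)

    config_echo = json.loads(config.to_json())
    config_echo.pop("out_dir")  # not part of the reproducible content
    report: dict = {
        "seatkit_version": __version__,
        "seed": config.seed,
        "config": config_echo,
        "n_patients": config.synthetic.n_patients,
        "per_patient": per_patient,
        "by_setting": by_setting.reset_index().to_dict(orient="records"),
    }

    if config.flow_log_path is not None:
        stage = _stage("trialflow")
        path = Path(config.flow_log_path)
        if not path.exists():
            raise PipelineError(f"{stage}: config references missing file: {path}")
        try:
            report["flow_metrics"] = flow_metrics(read_flow_log(path)).to_dict()
        except SeatkitError as exc:
            raise PipelineError(f"{stage}: {exc}") from exc

    (out / "cohort.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = [
        "# seatkit pipeline report",
        "",
        f"- seatkit version: {report['seatkit_version']}",
        f"- seed: {report['seed']}",
        f"- patients: {report['n_patients']}",
        "",
        "## Prompt outcomes by interval setting",
        "",
        "| setting (min) | patients | prompts | prompts/day | % days prompted | % non-response | % within 5 min (of prompts) |",
        "|---|---|---|---|---|---|---|",
    ]
    for row in report["by_setting"]:
        lines.append(
            "| {setting_min} | {n_patients} | {n_prompts} | {prompts_per_day} "
            "| {pct_days_prompted} | {pct_nonresponse} | {pct_within5_of_prompts} |".format(**row)
        )
    lines += ["", "## Per-patient adherence", ""]
    lines.append("| patient | days worn | charging compliance % | valid days | included |")
    lines.append("|---|---|---|---|---|")
    for pid, p in sorted(report["per_patient"].items()):
        lines.append(
            f"| {pid} | {p['adherence']['days_worn']} | "
            f"{p['adherence']['charging_compliance_pct']} | {p['n_valid_days']} | "
            f"{p['inclusion']['included']} |"
        )
    if "flow_metrics" in report:
        fm = report["flow_metrics"]
        lines += [
            "",
            "## Trial flow",
            "",
            f"- screened: {fm['n_screened']}, eligible: {fm['n_eligible']} ({fm['pct_eligible']}%)",
            f"- approached: {fm['n_approached']} ({fm['pct_approached']}% of eligible)",
            f"- consented: {fm['n_consented']} ({fm['pct_uptake']}% of approached)",
            f"- completed: {fm['n_completed']} ({fm['pct_retention']}% of enrolled)",
        ]
    lines.append("")
    return "\n".join(lines)
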