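"""End-to-end pipeline: synthesize -> extract -> validate -> assemble ->
associate -> predict, with persisted artifacts and a consolidated report.

A single global seed deterministically derives one sub-seed per stage via
``numpy.random.SeedSequence(seed).generate_state(...)`` (each reduced mod
2**31), so any stage can be re-run in isolation reproducibly.  All
numeric thresholds (amplitude 0.3, importance cutoffs 50/20, balancing
floor/cap 180/500, k=4 folds, 1,000 bootstrap iterations, alpha 0.05)
live in this config, never in stage logic.
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

from . import assembly, inference, prediction, speechvalidation, syncohort
from .syncohort import CohortConfig
from .util import percent
from .voicesignal import extract_recordings

logger = logging.getLogger(__name__)

_STAGES = ("cohort", "audio", "validation", "screening", "gam", "folds",
           "skcv", "bootstrap")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold: float = 0.3
    min_duration_samples: int = 0
    validation_fraction: float = 0.083
    screening_cutoff: float = 50.0
    fold_cutoff: float = 20.0
    reset_alpha: float = 0.05
    gam_k: int = 10
    k_folds: int = 4
    balance_floor: int = 180
    balance_cap: int = 500
    bootstrap: int = 1000
    averaging_mode: str = "macro"
    rf_trees: int = 500
    seed: int = 0
    out_dir: str | None = None
    write_audio: bool = False

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {name: int(s % 2**31) for name, s in zip(_STAGES, state)}


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a declarative YAML file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {})
    link = syncohort.VrtLink(**cohort_raw.pop("vrt_link", {}))
    rec = syncohort.RecordingSpec(**cohort_raw.pop("recording", {}))
    if "sleepiness_probs" in cohort_raw:
        cohort_raw["sleepiness_probs"] = tuple(cohort_raw["sleepiness_probs"])
    cohort = CohortConfig(vrt_link=link, recording=rec, **cohort_raw)
    return RunConfig(cohort=cohort, **raw)


@dataclass
class RunReport:
    config: RunConfig
    participants: pd.DataFrame
    ema: pd.DataFrame
    sessions: pd.DataFrame
    onsets: pd.DataFrame
    validation: speechvalidation.ValidationReport
    flow: speechvalidation.FlowLedger
    observations: pd.DataFrame
    exclusion_log: pd.DataFrame
    summary: assembly.CohortSummary
    sex_tests: dict[str, float]
    cascade: inference.CascadeResult
    fold_plan: prediction.FoldPlan
    fold_metrics: list[prediction.FoldMetrics]
    aggregate: prediction.AggregateMetrics

    def render_markdown(self) -> str:
        lines = ["# Pipeline report", ""]
        lines += ["## Attempt flow",
                  "```",
                  speechvalidation.render_flow_text(self.flow),
                  "```", ""]
        v = self.validation
        lines += ["## Speech validation",
                  f"- subsample: {v.subsample_size} "
                  f"({percent(v.subsample_fraction)}%)",
                  f"- confusion (speech positive): TP={v.cm.tp} FP={v.cm.fp} "
                  f"FN={v.cm.fn} TN={v.cm.tn}"]
        for name, val in (("PPV", v.ppv), ("NPV", v.npv),
                          ("accuracy", v.accuracy)):
            lines.append(f"- {name}: "
                         + ("undefined" if val is None else f"{percent(val)}%"))
        lines += [f"- corrected totals: {v.corrected_speech_total} speech / "
                  f"{v.corrected_nonspeech_total} non-speech", ""]
        s = self.summary
        lines += ["## Cohort",
                  f"- {s.n_participants} participants; "
                  f"sex: {s.sex_counts} ({s.sex_percent})",
                  f"- VRT: median {s.vrt['median']:.2f} s, "
                  f"mean {s.vrt['mean']:.2f} +/- {s.vrt['sd']:.2f} s",
                  f"- sleepiness %: {s.sleepiness_percent}",
                  f"- sex-difference p-values: "
                  + ", ".join(f"{k}={p:.2f}" for k, p in self.sex_tests.items()),
                  ""]
        c = self.cascade
        lines += ["## Association cascade",
                  f"- screening retained: {list(c.importance.retained)}",
                  f"- linear model R^2 = {c.linear.r_squared:.3f}, "
                  f"AIC = {c.linear.aic:.2f}",
                  f"- RESET p = {c.reset_p:.3g}"]
        if c.comparison is not None:
            lines.append("- " + c.comparison.report_line())
        else:
            lines.append("- RESET not significant: additive model not fitted")
        lines.append("")
        lines += ["## Prediction (patient-level stratified CV)"]
        agg = self.aggregate.as_dict()
        header = "| fold | accuracy | precision | recall | F1 |"
        lines += [header, "|---|---|---|---|---|"]
        for fm in self.fold_metrics:
            lines.append(f"| {fm.fold_id} | {fm.accuracy:.2f} | "
                         f"{fm.precision:.2f} | {fm.recall:.2f} | {fm.f1:.2f} |")
        lines.append("| mean +/- sd | "
                     + " | ".join(f"{agg[m]['mean']:.2f} +/- {agg[m]['sd']:.2f}"
                                  for m in ("accuracy", "precision",
                                            "recall", "f1")) + " |")
        return "\n".join(lines) + "\n"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline; deterministic given config + seed.

    Stages run in the analysis's order; any stage failure raises
    :class:`StageError` naming the stage, with artifacts from completed
    stages already persisted when an output directory is configured.
    """
    seeds = config.stage_seeds()
    stage = "synthesize"
    try:
        # the global seed owns all randomness: the cohort's own seed field
        # is overridden by the derived stage seed
        cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
        participants, ema, sessions = syncohort.generate_cohort(cohort_cfg)

        stage = "extract-vrt"
        recs = syncohort.synthesize_cohort_audio(sessions, cohort_cfg)
        onsets = extract_recordings((r for _, r in recs),
                                    threshold=config.threshold,
                                    min_duration_samples=config.min_duration_samples)

        stage = "validate"
        truth = dict(zip(sessions["source_id"], ~sessions["non_speech"]))
        validation, corrected = speechvalidation.run_validation(
            onsets, truth, fraction=config.validation_fraction,
            seed=seeds["validation"])
        flags = syncohort.attempt_flags(sessions, ema)
        flags = flags.merge(corrected[["source_id", "is_speech"]],
                            on="source_id")
        flags["non_speech"] = ~flags["is_speech"].astype(bool)
        flow, _ = speechvalidation.account_flow(flags)

        stage = "assemble"
        observations, exclusion_log = assembly.assemble(
            corrected, ema, sessions, participants)
        summary = assembly.summarize(observations)
        sex_tests = assembly.sex_difference_tests(observations)

        stage = "associate"
        cascade = inference.association_cascade(
            observations, screening_cutoff=config.screening_cutoff,
            reset_alpha=config.reset_alpha, gam_k=config.gam_k,
            n_trees=config.rf_trees, seed=seeds["screening"])

        stage = "predict"
        plan = prediction.plan_folds(observations, k=config.k_folds,
                                     seed=seeds["folds"])
        rule = prediction.BalancingRule(config.balance_floor,
                                        config.balance_cap,
                                        seed=seeds["folds"])
        train_sets = [observations[observations["participant_id"]
                                   .isin(f.train_patient_ids)]
                      for f in plan.folds]
        retained, _fold_imp = prediction.select_features_per_fold(
            train_sets, cutoff=config.fold_cutoff, n_trees=config.rf_trees,
            seed=seeds["skcv"])
        features = [f for f in prediction.DEFAULT_FEATURES if f in retained] \
            or list(prediction.DEFAULT_FEATURES)
        fold_metrics = prediction.run_skcv(
            observations, plan, rule, features,
            rf_params={"n_estimators": config.rf_trees},
            bootstrap=config.bootstrap, averaging_mode=config.averaging_mode,
            seed=seeds["bootstrap"])
        agg = prediction.aggregate(fold_metrics)
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(config=config, participants=participants, ema=ema,
                       sessions=sessions, onsets=onsets, validation=validation,
                       flow=flow, observations=observations,
                       exclusion_log=exclusion_log, summary=summary,
                       sex_tests=sex_tests, cascade=cascade, fold_plan=plan,
                       fold_metrics=fold_metrics, aggregate=agg)
    if config.out_dir is not None:
        write_artifacts(report, Path(config.out_dir))
    return report


def write_artifacts(report: RunReport, out: Path) -> None:
    """Persist every intermediate artifact as CSV/JSON plus report.md."""
    out.mkdir(parents=True, exist_ok=True)
    report.observations.to_csv(out / "analysis_table.csv", index=False)
    report.exclusion_log.to_csv(out / "exclusion_log.csv", index=False)
    report.onsets.to_csv(out / "onset_results.csv", index=False)
    report.flow.to_frame().to_csv(out / "flow_ledger.csv", index=False)
    report.cascade.importance.to_frame().to_csv(out / "importance.csv",
                                                index=False)
    report.cascade.linear.terms.to_csv(out / "lr_terms.csv", index=False)
    prediction.fold_metrics_frame(report.fold_metrics).to_csv(
        out / "fold_metrics.csv", index=False)
    assembly.sleepiness_by_participant_week(report.observations).to_csv(
        out / "sleepiness_by_week.csv", index=False)

    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(report.summary.as_dict(), fh, indent=2, default=_json_default)
    with open(out / "validation.json", "w") as fh:
        json.dump(report.validation.as_dict(), fh, indent=2,
                  default=_json_default)
    gam_summary = None
    if report.cascade.gam is not None:
        gam_summary = {
            "aic": report.cascade.gam.aic,
            "deviance_explained": report.cascade.gam.deviance_explained,
            "smooths": {f: {"edf": d["edf"], "p_value": d["p_value"]}
                        for f, d in report.cascade.gam.smooth_terms.items()},
            "linear_terms": report.cascade.gam.linear_terms,
        }
        pd.concat([pd.DataFrame({"feature": f, "x": d["x"],
                                 "effect": d["curve"]})
                   for f, d in report.cascade.gam.smooth_terms.items()]
                  ).to_csv(out / "gam_smooths.csv", index=False)
    with open(out / "gam_summary.json", "w") as fh:
        json.dump(gam_summary, fh, indent=2, default=_json_default)
    comparison = (dataclasses.asdict(report.cascade.comparison)
                  if report.cascade.comparison else None)
    with open(out / "model_comparison.json", "w") as fh:
        json.dump({"reset_p": report.cascade.reset_p,
                   "comparison": comparison}, fh, indent=2,
                  default=_json_default)
    with open(out / "aggregate_metrics.json", "w") as fh:
        json.dump(report.aggregate.as_dict(), fh, indent=2,
                  default=_json_default)
    with open(out / "fold_plan.json", "w") as fh:
        json.dump(report.fold_plan.as_dict(), fh, indent=2,
                  default=_json_default)
    with open(out / "sex_tests.json", "w") as fh:
        json.dump(report.sex_tests, fh, indent=2, default=_json_default)
    with open(out / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(report.config), fh, indent=2,
                  default=_json_default)
    with open(out / "report.md", "w") as fh:
        fh.write(report.render_markdown())
    logger.info("artifacts written to %s", out)
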