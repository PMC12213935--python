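"""Manual-validation workflow for speech/non-speech classification.

The automated amplitude-threshold classifier is audited against human
labels on a random subsample: a 2x2 confusion matrix is built with
*speech* as the positive class, PPV/NPV/accuracy are derived by exact
rational arithmetic, discovered false negatives are relabeled in a
correction pass, and an ordered flow ledger accounts for every exclusion
stage (non-speech, invalid strategy, missing sleepiness) down to the
analysis-ready sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .util import round_half_up

#: The exclusion cascade in its reported narrative order.
DEFAULT_STAGE_ORDER = ("non_speech", "invalid_strategy", "missing_sleepiness")

STAGE_LABELS = {
    "non_speech": "non-speech sounds removed",
    "invalid_strategy": "invalid-strategy attempts removed",
    "missing_sleepiness": "missing sleepiness removed",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with *speech* as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_confusion(predicted: Sequence[bool], manual: Sequence[bool]
                    ) -> ConfusionMatrix:
    """Tally predictions against human labels (positive class: speech)."""
    p = np.asarray(predicted, dtype=bool)
    m = np.asarray(manual, dtype=bool)
    if p.shape != m.shape:
        raise ValueError(
            f"length mismatch: {p.shape[0]} predictions vs {m.shape[0]} labels")
    return ConfusionMatrix(tp=int(np.sum(p & m)), fp=int(np.sum(p & ~m)),
                           fn=int(np.sum(~p & m)), tn=int(np.sum(~p & ~m)))


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """PPV, NPV and accuracy as exact ratios (floats of Fractions).

    A metric with a zero denominator is reported as ``None`` (undefined),
    never as 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else float(Fraction(num, den))

    return {
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": ratio(cm.tp + cm.tn, cm.total) if cm.total else None,
    }


def draw_validation_subsample(results: pd.DataFrame, fraction: float,
                              seed: int) -> pd.DataFrame:
    """Random subsample of round(fraction * N) rows, without replacement.

    Half-up rounding of the target size; deterministic given the seed;
    rows keep their original relative order.
    """
    if len(results) == 0:
        raise ValueError("cannot subsample an empty results table")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(results)
    size = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=size, replace=False))
    return results.iloc[idx]


def apply_corrections(results: pd.DataFrame, corrections: set[str] | Sequence[str]
                      ) -> tuple[pd.DataFrame, int, int]:
    """Relabel the given source_ids from non-speech to speech.

    Every id must exist and currently be non-speech, so re-applying the
    same correction set raises.  Returns the corrected table and the new
    (speech_total, nonspeech_total).
    """
    ids = set(corrections)
    out = results.copy()
    known = set(out["source_id"])
    missing = sorted(ids - known)
    if missing:
        raise ValueError(f"unknown source_ids in corrections: {missing}")
    mask = out["source_id"].isin(ids)
    already = sorted(out.loc[mask & out["is_speech"].astype(bool), "source_id"])
    if already:
        raise ValueError(f"corrections target rows already labeled speech: {already}")
    out.loc[mask, "is_speech"] = True
    speech = int(out["is_speech"].astype(bool).sum())
    return out, speech, len(out) - speech


@dataclass(frozen=True)
class ValidationReport:
    subsample_size: int
    subsample_fraction: float
    cm: ConfusionMatrix
    ppv: float | None
    npv: float | None
    accuracy: float | None
    corrected_speech_total: int
    corrected_nonspeech_total: int

    def as_dict(self) -> dict:
        d = dict(subsample_size=self.subsample_size,
                 subsample_fraction=self.subsample_fraction,
                 tp=self.cm.tp, fp=self.cm.fp, fn=self.cm.fn, tn=self.cm.tn,
                 ppv=self.ppv, npv=self.npv, accuracy=self.accuracy,
                 corrected_speech_total=self.corrected_speech_total,
                 corrected_nonspeech_total=self.corrected_nonspeech_total)
        return d


def run_validation(results: pd.DataFrame, manual_labels: Mapping[str, bool],
                   fraction: float = 0.083, seed: int = 0
                   ) -> tuple[ValidationReport, pd.DataFrame]:
    """Full validation pass: subsample, audit, correct.

    ``manual_labels`` maps source_id to the human speech/non-speech truth;
    it must cover at least the drawn subsample.  False negatives found in
    the subsample are relabeled in the returned corrected table.
    """
    sub = draw_validation_subsample(results, fraction, seed)
    missing = [s for s in sub["source_id"] if s not in manual_labels]
    if missing:
        raise ValueError(f"manual labels missing for {len(missing)} subsampled ids")
    manual = np.array([bool(manual_labels[s]) for s in sub["source_id"]])
    predicted = sub["is_speech"].astype(bool).to_numpy()
    cm = build_confusion(predicted, manual)
    metrics = confusion_metrics(cm)
    fn_ids = set(sub.loc[~predicted & manual, "source_id"])
    if fn_ids:
        corrected, speech, nonspeech = apply_corrections(results, fn_ids)
    else:
        corrected = results.copy()
        speech = int(corrected["is_speech"].astype(bool).sum())
        nonspeech = len(corrected) - speech
    report = ValidationReport(
        subsample_size=len(sub), subsample_fraction=fraction, cm=cm,
        ppv=metrics["ppv"], npv=metrics["npv"], accuracy=metrics["accuracy"],
        corrected_speech_total=speech, corrected_nonspeech_total=nonspeech)
    return report, corrected


# ---------------------------------------------------------------------------
# Flow ledger


@dataclass(frozen=True)
class FlowStage:
    label: str
    n_in: int
    n_removed: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - self.n_removed:
            raise ValueError("flow stage does not conserve counts")


@dataclass(frozen=True)
class FlowLedger:
    stages: tuple[FlowStage, ...] = field(default_factory=tuple)

    @property
    def final_n(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.stages])

    def __str__(self) -> str:
        lines = []
        for s in self.stages:
            lines.append(f"{s.n_in:>6} -> {s.label} (-{s.n_removed}) -> {s.n_out}")
        return "\n".join(lines)


def account_flow(attempts: pd.DataFrame,
                 stage_order: Sequence[str] = DEFAULT_STAGE_ORDER
                 ) -> tuple[FlowLedger, pd.DataFrame]:
    """Apply the exclusion cascade and account for every removed record.

    ``attempts`` must carry a boolean column per stage flag.  Stages are
    applied sequentially in ``stage_order`` (the reported order by
    default), so a record flagged at several stages is counted at the
    first.  Returns the ledger and the surviving rows.
    """
    for col in stage_order:
        if col not in attempts.columns:
            raise KeyError(f"attempt table is missing flag column {col!r}")
    remaining = attempts
    stages = []
    for col in stage_order:
        flag = remaining[col].astype(bool)
        removed = int(flag.sum())
        out = remaining.loc[~flag]
        stages.append(FlowStage(label=STAGE_LABELS.get(col, col),
                                n_in=len(remaining), n_removed=removed,
                                n_out=len(out)))
        remaining = out
    return FlowLedger(tuple(stages)), remaining


def render_flow_text(ledger: FlowLedger, title: str = "Attempt flow") -> str:
    """Human-readable flow-diagram block."""
    head = f"{title}\n{'=' * len(title)}"
    return f"{head}\n{ledger}\nanalysis-ready: {ledger.final_n}"


def percent_nonspeech(nonspeech: int, total: int) -> float:
    """Presentation percentage, half-up to one decimal (136/2230 -> 6.1)."""
    return round_half_up(100.0 * nonspeech / total, 1)
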