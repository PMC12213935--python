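"""Analysis-dataset assembly, descriptive summaries, and sex-difference tests.

Joins onset-extraction results with the session plan, the day-level EMA
record and participant demographics into one analysis-ready row per
attempt, routing every excluded row (non-speech, invalid strategy, missing
sleepiness — in that order) to an exclusion log with its reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .util import percent

logger = logging.getLogger(__name__)


class SchemaError(KeyError):
    """A required key column or table is missing."""


_OBS_COLUMNS = ["participant_id", "week", "test_type", "attempt_index",
                "vrt_seconds", "sleepiness", "mood", "cognition_scale",
                "caffeine", "alcohol", "age", "sex", "race", "education",
                "bzra_use", "difficulty", "pass_fail"]


def assemble(onsets: pd.DataFrame, ema: pd.DataFrame, sessions: pd.DataFrame,
             participants: pd.DataFrame
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the observation table; returns (observations, exclusion_log).

    The EMA record sharing the attempt's test day supplies the day's
    covariates; duplicate EMA records for a participant-day are resolved by
    keeping the last one (record order), with a logged warning.  Every
    input onset row lands exactly once in the output or the exclusion log.
    """
    for col in ("source_id", "is_speech"):
        if col not in onsets.columns:
            raise SchemaError(f"onsets table is missing column {col!r}")
    for col in ("participant_id", "day", "source_id"):
        if col not in sessions.columns:
            raise SchemaError(f"sessions table is missing column {col!r}")
    if "participant_id" not in participants.columns:
        raise SchemaError("participants table is missing 'participant_id'")

    ema = ema.copy()
    dup = ema.duplicated(["participant_id", "session_day"], keep=False)
    if dup.any():
        logger.warning("dropping %d duplicate EMA records (keeping last per day)",
                       int(dup.sum()) - ema.loc[dup, ["participant_id",
                                                      "session_day"]]
                       .drop_duplicates().shape[0])
        ema = ema.drop_duplicates(["participant_id", "session_day"], keep="last")

    merged = onsets.merge(sessions, on="source_id", how="inner",
                          suffixes=("", "_sess"))
    unmatched = onsets.loc[~onsets["source_id"].isin(merged["source_id"]),
                           ["source_id"]].copy()
    unmatched["participant_id"] = pd.NA
    unmatched["reason"] = "unmatched_session"
    merged = merged.merge(
        ema, left_on=["participant_id", "day"],
        right_on=["participant_id", "session_day"], how="left",
        suffixes=("", "_ema"))

    missing_pids = set(merged["participant_id"]) - set(participants["participant_id"])
    if missing_pids:
        raise SchemaError(
            f"participants table lacks records for {sorted(missing_pids)}")
    merged = merged.merge(participants, on="participant_id", how="left",
                          suffixes=("", "_part"))

    non_speech = ~merged["is_speech"].fillna(False).astype(bool)
    invalid = merged.get("invalid_strategy",
                         pd.Series(False, index=merged.index)).astype(bool)
    attempt_missing = merged.get("missing_sleepiness",
                                 pd.Series(False, index=merged.index)).astype(bool)
    missing_sleep = merged["sleepiness"].isna() | attempt_missing

    reason = pd.Series(pd.NA, index=merged.index, dtype="object")
    reason[missing_sleep] = "missing_sleepiness"
    reason[invalid] = "invalid_strategy"
    reason[non_speech] = "non_speech"  # reported order: first applicable wins

    excluded = reason.notna()
    log = merged.loc[excluded, ["source_id", "participant_id"]].copy()
    log["reason"] = reason[excluded]
    if len(unmatched):
        log = pd.concat([log, unmatched], ignore_index=True)

    obs = merged.loc[~excluded].copy()
    obs["sleepiness"] = obs["sleepiness"].astype(int)
    obs["sleepiness_cat"] = pd.Categorical(obs["sleepiness"],
                                           categories=[1, 2, 3, 4], ordered=True)
    keep = [c for c in _OBS_COLUMNS if c in obs.columns] + ["source_id",
                                                            "sleepiness_cat"]
    return obs[keep].reset_index(drop=True), log.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Descriptive summaries


def _num_summary(x: np.ndarray) -> dict:
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation (type-7)
    return dict(mean=float(np.mean(x)),
                sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                median=float(np.median(x)), iqr=(float(q1), float(q3)),
                range=(float(np.min(x)), float(np.max(x))))


@dataclass(frozen=True)
class CohortSummary:
    n_participants: int
    age: dict
    sex_counts: dict
    sex_percent: dict
    race_counts: dict
    education: dict
    sleepiness_percent: dict
    vrt: dict

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(table: pd.DataFrame) -> CohortSummary:
    """Participant- and attempt-level descriptives.

    Demographics are summarized over unique participants; VRT and
    sleepiness over attempt rows.  SD uses the n-1 denominator, quartiles
    linear interpolation, and percentages are rounded half-up to one
    decimal at presentation.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    people = table.drop_duplicates("participant_id")
    sex_counts = people["sex"].value_counts().to_dict()
    n_people = len(people)
    sleep_counts = table["sleepiness"].value_counts().reindex([1, 2, 3, 4],
                                                              fill_value=0)
    return CohortSummary(
        n_participants=n_people,
        age=_num_summary(people["age"].to_numpy(dtype=float)),
        sex_counts={k: int(v) for k, v in sex_counts.items()},
        sex_percent={k: percent(v / n_people) for k, v in sex_counts.items()},
        race_counts={k: int(v) for k, v in
                     people["race"].value_counts().to_dict().items()},
        education=_num_summary(people["education"].to_numpy(dtype=float)),
        sleepiness_percent={int(k): percent(v / len(table))
                            for k, v in sleep_counts.items()},
        vrt=_num_summary(table["vrt_seconds"].to_numpy(dtype=float)),
    )


def sleepiness_by_participant_week(table: pd.DataFrame) -> pd.DataFrame:
    """Wide participant x week view of modal sleepiness per session week."""
    def modal(s: pd.Series):
        m = s.mode()
        return int(m.iloc[0]) if len(m) else np.nan
    wide = table.pivot_table(index="participant_id", columns="week",
                             values="sleepiness", aggfunc=modal)
    wide.columns = [f"week_{w}" for w in wide.columns]
    return wide.reset_index()


# ---------------------------------------------------------------------------
# Sex-difference tests on VRT


def sex_difference_tests(table: pd.DataFrame, use_levene: bool = False
                         ) -> dict[str, float]:
    """Two-sided tests of VRT differences between the sexes.

    Welch t-test for means, Mann-Whitney U (normal approximation with tie
    correction) for distributions, and the two-sample F-test of the
    variance ratio (``use_levene=True`` substitutes Levene's test, which is
    robust to non-normality).
    """
    groups = {sex: sub["vrt_seconds"].to_numpy(dtype=float)
              for sex, sub in table.groupby("sex")}
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 sexes, found {sorted(groups)}")
    (a, b) = groups.values()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sex needs at least 2 observations")

    t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)
    if use_levene:
        var_p = float(stats.levene(a, b).pvalue)
    else:
        f_stat = np.var(a, ddof=1) / np.var(b, ddof=1)
        df1, df2 = len(a) - 1, len(b) - 1
        cdf = stats.f.cdf(f_stat, df1, df2)
        var_p = float(2.0 * min(cdf, 1.0 - cdf))
    return {"t_test_p": t_p, "mann_whitney_p": mw_p, "variance_test_p": var_p}
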