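"""Synthetic cohort generator.

Emulates the study design this package analyzes: ~16 adults aged >=55 with
insomnia and benzodiazepine-receptor-agonist (BZRA) history complete weekly
verbal paired-associates (VPA) tests on days 1/8/15/22, each attempt audio
recorded, with a daily ecological momentary assessment (EMA) of sleepiness
(1 not at all ... 4 more prominent), mood, cognition, caffeine, alcohol and
tobacco.  The generator plants a lognormal link from sleepiness to verbal
reaction time (VRT) so the downstream association and prediction stages
have a recoverable signal, and synthesizes WAV-writable audio with the
planted onset latency.

Default rates and distributions are the study's reported ones: sleepiness
levels 23.7/39.5/17.1/19.8% (normalized), ~6.1% non-speech recordings, 14%
invalid-strategy attempts, 12.8% missing sleepiness, and a marginal VRT
with median 1.68 s and mean 2.19 s (achieved by the calibrated link
defaults below).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .voicesignal import AudioRecording, write_recording

#: Reported sleepiness-level percentages normalized to sum to one
#: (the printed 23.7/39.5/17.1/19.8 sum to 100.1 due to rounding).
_RAW_PROBS = np.array([0.237, 0.395, 0.171, 0.198])
DEFAULT_SLEEPINESS_PROBS: tuple[float, ...] = tuple(_RAW_PROBS / _RAW_PROBS.sum())

#: Calibrated so the marginal VRT mixture under DEFAULT_SLEEPINESS_PROBS has
#: median 1.68 s and mean 2.19 s (implied sd ~1.82 s).
DEFAULT_BASELINE_LOG_LATENCY = 0.385956
DEFAULT_SLOPE_PER_LEVEL = 0.10
DEFAULT_NOISE_SD = 0.720370

TEST_DAYS = (1, 8, 15, 22, 29)  # weekly test days; week 5 occurs for some cohorts


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class VrtLink:
    """Lognormal sleepiness -> latency link.

    latency = exp(baseline + slope * (sleepiness - 1) + Normal(0, noise_sd)).
    """

    baseline_log_latency: float = DEFAULT_BASELINE_LOG_LATENCY
    slope_per_level: float = DEFAULT_SLOPE_PER_LEVEL
    noise_sd: float = DEFAULT_NOISE_SD


@dataclass(frozen=True)
class RecordingSpec:
    """Audio synthesis parameters (amplitudes as fractions of full scale)."""

    sample_rate: int = 16000
    speech_amplitude: float = 0.8
    noise_amplitude: float = 0.05
    stereo: bool = True  # speech on the left channel


@dataclass(frozen=True)
class Fig1Counts:
    """Exact flow-diagram composition for the fixture preset."""

    total_attempts: int = 2230
    non_speech: int = 136
    invalid_strategy: int = 295
    missing_sleepiness: int = 286


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 16
    n_weeks: int = 4
    attempts_per_session: int = 35
    sleepiness_probs: tuple[float, ...] = DEFAULT_SLEEPINESS_PROBS
    nonspeech_rate: float = 0.061
    invalid_strategy_rate: float = 0.14
    missing_sleepiness_rate: float = 0.128
    vrt_link: VrtLink = field(default_factory=VrtLink)
    covariate_effects: dict = field(default_factory=dict)
    participant_sleepiness_sd: float = 0.0  # latent random intercept; 0 = i.i.d.
    participant_latency_sd: float = 0.0     # log-scale random intercept on VRT
    caffeine_mean: float = 1.5
    recording: RecordingSpec = field(default_factory=RecordingSpec)
    sample_rate: int = 16000
    seed: int = 0
    exact_counts: Fig1Counts | None = None

    def validate(self) -> None:
        p = np.asarray(self.sleepiness_probs, dtype=float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(
                "sleepiness_probs must be 4 nonnegative entries summing to 1")
        for name in ("nonspeech_rate", "invalid_strategy_rate",
                     "missing_sleepiness_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.n_weeks not in (4, 5):
            raise ConfigError("n_weeks must be 4 or 5")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")


def fig1_preset(seed: int = 0) -> CohortConfig:
    """Cohort preset reproducing the flow-diagram composition exactly.

    2,230 attempts of which exactly 136 non-speech, 295 invalid-strategy
    and 286 missing-sleepiness (disjoint sets, assigned by seeded
    permutation), leaving 1,513 analysis-ready rows.
    """
    return CohortConfig(seed=seed, exact_counts=Fig1Counts())


# ---------------------------------------------------------------------------
# Table generation


def _sample_levels(probs: np.ndarray, shift: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    """Draw ordinal 1-4 levels via a latent-normal copula.

    With zero shift this reproduces i.i.d. categorical sampling from
    ``probs`` exactly; a positive shift moves mass toward higher levels.
    """
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    z = rng.standard_normal(shift.shape[0]) + shift
    return np.searchsorted(cuts, z, side="left") + 1


def latency_for(sleepiness: int | np.ndarray, vrt_link: VrtLink,
                rng: np.random.Generator) -> float | np.ndarray:
    """Draw a strictly positive latency for a given sleepiness level."""
    s = np.asarray(sleepiness, dtype=float)
    noise = vrt_link.noise_sd * rng.standard_normal(s.shape) if s.shape \
        else vrt_link.noise_sd * rng.standard_normal()
    out = np.exp(vrt_link.baseline_log_latency
                 + vrt_link.slope_per_level * (s - 1.0) + noise)
    return float(out) if np.isscalar(sleepiness) or s.shape == () else out


def _participants(n: int, rng: np.random.Generator) -> pd.DataFrame:
    races = np.array(["White", "Black or African American", "Hispanic or Latino"])
    race_p = np.array([0.874, 0.063, 0.063])
    df = pd.DataFrame({
        "participant_id": [f"P{i + 1:02d}" for i in range(n)],
        "age": np.round(rng.uniform(56.0, 74.0, n), 1),
        "sex": rng.choice(["female", "male"], size=n, p=[0.688, 0.312]),
        "race": rng.choice(races, size=n, p=race_p / race_p.sum()),
        "education": rng.choice(np.arange(12, 21), size=n,
                                p=_education_weights()),
        "bzra_use": rng.random(n) < 0.5,
        "mmse": rng.integers(24, 31, n),
    })
    return df


def _education_weights() -> np.ndarray:
    # peaked at 16 years (college), range 12-20 as in the cohort
    w = np.array([1, 1, 2, 3, 8, 4, 4, 2, 1], dtype=float)
    return w / w.sum()


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (participants, ema, sessions) tables, deterministic in seed.

    ``sessions`` has one row per recorded attempt and carries the planted
    ground truth (``true_sleepiness``, ``true_latency``, ``non_speech``)
    used by audio synthesis and by validation tests.  In normal mode
    missing sleepiness lives in the EMA table (day-level NaN); the exact
    fixture preset marks attempt-level ``missing_sleepiness`` instead so
    the flow composition is hit exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.sleepiness_probs, dtype=float)

    empty_cols = dict(
        participants=["participant_id", "age", "sex", "race", "education",
                      "bzra_use", "mmse"],
        ema=["participant_id", "session_day", "sleepiness", "mood",
             "cognition_scale", "caffeine", "alcohol", "tobacco"],
        sessions=["participant_id", "week", "day", "test_type", "attempt_index",
                  "difficulty", "invalid_strategy", "pass_fail", "source_id",
                  "non_speech", "missing_sleepiness", "true_sleepiness",
                  "true_latency"],
    )
    if config.n_participants == 0:
        return tuple(pd.DataFrame(columns=c) for c in empty_cols.values())

    participants = _participants(config.n_participants, rng)
    pids = participants["participant_id"].to_numpy()
    intercepts = (config.participant_sleepiness_sd
                  * rng.standard_normal(config.n_participants))
    lat_intercepts = (config.participant_latency_sd
                      * rng.standard_normal(config.n_participants))

    # attempts per (participant, week): either the configured constant or a
    # distribution hitting an exact grand total for the fixture preset.
    n_cells = config.n_participants * config.n_weeks
    if config.exact_counts is not None:
        total = config.exact_counts.total_attempts
        base, rem = divmod(total, n_cells)
        per_cell = np.full(n_cells, base, dtype=int)
        per_cell[:rem] += 1
    else:
        per_cell = np.full(n_cells, config.attempts_per_session, dtype=int)

    ema_rows, sess_rows = [], []
    cell = 0
    for pi, pid in enumerate(pids):
        for week in range(1, config.n_weeks + 1):
            day = TEST_DAYS[week - 1]
            # day-level EMA (one record per test day, inherited by attempts)
            caffeine = int(rng.poisson(config.caffeine_mean))
            alcohol = bool(rng.random() < 0.10)
            tobacco = bool(rng.random() < 0.05)
            mood = int(_sample_levels(np.array([0.3, 0.4, 0.2, 0.1]),
                                      np.zeros(1), rng)[0])
            cognition = int(_sample_levels(np.array([0.35, 0.35, 0.2, 0.1]),
                                           np.zeros(1), rng)[0])
            shift = intercepts[pi]
            for cov, eff in config.covariate_effects.items():
                shift = shift + eff * {"caffeine": caffeine,
                                       "alcohol": float(alcohol),
                                       "mood": mood,
                                       "cognition_scale": cognition}.get(cov, 0.0)
            level = int(_sample_levels(probs, np.asarray([shift]), rng)[0])
            missing = (config.exact_counts is None
                       and rng.random() < config.missing_sleepiness_rate)
            ema_rows.append(dict(
                participant_id=pid, session_day=day,
                sleepiness=(np.nan if missing else level), mood=mood,
                cognition_scale=cognition, caffeine=caffeine,
                alcohol=alcohol, tobacco=tobacco))

            n_att = per_cell[cell]
            cell += 1
            for a in range(1, n_att + 1):
                non_speech = (False if config.exact_counts is not None
                              else bool(rng.random() < config.nonspeech_rate))
                invalid = (False if config.exact_counts is not None
                           else bool(rng.random() < config.invalid_strategy_rate))
                latency = (np.nan if non_speech else float(np.exp(
                    config.vrt_link.baseline_log_latency
                    + config.vrt_link.slope_per_level * (level - 1)
                    + lat_intercepts[pi]
                    + config.vrt_link.noise_sd * rng.standard_normal())))
                sess_rows.append(dict(
                    participant_id=pid, week=week, day=day,
                    test_type="VPA-DR" if a == n_att else "VPA-I",
                    attempt_index=a,
                    difficulty=float(np.round(rng.normal(0.0, 1.0), 3)),
                    invalid_strategy=invalid,
                    pass_fail=bool(rng.random() < 0.8),
                    source_id=f"{pid}_w{week}_a{a:03d}",
                    non_speech=non_speech, missing_sleepiness=False,
                    true_sleepiness=level, true_latency=latency))

    ema = pd.DataFrame(ema_rows)
    sessions = pd.DataFrame(sess_rows)

    if config.exact_counts is not None:
        c = config.exact_counts
        order = rng.permutation(len(sessions))
        ns = order[:c.non_speech]
        inv = order[c.non_speech:c.non_speech + c.invalid_strategy]
        mis = order[c.non_speech + c.invalid_strategy:
                    c.non_speech + c.invalid_strategy + c.missing_sleepiness]
        sessions.loc[sessions.index[ns], "non_speech"] = True
        sessions.loc[sessions.index[ns], "true_latency"] = np.nan
        sessions.loc[sessions.index[inv], "invalid_strategy"] = True
        sessions.loc[sessions.index[mis], "missing_sleepiness"] = True

    return participants, ema, sessions


def attempt_flags(sessions: pd.DataFrame, ema: pd.DataFrame) -> pd.DataFrame:
    """Attempt-level exclusion flags for the flow ledger.

    ``missing_sleepiness`` is true when the day's EMA sleepiness is absent
    or the attempt is individually marked (exact fixture mode).
    """
    merged = sessions.merge(
        ema[["participant_id", "session_day", "sleepiness"]],
        left_on=["participant_id", "day"],
        right_on=["participant_id", "session_day"], how="left")
    out = sessions[["source_id", "non_speech", "invalid_strategy"]].copy()
    out["missing_sleepiness"] = (merged["sleepiness"].isna().to_numpy()
                                 | sessions["missing_sleepiness"].to_numpy())
    return out


def onsets_from_truth(sessions: pd.DataFrame,
                      sample_rate: int = 16000) -> pd.DataFrame:
    """Onset-result table implied by the planted ground truth.

    Bypasses audio synthesis/detection for table-only workflows: speech
    attempts get their planted latency as VRT, non-speech attempts get
    none.  Matches the schema of :func:`sleepvoice.voicesignal.batch_extract`.
    """
    speech = ~sessions["non_speech"].astype(bool)
    lat = sessions["true_latency"].to_numpy(dtype=float)
    onset_idx = np.where(speech, np.round(lat * sample_rate), np.nan)
    return pd.DataFrame({
        "source_id": sessions["source_id"],
        "is_speech": speech,
        "onset_index": onset_idx,
        "vrt_seconds": np.where(speech, lat, np.nan),
        "threshold": 0.3,
        "error": None,
    })


# ---------------------------------------------------------------------------
# Audio synthesis


def synthesize_recording(latency: float | None, duration: float,
                         spec: RecordingSpec, rng: np.random.Generator,
                         source_id: str = "") -> AudioRecording:
    """Synthesize one attempt's audio with a planted onset.

    Background is uniform noise within +/- ``noise_amplitude``.  A speech
    burst (amplitude-modulated tone at ``speech_amplitude``) starts at
    ``round(latency * sample_rate)``; the first burst sample is forced to
    ``speech_amplitude`` exactly so threshold detection recovers the
    planted latency to within one sample.  ``latency=None`` produces a
    non-speech recording that never exceeds ``noise_amplitude``.  No
    attempt is made at intelligible speech.
    """
    sr = spec.sample_rate
    n = int(round(duration * sr))
    if n <= 0:
        raise ValueError("duration must be positive")
    if latency is not None:
        if not 0.0 <= latency:
            raise ValueError("latency must be nonnegative")
        if latency >= duration:
            raise ValueError(
                f"latency {latency} s must be less than duration {duration} s")

    left = rng.uniform(-spec.noise_amplitude, spec.noise_amplitude, n)
    if latency is not None:
        onset = int(round(latency * sr))
        burst_n = min(n - onset, int(0.4 * sr))
        t = np.arange(burst_n) / sr
        envelope = np.exp(-t / 0.15)
        phase = rng.uniform(0, 2 * np.pi)
        burst = spec.speech_amplitude * envelope * np.sin(
            2 * np.pi * 220.0 * t + phase)
        left[onset:onset + burst_n] = np.clip(burst, -spec.speech_amplitude,
                                              spec.speech_amplitude)
        left[onset] = spec.speech_amplitude

    if spec.stereo:
        right = rng.uniform(-spec.noise_amplitude, spec.noise_amplitude, n)
        samples = np.column_stack([left, right])
    else:
        samples = left
    return AudioRecording(samples=samples, sample_rate=sr, source_id=source_id)


def synthesize_cohort_audio(sessions: pd.DataFrame, config: CohortConfig,
                            margin: float = 1.0):
    """Yield (source_id, AudioRecording) for every session row.

    Deterministic: a per-row generator is derived from the config seed and
    the row position, so any subset can be regenerated independently.
    """
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    child_seeds = ss.generate_state(max(len(sessions), 1))
    for i, row in enumerate(sessions.itertuples(index=False)):
        rng = np.random.default_rng(int(child_seeds[i]))
        latency = None if row.non_speech else float(row.true_latency)
        duration = margin if latency is None else latency + margin
        rec = synthesize_recording(latency, duration, config.recording, rng,
                                   source_id=row.source_id)
        yield row.source_id, rec


def write_cohort(out_dir: str | Path, config: CohortConfig,
                 write_audio: bool = True) -> dict[str, Path]:
    """Generate a cohort and persist it: three CSVs, WAVs, and a manifest.

    Returns a dict of the written paths.  Audio is 16-bit PCM WAV at the
    configured rate (stereo by default, speech on the left channel).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants, ema, sessions = generate_cohort(config)
    paths = {
        "participants": out / "participants.csv",
        "ema": out / "ema.csv",
        "sessions": out / "sessions.csv",
        "manifest": out / "manifest.csv",
    }
    participants.to_csv(paths["participants"], index=False)
    ema.to_csv(paths["ema"], index=False)
    sessions.to_csv(paths["sessions"], index=False)

    manifest_rows = []
    if write_audio:
        wav_dir = out / "wav"
        wav_dir.mkdir(exist_ok=True)
        for source_id, rec in synthesize_cohort_audio(sessions, config):
            wav_path = wav_dir / f"{source_id}.wav"
            write_recording(str(wav_path), rec)
            manifest_rows.append(dict(source_id=source_id, wav_path=str(wav_path)))
    pd.DataFrame(manifest_rows, columns=["source_id", "wav_path"]).to_csv(
        paths["manifest"], index=False)
    return paths
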