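"""Speech-onset detection and verbal reaction time (VRT) extraction.

A test attempt's recording is classified as speech iff any sample of its
(full-scale normalized) left channel strictly exceeds an amplitude
threshold, 0.3 of full scale by default.  VRT is the time from recording
start to that first supra-threshold sample.  MFCCs are provided only as an
audit representation for manual validation plots; they play no role in
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from scipy.io import wavfile

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.3


class FormatError(ValueError):
    """Unsupported or corrupt audio encoding."""


@dataclass(frozen=True)
class AudioRecording:
    """One test attempt's audio.

    ``samples`` is float64 in [-1, 1]: shape ``(n,)`` for mono or
    ``(n, n_channels)`` for multichannel.  ``bit_depth`` records the source
    PCM depth (purely informational once normalized).
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (n, channels)")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class OnsetResult:
    """Speech/non-speech decision and VRT for one recording.

    ``is_speech``, ``onset_index`` and ``vrt_seconds`` are jointly present
    or jointly absent: a non-speech recording has neither an onset index
    nor a VRT.
    """

    source_id: str
    is_speech: bool
    onset_index: int | None
    vrt_seconds: float | None
    threshold: float
    min_duration_samples: int = 0

    def __post_init__(self) -> None:
        present = (self.onset_index is not None, self.vrt_seconds is not None)
        if any(present) != all(present) or self.is_speech != all(present):
            raise ValueError("is_speech, onset_index, vrt_seconds must agree")


_PCM_BITS = {np.dtype(np.uint8): 8, np.dtype(np.int16): 16, np.dtype(np.int32): 32}


def read_recording(path: str, source_id: str | None = None) -> AudioRecording:
    """Read a PCM or float WAV file and normalize to [-1, 1].

    Integer PCM is divided by full scale ``2**(bits-1)`` (8-bit WAV is
    unsigned and is re-centred first); 24-bit files arrive from the reader
    already left-justified in int32 so the same division applies.  Float
    WAV is passed through clipped to [-1, 1].
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except (ValueError, EOFError) as exc:
        raise FormatError(f"cannot decode WAV file {path!r}: {exc}") from exc
    except OSError as exc:
        raise OSError(f"cannot read WAV file {path!r}: {exc}") from exc

    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
        bits = 8
    elif data.dtype in (np.dtype(np.int16), np.dtype(np.int32)):
        bits = _PCM_BITS[data.dtype]
        samples = data.astype(np.float64) / float(2 ** (bits - 1))
    elif np.issubdtype(data.dtype, np.floating):
        samples = np.clip(data.astype(np.float64), -1.0, 1.0)
        bits = data.dtype.itemsize * 8
    else:
        raise FormatError(f"unsupported WAV encoding {data.dtype} in {path!r}")
    return AudioRecording(samples=samples, sample_rate=int(rate),
                          source_id=source_id if source_id is not None else str(path),
                          bit_depth=bits)


def write_recording(path: str, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    pcm = np.clip(np.round(rec.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, rec.sample_rate, pcm)


def select_channel(rec: AudioRecording, channel: int = 0) -> AudioRecording:
    """Extract one channel (default the left, channel 0) as a mono recording.

    Mono input with ``channel=0`` is returned unchanged.
    """
    if rec.samples.ndim == 1:
        if channel != 0:
            raise IndexError(f"mono recording has no channel {channel}")
        return rec
    if not 0 <= channel < rec.samples.shape[1]:
        raise IndexError(
            f"channel {channel} out of range for {rec.samples.shape[1]}-channel recording")
    return replace(rec, samples=np.ascontiguousarray(rec.samples[:, channel]))


def detect_onset(rec: AudioRecording, threshold: float = DEFAULT_THRESHOLD,
                 min_duration_samples: int = 0) -> OnsetResult:
    """Find the first sample whose absolute amplitude strictly exceeds the threshold.

    The comparison is on |amplitude| with strict inequality, so a sample at
    exactly the threshold is not an onset.  With ``min_duration_samples > 0``
    the onset must additionally start a run of at least that many
    consecutive samples with |amplitude| >= threshold — a guard against
    isolated click artifacts, off by default.  If no qualifying sample
    exists the recording is non-speech and the VRT is undefined.
    """
    if rec.samples.ndim != 1:
        raise ValueError("detect_onset requires a mono recording; use select_channel")
    x = rec.samples
    if x.size == 0:
        raise ValueError("empty signal")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if min_duration_samples < 0:
        raise ValueError("min_duration_samples must be >= 0")

    a = np.abs(x)
    exceeds = a > threshold
    if min_duration_samples <= 1:
        candidates = np.flatnonzero(exceeds)
    else:
        d = min_duration_samples
        ge = a >= threshold
        c = np.concatenate(([0], np.cumsum(ge)))
        ok_run = np.zeros_like(exceeds)
        if x.size >= d:
            ok_run[: x.size - d + 1] = (c[d:] - c[:-d]) == d
        candidates = np.flatnonzero(exceeds & ok_run)

    if candidates.size == 0:
        return OnsetResult(rec.source_id, False, None, None, threshold,
                           min_duration_samples)
    onset = int(candidates[0])
    return OnsetResult(rec.source_id, True, onset, onset / rec.sample_rate,
                       threshold, min_duration_samples)


def _results_frame(results: list[dict]) -> pd.DataFrame:
    cols = ["source_id", "is_speech", "onset_index", "vrt_seconds",
            "threshold", "error"]
    frame = pd.DataFrame(results, columns=cols)
    n_ok = int(frame["error"].isna().sum()) if len(frame) else 0
    n_speech = int(frame["is_speech"].eq(True).sum()) if len(frame) else 0
    logger.info("batch_extract: %d recordings, %d readable, %d speech, %d non-speech",
                len(frame), n_ok, n_speech, n_ok - n_speech)
    return frame


def batch_extract(paths: Sequence[str], threshold: float = DEFAULT_THRESHOLD,
                  min_duration_samples: int = 0, channel: int = 0) -> pd.DataFrame:
    """Extract onsets for a batch of WAV files, one row per file in input order.

    Per-file failures are recorded in the ``error`` column and do not abort
    the batch.
    """
    rows = []
    for p in paths:
        try:
            rec = select_channel(read_recording(p), channel)
            res = detect_onset(rec, threshold, min_duration_samples)
            rows.append(dict(source_id=res.source_id, is_speech=res.is_speech,
                             onset_index=res.onset_index, vrt_seconds=res.vrt_seconds,
                             threshold=threshold, error=None))
        except Exception as exc:  # noqa: BLE001 - skip-and-log policy
            rows.append(dict(source_id=str(p), is_speech=None, onset_index=None,
                             vrt_seconds=None, threshold=threshold, error=str(exc)))
    return _results_frame(rows)


def extract_recordings(recordings: Iterable[AudioRecording],
                       threshold: float = DEFAULT_THRESHOLD,
                       min_duration_samples: int = 0,
                       channel: int = 0) -> pd.DataFrame:
    """Like :func:`batch_extract` but over in-memory recordings."""
    rows = []
    for rec in recordings:
        try:
            res = detect_onset(select_channel(rec, channel), threshold,
                               min_duration_samples)
            rows.append(dict(source_id=res.source_id, is_speech=res.is_speech,
                             onset_index=res.onset_index, vrt_seconds=res.vrt_seconds,
                             threshold=threshold, error=None))
        except Exception as exc:  # noqa: BLE001
            rows.append(dict(source_id=rec.source_id, is_speech=None,
                             onset_index=None, vrt_seconds=None,
                             threshold=threshold, error=str(exc)))
    return _results_frame(rows)


# ---------------------------------------------------------------------------
# MFCC audit features


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2.0), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for i in range(n_mels):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


def compute_mfcc(rec: AudioRecording, frame_length: int = 400,
                 hop_length: int = 160, n_coefficients: int = 13,
                 n_mels: int = 26) -> np.ndarray:
    """Mel-frequency cepstral coefficients, one row per frame.

    Frames are ``frame_length`` samples advanced by ``hop_length``; the
    frame count is ``floor((N - frame_length)/hop_length) + 1``.  Hann
    window, power spectrum, triangular mel filterbank, log, then an
    orthonormal DCT-II keeping the first ``n_coefficients`` coefficients.
    Intended for audit plots during manual validation only.
    """
    if rec.samples.ndim != 1:
        raise ValueError("compute_mfcc requires a mono recording")
    x = rec.samples
    if frame_length > x.size:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one frame ({frame_length})")
    if hop_length <= 0 or frame_length <= 0:
        raise ValueError("frame_length and hop_length must be positive")

    n_frames = (x.size - frame_length) // hop_length + 1
    idx = np.arange(frame_length)[None, :] + hop_length * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(frame_length)[None, :]
    power = np.abs(rfft(frames, axis=1)) ** 2
    fb = mel_filterbank(n_mels, frame_length, rec.sample_rate)
    logmel = np.log(power @ fb.T + 1e-12)
    coeffs = dct(logmel, type=2, norm="ortho", axis=1)[:, :n_coefficients]
    return coeffs
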