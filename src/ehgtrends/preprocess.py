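"""Preprocessing of raw electrohysterogram (EHG) recordings.

Turns a raw single-channel recording plus artifact annotations into
artifact-free, band-limited, resampled analysis windows:

1. zero-phase Butterworth band-pass to the physiological 0.1-4 Hz band,
2. anti-aliased polyphase resampling to 20 Hz,
3. removal of annotated artifact intervals (motion, respiration),
4. cutting fixed-length sliding windows (120 s, 50 % overlap) that never
   span an artifact.

Conventions: time is in seconds from recording start; artifact intervals are
half-open ``[start_s, end_s)``; a window that would touch an annotated
interval is discarded entirely, never patched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EHGRecording",
    "ArtifactAnnotation",
    "CleanSegment",
    "AnalysisWindow",
    "bandpass_filter",
    "resample_to",
    "exclude_artifacts",
    "segment_windows",
    "preprocess_recording",
]

#: default analysis band (Hz): keeps fast-wave content, rejects drift and EMG/ECG
DEFAULT_BAND = (0.1, 4.0)
#: default working sampling rate after decimation (Hz)
DEFAULT_FS_OUT = 20.0
#: default sliding-window length (s) and fractional overlap
DEFAULT_WINDOW_S = 120.0
DEFAULT_OVERLAP = 0.5
#: Butterworth order used for all band-pass filters in the pipeline
FILTER_ORDER = 5


@dataclass
class EHGRecording:
    """One channel of uterine surface potential with cohort metadata.

    Amplitude units are arbitrary: every downstream feature is either
    unit-agnostic or reported in the recording's own units.
    """

    samples: np.ndarray
    fs: float
    recording_id: str | None = None
    woman_id: str | None = None
    ga_wog: float | None = None  # gestational age, weeks of gestation
    gestation_type: str | None = None  # "SG" (singleton) or "MG" (multiple)
    stage_label: str | None = None  # "routine", "TNL" or "APL"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.ga_wog is not None and not self.ga_wog > 0:
            raise ValueError(f"ga_wog must be positive, got {self.ga_wog}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def replace_samples(self, samples: np.ndarray, fs: float | None = None) -> "EHGRecording":
        """Copy of this recording with new samples (metadata preserved)."""
        return EHGRecording(
            samples=samples,
            fs=self.fs if fs is None else fs,
            recording_id=self.recording_id,
            woman_id=self.woman_id,
            ga_wog=self.ga_wog,
            gestation_type=self.gestation_type,
            stage_label=self.stage_label,
        )


@dataclass
class ArtifactAnnotation:
    """Half-open artifact intervals ``[start_s, end_s)`` in recording time.

    Intervals are normalised (sorted, merged, non-overlapping) on creation.
    """

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in ivs:
            if not (0 <= a < b):
                raise ValueError(f"invalid interval ({a}, {b}): need 0 <= start < end")
        ivs.sort()
        merged: list[tuple[float, float]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        self.intervals = merged

    @property
    def total_s(self) -> float:
        return sum(b - a for a, b in self.intervals)


@dataclass
class CleanSegment:
    """A contiguous artifact-free stretch of a recording."""

    samples: np.ndarray
    fs: float
    offset_s: float  # seconds from original recording start

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class AnalysisWindow:
    """A fixed-length window cut from a clean segment."""

    samples: np.ndarray
    fs: float
    start_s: float  # seconds from original recording start


def _bandpass_sos(low_hz: float, high_hz: float, fs: float) -> np.ndarray:
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got "
            f"low={low_hz}, high={high_hz}, fs={fs}"
        )
    return signal.butter(FILTER_ORDER, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    recording: EHGRecording,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> EHGRecording:
    """Zero-phase Butterworth band-pass; output has identical length.

    Applied forward-backward (``sosfiltfilt``) so features keep their timing.
    The first/last ~10 s carry the usual zero-phase edge transient and should
    be ignored when asserting gain.
    """
    sos = _bandpass_sos(low_hz, high_hz, recording.fs)
    return recording.replace_samples(signal.sosfiltfilt(sos, recording.samples))


def resample_to(recording: EHGRecording, target_fs: float = DEFAULT_FS_OUT) -> EHGRecording:
    """Anti-aliased polyphase resampling (e.g. 500 Hz -> 20 Hz, factor 25).

    ``target_fs`` must stay above twice the 4 Hz analysis band so the band
    survives decimation. An explicit zero-phase Butterworth low-pass at
    0.35 * target_fs guards the top of the new Nyquist interval, where the
    polyphase filter's own transition band is still open.
    """
    if target_fs >= recording.fs:
        raise ValueError(f"target_fs ({target_fs}) must be below fs ({recording.fs})")
    if target_fs <= 2 * DEFAULT_BAND[1]:
        raise ValueError(f"target_fs ({target_fs}) must exceed twice the 4 Hz band edge")
    sos = signal.butter(8, 0.35 * target_fs, btype="lowpass", fs=recording.fs, output="sos")
    guarded = signal.sosfiltfilt(sos, recording.samples)
    ratio = Fraction(target_fs / recording.fs).limit_denominator(10_000)
    out = signal.resample_poly(guarded, ratio.numerator, ratio.denominator)
    # resample_poly yields ceil(N*up/down); trim to the contracted round(N*ratio)
    n_target = round(recording.samples.size * target_fs / recording.fs)
    return recording.replace_samples(out[:n_target], fs=target_fs)


def exclude_artifacts(
    recording: EHGRecording, annotation: ArtifactAnnotation
) -> list[CleanSegment]:
    """Split a recording into the clean segments between annotated intervals.

    The returned segments partition the complement of the annotation: summed
    clean duration equals total minus annotated duration to within one sample
    period. Empty complements yield an empty list.
    """
    fs = recording.fs
    n = recording.samples.size
    duration = n / fs
    for a, b in annotation.intervals:
        if b > duration + 0.5 / fs:
            raise ValueError(f"interval ({a}, {b}) exceeds recording duration {duration:.3f} s")
    segments: list[CleanSegment] = []
    cursor = 0  # first candidate sample index of the next clean segment
    for a, b in annotation.intervals:
        # samples i with i/fs in [a, b) are excluded
        start_idx = int(np.ceil(a * fs - 1e-9))
        end_idx = min(n, int(np.ceil(b * fs - 1e-9)))
        if start_idx > cursor:
            segments.append(
                CleanSegment(recording.samples[cursor:start_idx], fs, cursor / fs)
            )
        cursor = max(cursor, end_idx)
    if cursor < n:
        segments.append(CleanSegment(recording.samples[cursor:n], fs, cursor / fs))
    return segments


def segment_windows(
    segments: Sequence[CleanSegment],
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> list[AnalysisWindow]:
    """Cut fixed-length sliding windows from clean segments.

    A segment of duration D yields ``floor((D - window_s)/step) + 1`` windows
    with ``step = window_s * (1 - overlap)`` when D >= window_s, else none.
    Windows are cut only inside clean segments, so none spans an artifact.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if not window_s > 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    step_s = window_s * (1.0 - overlap)
    windows: list[AnalysisWindow] = []
    for seg in segments:
        n_win_samples = round(window_s * seg.fs)
        step_samples = step_s * seg.fs
        n_avail = len(seg.samples)
        if n_avail < n_win_samples:
            continue
        k = 0
        while True:
            start = round(k * step_samples)
            if start + n_win_samples > n_avail:
                break
            windows.append(
                AnalysisWindow(
                    samples=seg.samples[start : start + n_win_samples],
                    fs=seg.fs,
                    start_s=seg.offset_s + start / seg.fs,
                )
            )
            k += 1
    return windows


#: guard margin (s) added around annotated intervals in the full pipeline:
#: the zero-phase filters smear high-amplitude artifact energy a few time
#: constants (the 0.1 Hz edge rings for seconds) past the annotation edges
DEFAULT_ARTIFACT_PAD_S = 10.0


def preprocess_recording(
    recording: EHGRecording,
    annotation: ArtifactAnnotation | None = None,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    target_fs: float = DEFAULT_FS_OUT,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    artifact_pad_s: float = DEFAULT_ARTIFACT_PAD_S,
) -> list[AnalysisWindow]:
    """Full chain: band-pass at the native rate, resample, drop artifacts, window.

    Annotated intervals are widened by ``artifact_pad_s`` on each side before
    exclusion, so filter ringing leaking out of an artifact never reaches an
    analysis window.
    """
    if annotation is None:
        annotation = ArtifactAnnotation([])
    if annotation.intervals and artifact_pad_s > 0:
        duration = recording.duration_s
        annotation = ArtifactAnnotation(
            [
                (max(0.0, a - artifact_pad_s), min(duration, b + artifact_pad_s))
                for a, b in annotation.intervals
            ]
        )
    filtered = bandpass_filter(recording, low_hz, high_hz)
    if target_fs < recording.fs:
        filtered = resample_to(filtered, target_fs)
    segments = exclude_artifacts(filtered, annotation)
    return segment_windows(segments, window_s, overlap)
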