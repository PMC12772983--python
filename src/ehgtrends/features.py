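"""Whole-window EHG features and per-recording aggregation.

Four features per 120-s analysis window, each a standard descriptor of
uterine myoelectrical activity:

- **PPA** — peak-to-peak amplitude in the 0.1-4 Hz band; proxy for
  contraction intensity (units of the recording).
- **KHE** — Pearson kurtosis of the Hilbert (analytic-signal) envelope in the
  0.1-4 Hz band; proxy for impulsiveness/burstiness (unitless; Gaussian
  envelope background gives the Rayleigh value ~3.245).
- **MDF** — median frequency of the power spectrum restricted to 0.2-1 Hz
  (reduces cardiac interference); proxy for cellular excitability (Hz).
- **SampEn** — sample entropy (m=2, r=0.2*SD) of the window re-filtered to the
  fast-wave-high band 0.34-4 Hz; lower values mean more regular activity.

A recording is summarised by the median of each feature across its windows.
Undefined values (e.g. zero-variance windows) are flagged as NaN and excluded
per feature at aggregation, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from scipy.spatial import cKDTree

from .preprocess import (
    AnalysisWindow,
    ArtifactAnnotation,
    EHGRecording,
    FILTER_ORDER,
    preprocess_recording,
)

__all__ = [
    "WindowFeatures",
    "RecordingSummary",
    "peak_to_peak",
    "hilbert_envelope_kurtosis",
    "median_frequency",
    "sample_entropy",
    "window_features",
    "summarize_recording",
    "extract_recording_features",
    "FEATURE_NAMES",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("ppa", "khe", "mdf", "sampen")

#: MDF integration band (Hz)
DEFAULT_MDF_BAND = (0.2, 1.0)
#: fast-wave-high band used for SampEn (Hz)
DEFAULT_SAMPEN_BAND = (0.34, 4.0)
#: SampEn template length and tolerance factor (times window SD)
DEFAULT_M = 2
DEFAULT_R_FACTOR = 0.2
#: Welch segment length for the MDF spectrum (samples; 12.8 s at 20 Hz)
MDF_NPERSEG = 256
#: envelope trim before kurtosis (s per end), suppresses analytic-signal edge
#: transients that would inflate the fourth moment
KHE_EDGE_TRIM_S = 2.0


@dataclass
class WindowFeatures:
    """Feature vector of one analysis window (NaN marks undefined)."""

    ppa: float
    khe: float
    mdf: float
    sampen: float
    start_s: float


@dataclass
class RecordingSummary:
    """Per-recording medians of the window features, with cohort metadata."""

    recording_id: str | None
    woman_id: str | None
    ga_wog: float | None
    gestation_type: str | None
    stage_label: str | None
    median_ppa: float
    median_khe: float
    median_mdf: float
    median_sampen: float
    n_windows: int


def peak_to_peak(window: AnalysisWindow | np.ndarray) -> float:
    """max(samples) - min(samples); the window must already be band-limited."""
    x = window.samples if isinstance(window, AnalysisWindow) else np.asarray(window, float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.max(x) - np.min(x))


def hilbert_envelope_kurtosis(window: AnalysisWindow | np.ndarray, fs: float | None = None) -> float:
    """Pearson kurtosis (Gaussian -> 3) of the analytic-signal magnitude.

    The envelope's first/last ``KHE_EDGE_TRIM_S`` seconds are discarded before
    the moment computation. Zero-variance envelopes return NaN.
    """
    if isinstance(window, AnalysisWindow):
        x, fs = window.samples, window.fs
    else:
        x = np.asarray(window, float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if x.size == 0:
        raise ValueError("empty window")
    env = np.abs(sp_signal.hilbert(x))
    trim = int(round(KHE_EDGE_TRIM_S * fs))
    if 2 * trim < env.size:
        env = env[trim : env.size - trim]
    if np.std(env) == 0:
        logger.warning("zero-variance envelope: KHE undefined")
        return float("nan")
    return float(sp_stats.kurtosis(env, fisher=False, bias=True))


def median_frequency(
    window: AnalysisWindow | np.ndarray,
    fs: float | None = None,
    band: tuple[float, float] = DEFAULT_MDF_BAND,
    nperseg: int = MDF_NPERSEG,
) -> float:
    """Frequency splitting in-band Welch spectral power into equal halves.

    The PSD (Hann taper, 50 % segment overlap) is restricted to ``band`` and
    the half-power crossing of the cumulative spectrum is located by linear
    interpolation between frequency bins. Zero in-band power returns NaN.
    """
    if isinstance(window, AnalysisWindow):
        x, fs = window.samples, window.fs
    else:
        x = np.asarray(window, float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if x.size == 0:
        raise ValueError("empty window")
    nperseg = min(nperseg, x.size)
    freqs, psd = sp_signal.welch(x, fs=fs, nperseg=nperseg, window="hann")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    f, p = freqs[in_band], psd[in_band]
    total = float(np.sum(p))
    if total <= 0 or f.size == 0:
        logger.warning("zero in-band power: MDF undefined")
        return float("nan")
    cum = np.cumsum(p)
    half = 0.5 * total
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(f[0])
    # linear interpolation of the crossing inside bin k
    frac = (half - cum[k - 1]) / p[k] if p[k] > 0 else 0.5
    return float(f[k - 1] + frac * (f[k] - f[k - 1]))


def _template_pairs(x: np.ndarray, m: int, r: float) -> int:
    """Unordered template pairs of length m within Chebyshev distance r.

    Uses a k-d tree neighbour count; the count includes self-pairs, which are
    removed. Distance comparison is ``<= r``, the classical convention.
    """
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    tree = cKDTree(emb)
    total = tree.count_neighbors(tree, r, p=np.inf)
    return int(total - len(emb)) // 2


def sample_entropy(
    x: Sequence[float] | AnalysisWindow,
    m: int = DEFAULT_M,
    r_factor: float = DEFAULT_R_FACTOR,
) -> float:
    """Sample entropy: -ln(A/B) over template matches, self-matches excluded.

    B counts pairs of length-``m`` templates within Chebyshev distance
    ``r = r_factor * SD(x)``; A the same for length ``m+1``. Both counts use
    the N-m-1 templates that admit an (m+1)-extension, so B >= A always.
    Returns NaN when the signal is constant (r = 0) or when A or B is zero.

    The caller is expected to band-limit the input (fast-wave-high 0.34-4 Hz
    in this pipeline) before calling.
    """
    if isinstance(x, AnalysisWindow):
        x = x.samples
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {n}")
    sd = float(np.std(x))
    if sd == 0:
        logger.warning("constant window: SampEn undefined")
        return float("nan")
    r = r_factor * sd
    b = _template_pairs(x[: n - 1], m, r)  # length-m templates, last one dropped
    a = _template_pairs(x, m + 1, r)
    if a == 0 or b == 0:
        logger.warning("no template matches (A=%d, B=%d): SampEn undefined", a, b)
        return float("nan")
    return float(-np.log(a / b))


def window_features(
    window: AnalysisWindow,
    mdf_band: tuple[float, float] = DEFAULT_MDF_BAND,
    sampen_band: tuple[float, float] = DEFAULT_SAMPEN_BAND,
    m: int = DEFAULT_M,
    r_factor: float = DEFAULT_R_FACTOR,
) -> WindowFeatures:
    """All four features of one (0.1-4 Hz band-limited) analysis window.

    SampEn is computed on a zero-phase Butterworth re-filtered copy restricted
    to the fast-wave-high band.
    """
    sos = sp_signal.butter(
        FILTER_ORDER, list(sampen_band), btype="bandpass", fs=window.fs, output="sos"
    )
    fwh = sp_signal.sosfiltfilt(sos, window.samples)
    return WindowFeatures(
        ppa=peak_to_peak(window),
        khe=hilbert_envelope_kurtosis(window),
        mdf=median_frequency(window, band=mdf_band),
        sampen=sample_entropy(fwh, m=m, r_factor=r_factor),
        start_s=window.start_s,
    )


def summarize_recording(
    features: Sequence[WindowFeatures],
    recording: EHGRecording | None = None,
) -> RecordingSummary:
    """Median of each feature across windows; NaN windows excluded per feature.

    Raises ``ValueError`` for zero windows — the recording is excluded
    upstream with a logged reason rather than summarised.
    """
    if len(features) == 0:
        raise ValueError("recording yielded zero analysis windows; excluded")

    def med(vals: list[float]) -> float:
        arr = np.asarray(vals, float)
        arr = arr[~np.isnan(arr)]
        return float(np.median(arr)) if arr.size else float("nan")

    meta = recording or EHGRecording(np.zeros(1), 1.0)
    return RecordingSummary(
        recording_id=meta.recording_id,
        woman_id=meta.woman_id,
        ga_wog=meta.ga_wog,
        gestation_type=meta.gestation_type,
        stage_label=meta.stage_label,
        median_ppa=med([f.ppa for f in features]),
        median_khe=med([f.khe for f in features]),
        median_mdf=med([f.mdf for f in features]),
        median_sampen=med([f.sampen for f in features]),
        n_windows=len(features),
    )


def extract_recording_features(
    recording: EHGRecording,
    annotation: ArtifactAnnotation | None = None,
    **kwargs,
) -> tuple[list[WindowFeatures], RecordingSummary]:
    """Preprocess a raw recording and compute window features plus the summary.

    Keyword arguments are forwarded to :func:`window_features`.
    """
    windows = preprocess_recording(recording, annotation)
    feats = [window_features(w, **kwargs) for w in windows]
    return feats, summarize_recording(feats, recording)
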