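"""Plain-text interchange formats.

* signal CSV — two columns ``time_s,value``, one row per sample;
* annotation CSV — columns ``start_s,end_s``, half-open intervals in seconds;
* cohort CSV — one row per recording with metadata (and, after feature
  extraction, the per-recording median features).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ArtifactAnnotation, EHGRecording

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_annotation_csv",
    "read_annotation_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]


def write_signal_csv(recording: EHGRecording, path: str | Path) -> None:
    t = np.arange(recording.samples.size) / recording.fs
    pd.DataFrame({"time_s": t, "value": recording.samples}).to_csv(path, index=False)


def read_signal_csv(path: str | Path, **metadata) -> EHGRecording:
    """Read a two-column signal CSV; fs is inferred from the time column."""
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value, got {list(df.columns)}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return EHGRecording(samples=df["value"].to_numpy(float), fs=1.0 / dt[0], **metadata)


def write_annotation_csv(annotation: ArtifactAnnotation, path: str | Path) -> None:
    pd.DataFrame(annotation.intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


def read_annotation_csv(path: str | Path) -> ArtifactAnnotation:
    df = pd.read_csv(path)
    if df.empty:
        return ArtifactAnnotation([])
    return ArtifactAnnotation(list(zip(df["start_s"], df["end_s"])))


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
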