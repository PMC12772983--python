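"""Synthetic EHG recordings and cohorts.

No public EHG dataset matches the cohort structure this pipeline analyses
(third-trimester singleton vs twin pregnancies with repeated visits), so the
package ships a seeded generator that emulates the signal and cohort
structure the analysis assumes:

* ≥30-minute single-channel recordings sampled at 500 Hz;
* contraction bursts whose content lives in the two fast-wave bands —
  fast-wave-low (FWL, 0.13-0.26 Hz, propagation-related) and fast-wave-high
  (FWH, 0.34-4 Hz, excitability-related) — over a continuous low-level
  background of the same fast-wave content (myometrial activity does not
  vanish between contractions);
* baseline drift below 0.1 Hz and broadband instrumentation noise;
* cohort-level gestational-age (GA) trends: burst amplitude (PPA) rising
  with GA, bursts growing more prominent relative to the background
  (envelope kurtosis rising), waveform regularity rising with GA (sample
  entropy falling), with twin-pregnancy offsets concentrated before 32 weeks
  of gestation.

The activity model is ``amplitude * (background_level + envelope) * content``
where the envelope is a sum of Gaussian-tapered bursts and the content mixes
two unit-variance narrowband processes: band-limited Gaussian noise for FWL,
and a phase-jittered oscillator (band-limited after synthesis) for FWH. The
``regularity`` knob scales the oscillator's phase-noise intensity, giving
monotone control of sample entropy; ``background_level`` sets how strongly
bursts stand out of the ongoing activity, giving scale-free control of the
envelope kurtosis. Neither claims physiological realism beyond band content
and burstiness.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .preprocess import ArtifactAnnotation, EHGRecording, FILTER_ORDER

__all__ = [
    "SignalSimConfig",
    "CohortSimConfig",
    "simulate_recording",
    "simulate_cohort",
    "iter_cohort",
    "simulate_cohort_features",
    "inject_artifacts",
]

logger = logging.getLogger(__name__)

#: maximum phase-noise intensity of the FWH oscillator (rad per sqrt-second),
#: reached at regularity = 0
_JITTER_MAX = 2.0
#: number of sinusoidal baseline-drift components and their frequency range (Hz)
_DRIFT_COMPONENTS = 3
_DRIFT_BAND = (0.01, 0.08)


@dataclass
class SignalSimConfig:
    """Parameters of one simulated EHG recording (amplitudes in arbitrary units)."""

    duration_s: float = 1800.0
    fs: float = 500.0
    burst_rate: float = 0.7  # bursts per minute (before non-overlap thinning)
    burst_duration_s: float = 50.0
    burst_amplitude: float = 0.4
    background_level: float = 0.5  # continuous activity, fraction of burst peak
    fwl_band: tuple[float, float] = (0.13, 0.26)
    fwh_band: tuple[float, float] = (0.34, 4.0)
    fwh_fraction: float = 0.6  # share of burst power in the FWH band
    fwh_carrier_hz: float = 0.55
    baseline_drift_amplitude: float = 0.5
    noise_sd: float = 0.4  # broadband; ~0.05 remains in the 0.1-4 Hz band at 500 Hz
    regularity: float = 0.5  # in [0,1]; higher -> less jitter -> lower SampEn
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fwh_fraction <= 1:
            raise ValueError(f"fwh_fraction must be in [0,1], got {self.fwh_fraction}")
        if not 0 <= self.regularity <= 1:
            raise ValueError(f"regularity must be in [0,1], got {self.regularity}")
        for name in (
            "burst_amplitude",
            "background_level",
            "baseline_drift_amplitude",
            "noise_sd",
            "burst_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for band in (self.fwl_band, self.fwh_band):
            if not band[0] < band[1]:
                raise ValueError(f"invalid band edges {band}: low must be < high")
        if not self.fs > 2 * self.fwh_band[1]:
            raise ValueError(
                f"fs={self.fs} must exceed twice the upper FWH edge {self.fwh_band[1]}"
            )
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")


def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _burst_onsets(rng: np.random.Generator, cfg: SignalSimConfig) -> list[float]:
    """Poisson onsets thinned to forbid overlap: next onset waits for burst end."""
    if cfg.burst_rate <= 0:
        return []
    onsets: list[float] = []
    t = 0.0
    rate = cfg.burst_rate / 60.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t + cfg.burst_duration_s > cfg.duration_s:
            break
        onsets.append(t)
        t += cfg.burst_duration_s
    return onsets


def simulate_recording(
    config: SignalSimConfig,
    ga_wog: float | None = None,
    gestation_type: str | None = None,
    recording_id: str | None = None,
    woman_id: str | None = None,
    stage_label: str | None = None,
) -> EHGRecording:
    """Simulate one recording: bursts + baseline drift + broadband noise.

    The same random variates are drawn in the same order for any amplitude
    settings, so two runs with the same seed differ only through the
    parameters that changed (e.g. doubling ``burst_amplitude`` exactly
    doubles the burst component).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = round(cfg.duration_s * cfg.fs)
    t = np.arange(n) / cfg.fs

    onsets = _burst_onsets(rng, cfg)

    # FWL: band-limited Gaussian noise, unit SD
    white = rng.standard_normal(n)
    sos_l = sp_signal.butter(FILTER_ORDER, list(cfg.fwl_band), "bandpass", fs=cfg.fs, output="sos")
    fwl = _unit_sd(sp_signal.sosfiltfilt(sos_l, white))

    # FWH: phase-jittered carrier, band-limited after synthesis so its power
    # stays inside fwh_band even at regularity = 0
    phase_steps = rng.standard_normal(n)
    phi0 = rng.uniform(0, 2 * np.pi)
    sigma_j = _JITTER_MAX * (1.0 - cfg.regularity)
    phi = np.cumsum(phase_steps) * (sigma_j / np.sqrt(cfg.fs))
    carrier = np.cos(2 * np.pi * cfg.fwh_carrier_hz * t + phi0 + phi)
    sos_h = sp_signal.butter(FILTER_ORDER, list(cfg.fwh_band), "bandpass", fs=cfg.fs, output="sos")
    fwh = _unit_sd(sp_signal.sosfiltfilt(sos_h, carrier))

    # Gaussian-tapered burst envelope
    env = np.zeros(n)
    sigma_e = cfg.burst_duration_s / 5.0
    for onset in onsets:
        c = onset + cfg.burst_duration_s / 2.0
        i0 = int(onset * cfg.fs)
        i1 = min(n, int((onset + cfg.burst_duration_s) * cfg.fs))
        tt = t[i0:i1]
        env[i0:i1] += np.exp(-0.5 * ((tt - c) / sigma_e) ** 2)

    content = np.sqrt(1.0 - cfg.fwh_fraction) * fwl + np.sqrt(cfg.fwh_fraction) * fwh
    bursts = cfg.burst_amplitude * (cfg.background_level + env) * content

    # slow sinusoidal baseline drift (< 0.1 Hz)
    drift_f = rng.uniform(*_DRIFT_BAND, size=_DRIFT_COMPONENTS)
    drift_ph = rng.uniform(0, 2 * np.pi, size=_DRIFT_COMPONENTS)
    drift_w = rng.uniform(0.5, 1.0, size=_DRIFT_COMPONENTS)
    drift_w = drift_w / drift_w.sum() * cfg.baseline_drift_amplitude
    drift = sum(
        w * np.sin(2 * np.pi * f * t + p) for w, f, p in zip(drift_w, drift_f, drift_ph)
    )

    noise = cfg.noise_sd * rng.standard_normal(n)

    return EHGRecording(
        samples=bursts + drift + noise,
        fs=cfg.fs,
        recording_id=recording_id,
        woman_id=woman_id,
        ga_wog=ga_wog,
        gestation_type=gestation_type,
        stage_label=stage_label,
    )


def inject_artifacts(
    recording: EHGRecording, fraction: float, seed: int
) -> tuple[EHGRecording, ArtifactAnnotation]:
    """Overwrite random intervals with clipped high-amplitude ramps.

    Returns a modified copy plus half-open annotation intervals covering at
    least ``fraction`` of the duration. The artifact morphology is crude by
    design: annotated intervals are excluded downstream, never repaired.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0:
        return recording.replace_samples(recording.samples.copy()), ArtifactAnnotation([])
    rng = np.random.default_rng(seed)
    duration = recording.duration_s
    target = fraction * duration
    intervals: list[tuple[float, float]] = []
    covered = 0.0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        d = rng.uniform(30.0, 90.0)  # motion artifacts come as long episodes
        if d > duration:
            d = duration * 0.5
        start = rng.uniform(0.0, duration - d)
        cand = (start, start + d)
        if any(cand[0] < b + 1.0 and cand[1] > a - 1.0 for a, b in intervals):
            continue
        intervals.append(cand)
        covered += d
    if covered < target:
        raise RuntimeError("could not place enough non-overlapping artifact intervals")
    annotation = ArtifactAnnotation(intervals)

    samples = recording.samples.copy()
    amp = 20.0 * max(np.std(samples), 1e-12)
    fs = recording.fs
    for a, b in annotation.intervals:
        i0, i1 = int(a * fs), min(samples.size, int(b * fs))
        tt = np.arange(i1 - i0) / fs
        ramp = amp * 1.5 * sp_signal.sawtooth(2 * np.pi * 0.3 * tt)
        samples[i0:i1] = np.clip(ramp, -amp, amp)
    return recording.replace_samples(samples), annotation


# --- cohort-level generation -------------------------------------------------

def _sg_amplitude_trend(ga: float) -> float:
    """Singleton burst amplitude: steady rise through the third trimester."""
    return 0.22 + 0.0253 * (ga - 26.0)


def _mg_amplitude_trend(ga: float) -> float:
    """Twin burst amplitude: earlier activation, near-plateau beyond 32 WoG."""
    return 0.42 + 0.0045 * (ga - 26.0)


def _sg_regularity_trend(ga: float) -> float:
    """Singleton waveform regularity rises with GA (SampEn falls)."""
    return float(np.clip(0.25 + 0.04 * (ga - 26.0), 0.0, 1.0))


def _mg_regularity_trend(ga: float) -> float:
    """Twins: more regular early, only a mild further rise."""
    return float(np.clip(0.55 + 0.0073 * (ga - 26.0), 0.0, 1.0))


def _sg_background_trend(ga: float) -> float:
    """Singleton bursts stand out more with advancing GA (KHE rises)."""
    return float(np.clip(0.80 - 0.0447 * (ga - 26.0), 0.1, 1.0))


def _mg_background_trend(ga: float) -> float:
    """Twins: already burst-dominant early, no further change."""
    return 0.42


@dataclass
class CohortSimConfig:
    """Cohort structure and GA-trend programming for the synthetic study.

    Defaults mirror the target study design: ~53 singleton (SG) and ~63 twin
    (MG) women, one to three visits each, GA 26-41 weeks for SG and 26-37 for
    MG, with amplitude and regularity trends per gestation type and twin
    offsets concentrated before 32 weeks.
    """

    n_women_sg: int = 53
    n_women_mg: int = 63
    recordings_per_woman: tuple[int, int] = (1, 3)
    ga_range_sg: tuple[float, float] = (26.0, 41.0)
    ga_range_mg: tuple[float, float] = (26.0, 37.0)
    amplitude_trend_sg: Callable[[float], float] = _sg_amplitude_trend
    amplitude_trend_mg: Callable[[float], float] = _mg_amplitude_trend
    regularity_trend_sg: Callable[[float], float] = _sg_regularity_trend
    regularity_trend_mg: Callable[[float], float] = _mg_regularity_trend
    background_trend_sg: Callable[[float], float] = _sg_background_trend
    background_trend_mg: Callable[[float], float] = _mg_background_trend
    woman_effect_sd: float = 0.12  # lognormal SD of the per-woman amplitude factor
    term_apl_fraction: float = 0.5  # share of GA>=37 recordings labelled APL (rest TNL)
    signal: SignalSimConfig = field(default_factory=SignalSimConfig)
    shared_signal_seed: bool = False  # True: identical variates for every recording
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women_sg <= 0 or self.n_women_mg <= 0:
            raise ValueError("n_women_sg and n_women_mg must be positive")
        lo, hi = self.recordings_per_woman
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid recordings_per_woman range {self.recordings_per_woman}")


def iter_cohort(config: CohortSimConfig) -> Iterator[tuple[EHGRecording, dict]]:
    """Yield (recording, metadata-row) pairs one at a time.

    Streaming counterpart of :func:`simulate_cohort`; a full default cohort of
    30-minute recordings at 500 Hz does not fit comfortably in memory at once.
    """
    master = np.random.default_rng(config.seed)
    seed_seq = np.random.SeedSequence(config.seed)

    for gtype, n_women, ga_range in (
        ("SG", config.n_women_sg, config.ga_range_sg),
        ("MG", config.n_women_mg, config.ga_range_mg),
    ):
        amp_trend = config.amplitude_trend_sg if gtype == "SG" else config.amplitude_trend_mg
        reg_trend = config.regularity_trend_sg if gtype == "SG" else config.regularity_trend_mg
        bg_trend = config.background_trend_sg if gtype == "SG" else config.background_trend_mg
        for w in range(n_women):
            woman_id = f"{gtype}W{w:03d}"
            woman_factor = float(np.exp(master.normal(0.0, config.woman_effect_sd)))
            lo, hi = config.recordings_per_woman
            n_rec = int(master.integers(lo, hi + 1))
            gas = np.sort(master.uniform(ga_range[0], ga_range[1], size=n_rec))
            for k, ga in enumerate(gas):
                ga = float(ga)
                if config.shared_signal_seed:
                    rec_seed = config.signal.seed
                else:
                    rec_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                if ga >= 37.0:
                    stage = "APL" if master.uniform() < config.term_apl_fraction else "TNL"
                else:
                    stage = "routine"
                sig_cfg = replace(
                    config.signal,
                    burst_amplitude=amp_trend(ga) * woman_factor,
                    regularity=float(np.clip(reg_trend(ga), 0.0, 1.0)),
                    background_level=float(np.clip(bg_trend(ga), 0.0, None)),
                    seed=rec_seed,
                )
                rid = f"{gtype}-{w:03d}-{k}"
                rec = simulate_recording(
                    sig_cfg,
                    ga_wog=ga,
                    gestation_type=gtype,
                    recording_id=rid,
                    woman_id=woman_id,
                    stage_label=stage,
                )
                yield rec, {
                    "recording_id": rid,
                    "woman_id": woman_id,
                    "ga_wog": ga,
                    "gestation_type": gtype,
                    "stage_label": stage,
                }


def simulate_cohort(config: CohortSimConfig) -> tuple[list[EHGRecording], pd.DataFrame]:
    """Materialise a whole cohort plus its metadata table.

    Deterministic given the seed. For the default cohort size prefer
    :func:`iter_cohort` or :func:`simulate_cohort_features`, which stream.
    """
    recordings: list[EHGRecording] = []
    rows: list[dict] = []
    for rec, row in iter_cohort(config):
        recordings.append(rec)
        rows.append(row)
    return recordings, pd.DataFrame(rows)


def simulate_cohort_features(
    config: CohortSimConfig,
    artifact_fraction: float = 0.0,
    **feature_kwargs,
) -> pd.DataFrame:
    """Generate the cohort and run preprocessing + feature extraction per
    recording, discarding raw samples as it goes.

    Returns the recording-level cohort table (one row per recording with
    median features), the input expected by the balancing and trend stages.
    ``artifact_fraction`` > 0 additionally injects annotated artifacts and
    excludes them, emulating a visual-rejection step.
    """
    from .features import extract_recording_features  # local import: heavier module

    rows: list[dict] = []
    art_seed_seq = np.random.SeedSequence(config.seed + 1)
    for rec, row in iter_cohort(config):
        annotation = None
        if artifact_fraction > 0:
            aseed = int(art_seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            rec, annotation = inject_artifacts(rec, artifact_fraction, aseed)
        try:
            _, summary = extract_recording_features(rec, annotation, **feature_kwargs)
        except ValueError as exc:
            logger.warning("recording %s excluded: %s", row["recording_id"], exc)
            continue
        rows.append(
            {
                **row,
                "median_ppa": summary.median_ppa,
                "median_khe": summary.median_khe,
                "median_mdf": summary.median_mdf,
                "median_sampen": summary.median_sampen,
                "n_windows": summary.n_windows,
            }
        )
    return pd.DataFrame(rows)
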