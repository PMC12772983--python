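import numpy as np
import pandas as pd
import pytest

from ehgtrends import CohortSimConfig, SignalSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_signal_config():
    """A 10-minute recording config, long enough for several windows."""
    return SignalSimConfig(duration_s=600.0, seed=42)


@pytest.fixture
def tiny_cohort_config():
    """A cohort small enough for end-to-end unit tests."""
    return CohortSimConfig(n_women_sg=3, n_women_mg=3, recordings_per_woman=(1, 2), seed=11)


def make_summary_table(
    n_sg: int = 40,
    n_mg: int = 40,
    seed: int = 0,
    ga_range_sg: tuple = (26.0, 41.0),
    ga_range_mg: tuple = (26.0, 37.0),
    sg_slopes: dict | None = None,
    mg_slopes: dict | None = None,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Synthetic recording-level summary table with linear GA trends.

    Bypasses signal simulation entirely: feature medians are drawn directly
    from programmed linear maps of GA plus optional Gaussian noise. Used to
    test balancing and trend statistics in isolation.
    """
    rng = np.random.default_rng(seed)
    sg_slopes = sg_slopes or {}
    mg_slopes = mg_slopes or {}
    rows = []
    for gtype, n, ga_range, slopes in (
        ("SG", n_sg, ga_range_sg, sg_slopes),
        ("MG", n_mg, ga_range_mg, mg_slopes),
    ):
        gas = rng.uniform(ga_range[0], ga_range[1], size=n)
        for i, ga in enumerate(gas):
            stage_label = "routine"
            if ga >= 37.0:
                stage_label = "TNL" if rng.uniform() < 0.5 else "APL"
            row = {
                "recording_id": f"{gtype}-{i}",
                "woman_id": f"{gtype}W{i}",
                "ga_wog": float(ga),
                "gestation_type": gtype,
                "stage_label": stage_label,
            }
            for feat, base in (
                ("median_ppa", 1.0),
                ("median_khe", 4.0),
                ("median_mdf", 0.5),
                ("median_sampen", 1.0),
            ):
                slope = slopes.get(feat, 0.0)
                row[feat] = base + slope * (ga - 26.0) + noise_sd * rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)
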