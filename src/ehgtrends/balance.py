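"""Gestational-age balancing of the two gestation-type groups.

Recordings from singleton (SG) and twin (MG) pregnancies are rarely
collected at the same gestational ages, and every feature here trends with
GA, so a raw between-group comparison confounds gestation type with age.
Stratified dynamic downsampling removes the confound: GA is cut into
fixed-width bins, and within each bin the larger group is randomly
downsampled (without replacement, seeded) to the smaller group's count.
Bins where either group is empty are dropped from both groups — an
unmatched stratum cannot support a between-group contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BalanceReport", "stratified_dynamic_sampling"]


@dataclass
class BalanceReport:
    """Per-bin before/after counts and the removed recording ids."""

    bin_edges: list[float]
    before: dict[str, list[int]]  # group -> per-bin counts
    after: dict[str, list[int]]
    removed_recording_ids: list[str]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges": self.bin_edges,
                "before": self.before,
                "after": self.after,
                "removed_recording_ids": self.removed_recording_ids,
                "seed": self.seed,
            },
            indent=2,
        )


def stratified_dynamic_sampling(
    cohort: pd.DataFrame,
    bin_width_wog: float = 1.0,
    seed: int = 0,
    group_col: str = "gestation_type",
    ga_col: str = "ga_wog",
) -> tuple[pd.DataFrame, BalanceReport]:
    """Equalise per-GA-bin group counts by seeded downsampling.

    Within every ``bin_width_wog``-week GA bin the larger group is sampled
    down (without replacement) to the smaller group's count; bins with one
    group absent are dropped entirely. Retained rows are returned unchanged,
    in their original order. A single seeded generator is consumed in
    ascending bin order, so the retained set is reproducible.
    """
    if ga_col not in cohort.columns or group_col not in cohort.columns:
        raise ValueError(f"cohort must have '{ga_col}' and '{group_col}' columns")
    if cohort[ga_col].isna().any():
        raise ValueError(f"cohort has missing {ga_col} values")
    if not bin_width_wog > 0:
        raise ValueError("bin_width_wog must be positive")
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")

    ga = cohort[ga_col].to_numpy(float)
    lo = np.floor(ga.min() / bin_width_wog) * bin_width_wog
    hi = np.ceil(ga.max() / bin_width_wog) * bin_width_wog
    if hi <= lo:
        hi = lo + bin_width_wog
    edges = np.arange(lo, hi + bin_width_wog / 2, bin_width_wog)
    # right-open bins [e_i, e_{i+1}); top edge inclusive so the max GA is kept
    bin_idx = np.clip(np.searchsorted(edges, ga, side="right") - 1, 0, len(edges) - 2)

    rng = np.random.default_rng(seed)
    keep_mask = np.zeros(len(cohort), dtype=bool)
    before: dict[str, list[int]] = {g: [] for g in groups}
    after: dict[str, list[int]] = {g: [] for g in groups}
    positions = np.arange(len(cohort))
    for b in range(len(edges) - 1):
        in_bin = bin_idx == b
        counts = {g: int(np.sum(in_bin & (cohort[group_col].to_numpy() == g))) for g in groups}
        for g in groups:
            before[g].append(counts[g])
        if min(counts.values()) == 0:
            for g in groups:
                after[g].append(0)
            continue
        n_keep = min(counts.values())
        for g in groups:
            pos = positions[in_bin & (cohort[group_col].to_numpy() == g)]
            if len(pos) > n_keep:
                pos = rng.choice(pos, size=n_keep, replace=False)
            keep_mask[pos] = True
            after[g].append(n_keep)

    balanced = cohort.loc[keep_mask].copy()
    removed = cohort.loc[~keep_mask]
    removed_ids = (
        removed["recording_id"].astype(str).tolist()
        if "recording_id" in cohort.columns
        else [str(i) for i in removed.index]
    )
    report = BalanceReport(
        bin_edges=[float(e) for e in edges],
        before=before,
        after=after,
        removed_recording_ids=removed_ids,
        seed=seed,
    )
    return balanced, report
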