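"""Trend statistics: stage stratification, GAM smooths, Spearman, Wilcoxon.

The analysis treats recordings as the unit of observation (repeated visits
from the same woman enter as independent rows — a simplification that is
logged as a caveat). Routine third-trimester recordings are stratified at
the clinically standard thresholds into Early3T (GA < 32 weeks) and Late3T
(32 <= GA < 37); term recordings keep their metadata labels TNL
(term-not-in-labour) or APL (active phase of labour).

For each feature and gestation type the pipeline produces

* a penalized-spline GAM smooth of the feature on GA with 95 % pointwise
  confidence bands (Gaussian response, identity link, GCV-selected penalty),
* a Spearman rank correlation with GA, and
* two Wilcoxon rank-sum comparison families at alpha = 0.05: SG vs MG within
  each stage, and stage vs stage within each gestation type.

Raw p-values are reported (no multiple-testing correction), matching common
practice for exploratory stage-wise EHG comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "TrendFit",
    "CorrelationResult",
    "GroupComparison",
    "AnalysisReport",
    "stratify_by_stage",
    "spearman_ga_correlation",
    "wilcoxon_compare",
    "fit_gam_trend",
    "run_full_analysis",
    "STAGE_ORDER",
]

logger = logging.getLogger(__name__)

#: GA thresholds (weeks of gestation) splitting the routine third trimester
EARLY3T_UPPER = 32.0
LATE3T_UPPER = 37.0
STAGE_ORDER = ("Early3T", "Late3T", "TNL", "APL")
DEFAULT_ALPHA = 0.05
#: maximum spline basis size for the GAM smooth
GAM_MAX_DF = 10
#: combined group size up to which Wilcoxon p-values are enumerated exactly
WILCOXON_EXACT_N = 20
#: Spearman p-value regimes: exact enumeration, seeded permutation, t-approx
SPEARMAN_EXACT_N = 8
SPEARMAN_PERM_N = 30
SPEARMAN_PERM_RESAMPLES = 10_000


@dataclass
class TrendFit:
    """A fitted GAM smooth of one feature on GA for one group."""

    feature: str
    group: str
    grid: np.ndarray  # GA evaluation grid (weeks)
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    edf: float  # effective degrees of freedom of the smooth
    alpha_penalty: float  # selected smoothing parameter


@dataclass
class CorrelationResult:
    feature: str
    group: str
    rho: float
    p_value: float
    n: int


@dataclass
class GroupComparison:
    feature: str
    contrast: str  # e.g. "SG-Early3T vs MG-Early3T"
    statistic: float  # rank sum of the first group
    p_value: float
    significant: bool
    n_a: int = 0
    n_b: int = 0


def stratify_by_stage(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add a ``stage`` column from GA thresholds and metadata labels.

    Rows flagged TNL/APL in ``stage_label`` keep those labels regardless of
    GA; routine rows are Early3T when GA < 32 and Late3T when 32 <= GA < 37.
    A routine row at GA >= 37 is outside the stratification scheme and raises.
    """
    if "ga_wog" not in cohort.columns:
        raise ValueError("cohort must have a 'ga_wog' column")
    labels = cohort.get("stage_label", pd.Series("routine", index=cohort.index))
    stages: list[str] = []
    for ga, label in zip(cohort["ga_wog"], labels.fillna("routine")):
        if label in ("TNL", "APL"):
            stages.append(label)
        elif ga < EARLY3T_UPPER:
            stages.append("Early3T")
        elif ga < LATE3T_UPPER:
            stages.append("Late3T")
        else:
            raise ValueError(
                f"routine recording at GA={ga} >= {LATE3T_UPPER} WoG has no stage; "
                "term recordings must carry a TNL or APL label"
            )
    out = cohort.copy()
    out["stage"] = stages
    return out


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sp_stats.rankdata(x)  # average ranks for ties
    ry = sp_stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_ga_correlation(
    values: np.ndarray,
    ga: np.ndarray,
    feature: str = "",
    group: str = "",
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation of a feature with GA, two-sided p-value.

    Ties get average ranks. The p-value uses exact permutation enumeration
    for n <= 8, a seeded Monte-Carlo permutation test for n <= 30 (accurate
    at the small stage-group sizes this cohort produces) and the
    t-approximation beyond.
    """
    values = np.asarray(values, float)
    ga = np.asarray(ga, float)
    if values.shape != ga.shape:
        raise ValueError("values and ga must have the same length")
    n = values.size
    if n < 5:
        raise ValueError(f"need n >= 5 pairs, got {n}")
    rho = _spearman_rho(ga, values)
    if math.isnan(rho):
        logger.warning("zero variance in ranks: correlation undefined")
        return CorrelationResult(feature, group, float("nan"), float("nan"), n)

    if n <= SPEARMAN_EXACT_N:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(ga, values[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    elif n <= SPEARMAN_PERM_N:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(SPEARMAN_PERM_RESAMPLES):
            r = _spearman_rho(ga, rng.permutation(values))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (SPEARMAN_PERM_RESAMPLES + 1)
    else:
        # t-approximation, as in the classical large-sample Spearman test
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * sp_stats.t.sf(abs(tstat), df=n - 2)
    return CorrelationResult(feature, group, rho, float(min(p, 1.0)), n)


def _rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    combined = np.concatenate([a, b])
    ranks = sp_stats.rankdata(combined)
    return float(np.sum(ranks[: len(a)])), ranks


def wilcoxon_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    feature: str = "",
    contrast: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    For combined sizes up to 20 the p-value is computed by full enumeration
    of the C(n_a+n_b, n_a) rank assignments (average ranks, so ties are
    handled exactly); larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    w_obs, ranks = _rank_sum(a, b)
    mu = n_a * (n + 1) / 2.0

    if n <= WILCOXON_EXACT_N:
        dev_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= dev_obs - 1e-9:
                count += 1
        p = count / total
    else:
        # normal approximation with tie correction
        _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
            p = 2 * sp_stats.norm.sf(max(z, 0.0))
    p = float(min(p, 1.0))
    return GroupComparison(
        feature=feature,
        contrast=contrast,
        statistic=w_obs,
        p_value=p,
        significant=bool(p < alpha),
        n_a=n_a,
        n_b=n_b,
    )


def fit_gam_trend(
    values: np.ndarray,
    ga: np.ndarray,
    group: str = "",
    feature: str = "",
    grid_step: float = 0.25,
    max_df: int = GAM_MAX_DF,
    ci_level: float = 0.95,
) -> TrendFit:
    """Penalized-spline GAM smooth of a feature on GA with pointwise CI.

    Gaussian response, identity link, cubic B-spline basis (at most
    ``max_df`` functions), smoothing parameter selected by generalized
    cross-validation. The evaluation grid spans the observed GA range.
    """
    values = np.asarray(values, float)
    ga = np.asarray(ga, float)
    n = values.size
    n_unique = np.unique(ga).size
    df = min(max_df, max(4, n_unique - 1))
    if n_unique < 5:
        raise ValueError(
            f"only {n_unique} unique GA values; need >= 5 (reduce the basis or pool groups)"
        )
    if np.ptp(ga) < 1e-9:
        raise ValueError("GA range is degenerate")

    x = ga[:, None]
    smoother = BSplines(x, df=[df], degree=[3])
    const = np.ones((n, 1))
    grid = np.arange(ga.min(), ga.max() + grid_step / 2, grid_step)
    grid = np.clip(grid, ga.min(), ga.max())

    try:
        model = GLMGam(values, exog=const, smoother=smoother)
        model.fit()  # primes internal scale attributes needed by select_penweight
        try:
            alpha = float(np.atleast_1d(model.select_penweight(criterion="gcv")[0])[0])
        except PerfectSeparationError:
            raise
        except Exception:  # optimizer hiccups; keep a mildly smoothed fit
            logger.warning(
                "GCV penalty selection failed for %s/%s; using alpha=1", feature, group
            )
            alpha = 1.0
        res = GLMGam(values, exog=const, smoother=smoother, alpha=alpha).fit()
        pred = res.get_prediction(exog=np.ones((grid.size, 1)), exog_smooth=grid[:, None])
        ci = pred.conf_int(alpha=1 - ci_level)
        mean = np.asarray(pred.predicted_mean, float)
        lower = np.asarray(ci[:, 0], float)
        upper = np.asarray(ci[:, 1], float)
        edf = float(np.sum(res.edf)) if hasattr(res, "edf") else float("nan")
    except PerfectSeparationError:
        # data lie exactly in the spline span (noiseless/constant input):
        # the penalized IRLS loop refuses, but plain least squares is exact
        mean, lower, upper, edf = _spline_ols_fit(values, ga, smoother, grid, ci_level)
        alpha = 0.0
    return TrendFit(
        feature=feature,
        group=group,
        grid=grid,
        mean=mean,
        ci_lower=lower,
        ci_upper=upper,
        edf=edf,
        alpha_penalty=alpha,
    )


def _spline_ols_fit(
    values: np.ndarray,
    ga: np.ndarray,
    smoother: BSplines,
    grid: np.ndarray,
    ci_level: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Unpenalized spline regression used when the smooth fits exactly."""
    X = np.column_stack([np.ones(ga.size), smoother.transform(ga[:, None])])
    beta, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    dof = max(ga.size - rank, 1)
    sigma2 = float(resid @ resid) / dof
    Xg = np.column_stack([np.ones(grid.size), smoother.transform(grid[:, None])])
    mean = Xg @ beta
    cov = np.linalg.pinv(X.T @ X) * sigma2
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
    z = sp_stats.norm.ppf(0.5 + ci_level / 2)
    return mean, mean - z * se, mean + z * se, float(rank)


@dataclass
class AnalysisReport:
    """Full pipeline output: smooths, correlations, comparisons, omissions."""

    trends: list[TrendFit] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    comparisons: list[GroupComparison] = field(default_factory=list)
    omissions: list[str] = field(default_factory=list)

    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature": c.feature, "group": c.group, "rho": c.rho,
                 "p_value": c.p_value, "n": c.n}
                for c in self.correlations
            ]
        )

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature": c.feature, "contrast": c.contrast, "statistic": c.statistic,
                 "p_value": c.p_value, "significant": c.significant,
                 "n_a": c.n_a, "n_b": c.n_b}
                for c in self.comparisons
            ]
        )

    def get_correlation(self, feature: str, group: str) -> CorrelationResult | None:
        for c in self.correlations:
            if c.feature == feature and c.group == group:
                return c
        return None

    def get_comparison(self, feature: str, contrast: str) -> GroupComparison | None:
        for c in self.comparisons:
            if c.feature == feature and c.contrast == contrast:
                return c
        return None


FEATURE_COLUMNS = {
    "ppa": "median_ppa",
    "khe": "median_khe",
    "mdf": "median_mdf",
    "sampen": "median_sampen",
}

MIN_GROUP_N_CORR = 5
MIN_GROUP_N_GAM = 20
MIN_GROUP_N_COMP = 3


def run_full_analysis(
    cohort: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    grid_step: float = 0.25,
    include_term: bool = True,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """GA-trend analysis of a (balanced, feature-summarised) cohort table.

    Emits per feature and gestation type a GAM trend and a Spearman
    correlation with GA, plus Wilcoxon comparisons SG vs MG within each stage
    and between stages within each gestation type. Missing groups or stages
    degrade to logged omissions rather than errors. ``include_term=False``
    restricts the correlations to routine (pre-37-week) recordings.
    """
    report = AnalysisReport()
    if "stage" not in cohort.columns:
        cohort = stratify_by_stage(cohort)
    if "woman_id" in cohort.columns and cohort["woman_id"].duplicated().any():
        logger.info(
            "repeated recordings per woman are treated as independent observations"
        )

    groups = [g for g in ("SG", "MG") if (cohort["gestation_type"] == g).any()]
    for g in ("SG", "MG"):
        if g not in groups:
            report.omissions.append(f"group {g} absent: trends/correlations skipped")

    for feature, col in FEATURE_COLUMNS.items():
        if col not in cohort.columns:
            report.omissions.append(f"feature column {col} missing: {feature} skipped")
            continue
        for g in groups:
            sub = cohort[(cohort["gestation_type"] == g) & cohort[col].notna()]
            if not include_term:
                sub = sub[sub["stage"].isin(["Early3T", "Late3T"])]
            vals = sub[col].to_numpy(float)
            gas = sub["ga_wog"].to_numpy(float)
            if vals.size >= MIN_GROUP_N_CORR:
                report.correlations.append(
                    spearman_ga_correlation(vals, gas, feature=feature, group=g)
                )
            else:
                report.omissions.append(f"{feature}/{g}: n={vals.size} too small for correlation")
            if vals.size >= MIN_GROUP_N_GAM and np.unique(gas).size >= 5:
                try:
                    report.trends.append(
                        fit_gam_trend(vals, gas, group=g, feature=feature, grid_step=grid_step)
                    )
                except ValueError as exc:
                    report.omissions.append(f"{feature}/{g}: GAM skipped ({exc})")
            else:
                report.omissions.append(f"{feature}/{g}: n={vals.size} too small for GAM")

        # SG vs MG within each stage
        for stage in STAGE_ORDER:
            sel = {
                g: cohort[
                    (cohort["gestation_type"] == g)
                    & (cohort["stage"] == stage)
                    & cohort[col].notna()
                ][col].to_numpy(float)
                for g in ("SG", "MG")
            }
            if all(len(v) >= MIN_GROUP_N_COMP for v in sel.values()):
                report.comparisons.append(
                    wilcoxon_compare(
                        sel["SG"], sel["MG"],
                        feature=feature,
                        contrast=f"SG-{stage} vs MG-{stage}",
                        alpha=alpha,
                    )
                )
            elif any(len(v) > 0 for v in sel.values()):
                report.omissions.append(
                    f"{feature}/{stage}: SG-vs-MG comparison skipped (insufficient n)"
                )

        # stage vs stage within each gestation type
        for g in groups:
            stage_vals = {
                s: cohort[
                    (cohort["gestation_type"] == g)
                    & (cohort["stage"] == s)
                    & cohort[col].notna()
                ][col].to_numpy(float)
                for s in STAGE_ORDER
            }
            for s1, s2 in itertools.combinations(STAGE_ORDER, 2):
                if len(stage_vals[s1]) >= MIN_GROUP_N_COMP and len(stage_vals[s2]) >= MIN_GROUP_N_COMP:
                    report.comparisons.append(
                        wilcoxon_compare(
                            stage_vals[s1], stage_vals[s2],
                            feature=feature,
                            contrast=f"{g}-{s1} vs {g}-{s2}",
                            alpha=alpha,
                        )
                    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.correlations_frame().to_csv(out / "correlations.csv", index=False)
        report.comparisons_frame().to_csv(out / "comparisons.csv", index=False)
        for tf in report.trends:
            pd.DataFrame(
                {"ga_wog": tf.grid, "mean": tf.mean,
                 "ci_lower": tf.ci_lower, "ci_upper": tf.ci_upper}
            ).to_csv(out / f"trend_{tf.feature}_{tf.group}.csv", index=False)
        (out / "omissions.txt").write_text("\n".join(report.omissions) + "\n")
    return report
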