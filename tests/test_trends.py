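"""Stage stratification, Spearman, Wilcoxon and GAM trend fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from ehgtrends import (
    fit_gam_trend,
    run_full_analysis,
    spearman_ga_correlation,
    stratify_by_stage,
    wilcoxon_compare,
)

from _oracles import mannwhitney_exact_enumeration, spearman_rank_pearson
from conftest import make_summary_table


class TestStratify:
    def make_row(self, ga, label="routine"):
        return pd.DataFrame(
            [{"recording_id": "r", "ga_wog": ga, "gestation_type": "SG", "stage_label": label}]
        )

    @pytest.mark.parametrize(
        "ga,label,expected",
        [
            (30.0, "routine", "Early3T"),
            (31.999, "routine", "Early3T"),
            (32.0, "routine", "Late3T"),
            (36.9, "routine", "Late3T"),
            (40.5, "APL", "APL"),
            (30.0, "TNL", "TNL"),  # metadata label wins over thresholds
        ],
    )
    def test_stage_assignment(self, ga, label, expected):
        out = stratify_by_stage(self.make_row(ga, label))
        assert out.stage.iloc[0] == expected

    def test_routine_at_term_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_stage(self.make_row(38.0, "routine"))


class TestSpearman:
    def test_strict_monotone(self):
        r = spearman_ga_correlation([1.0, 4.0, 9.0, 16.0, 25.0], [28.0, 30.0, 34.0, 35.0, 36.0])
        assert r.rho == pytest.approx(1.0)
        rr = spearman_ga_correlation([25.0, 16.0, 9.0, 4.0, 1.0], [28.0, 30.0, 34.0, 35.0, 36.0])
        assert rr.rho == pytest.approx(-1.0)

    def test_tie_handling_matches_rank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 5.0])
        r = spearman_ga_correlation(y, x)
        assert r.rho == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(6, 0), (12, 1), (25, 2), (60, 3)])
    def test_rho_matches_oracle_random(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(26, 41, n)
        y = np.round(rng.standard_normal(n), 1)  # rounding forces ties
        r = spearman_ga_correlation(y, x)
        assert r.rho == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)
        assert r.rho == pytest.approx(sp_stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_pvalue_regimes_agree_on_clear_effect(self):
        rng = np.random.default_rng(4)
        for n in (8, 20, 60):
            x = np.sort(rng.uniform(26, 41, n))
            y = x + 0.1 * rng.standard_normal(n)
            r = spearman_ga_correlation(y, x)
            assert r.p_value < 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_ga_correlation([1.0, 2.0], [3.0, 4.0])


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        r = wilcoxon_compare(g, g.copy())
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_separated_groups_exact_p(self):
        r = wilcoxon_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    @pytest.mark.parametrize("na,nb,seed", [(3, 3, 0), (4, 6, 1), (5, 5, 2), (8, 8, 3), (6, 8, 4)])
    def test_exact_pvalues_match_enumeration_oracle(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.standard_normal(na), 1)
        b = np.round(rng.standard_normal(nb) + 0.5, 1)
        r = wilcoxon_compare(a, b)
        assert r.p_value == pytest.approx(mannwhitney_exact_enumeration(a, b), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(7)
        b = rng.standard_normal(8) + 1.0
        r = wilcoxon_compare(a, b)
        expected = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert r.p_value == pytest.approx(expected, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1.0])

    def test_large_sample_approximation_reasonable(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50) + 1.0
        r = wilcoxon_compare(a, b)
        expected = sp_stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert r.p_value == pytest.approx(expected, rel=1e-6)
        assert r.significant


class TestGamTrend:
    def test_recovers_noiseless_line(self):
        rng = np.random.default_rng(0)
        ga = np.sort(rng.uniform(26, 41, 80))
        fit = fit_gam_trend(2.0 * ga, ga)
        interior = (fit.grid > 27) & (fit.grid < 40)
        np.testing.assert_allclose(fit.mean[interior], 2.0 * fit.grid[interior], atol=1e-3)

    def test_constant_data_flat_fit_and_narrow_ci(self):
        rng = np.random.default_rng(1)
        narrow = None
        for n in (50, 400):
            ga = np.sort(rng.uniform(26, 41, n))
            fit = fit_gam_trend(np.full(n, 3.7), ga)
            np.testing.assert_allclose(fit.mean, 3.7, atol=1e-6)
            width = np.mean(fit.ci_upper - fit.ci_lower)
            if narrow is not None:
                assert width <= narrow
            narrow = width

    def test_smooth_recovery_under_noise(self):
        rng = np.random.default_rng(2)
        ga = np.sort(rng.uniform(26, 41, 200))
        truth = np.sin(ga / 2)
        fit = fit_gam_trend(truth + 0.3 * rng.standard_normal(200), ga)
        interior = (fit.grid > 27) & (fit.grid < 40)
        rmse = np.sqrt(np.mean((fit.mean[interior] - np.sin(fit.grid[interior] / 2)) ** 2))
        assert rmse < 0.3
        assert np.all(fit.ci_lower <= fit.mean) and np.all(fit.mean <= fit.ci_upper)

    def test_degenerate_ga_rejected(self):
        with pytest.raises(ValueError):
            fit_gam_trend(np.ones(30), np.full(30, 30.0))


class TestFullAnalysis:
    def test_programmed_trends_recovered(self):
        """SG amplitude rises with GA, MG flat: only SG PPA correlates."""
        df = make_summary_table(
            n_sg=60, n_mg=60, seed=5,
            sg_slopes={"median_ppa": 0.1}, mg_slopes={}, noise_sd=0.05,
        )
        report = run_full_analysis(df)
        sg = report.get_correlation("ppa", "SG")
        mg = report.get_correlation("ppa", "MG")
        assert sg.rho > 0 and sg.p_value < 0.05
        assert mg.p_value > 0.05

    def test_early_offset_detected_only_early(self):
        """An MG>SG offset vanishing at 32 WoG shows up only in Early3T."""
        rng = np.random.default_rng(6)
        df = make_summary_table(n_sg=80, n_mg=80, seed=6, noise_sd=0.1)
        mg_mask = df.gestation_type == "MG"
        early = df.ga_wog < 32
        df.loc[mg_mask & early, "median_ppa"] += 0.6 * (32 - df.loc[mg_mask & early, "ga_wog"]) / 6
        report = run_full_analysis(df)
        early_cmp = report.get_comparison("ppa", "SG-Early3T vs MG-Early3T")
        late_cmp = report.get_comparison("ppa", "SG-Late3T vs MG-Late3T")
        assert early_cmp.significant
        assert not late_cmp.significant

    def test_missing_group_degrades_to_omission(self):
        df = make_summary_table(n_sg=40, n_mg=5, seed=7)
        df = df[df.gestation_type == "SG"]
        report = run_full_analysis(df)
        assert report.get_correlation("ppa", "SG") is not None
        assert report.get_correlation("ppa", "MG") is None
        assert any("MG" in o for o in report.omissions)
        assert report.comparisons_frame().empty or not any(
            "MG" in c for c in report.comparisons_frame().contrast
        )

    def test_output_files_written(self, tmp_path):
        df = make_summary_table(n_sg=40, n_mg=40, seed=8, noise_sd=0.1)
        run_full_analysis(df, out_dir=tmp_path)
        assert (tmp_path / "correlations.csv").exists()
        assert (tmp_path / "comparisons.csv").exists()
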