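"""Summaries, Mann–Whitney, Friedman + Dunn, normality-gated correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from mlcquant.stats import (
    build_report,
    correlate,
    friedman_with_posthoc,
    mann_whitney,
    summarize,
)
from mlcquant.synthesize import CohortSpec, sample_group_covariates, sample_region_triples


class TestSummarize:
    def test_median_iqr_linear_interpolation(self):
        s = summarize(np.arange(1, 101))
        assert s.median == 50.5
        assert s.iqr == pytest.approx(49.5)

    def test_constant_sample_degenerate(self):
        s = summarize([7.0] * 10)
        assert s.sd == 0.0
        assert not s.normal
        assert "(" in s.formatted  # median (IQR) path

    def test_gaussian_sample_mean_sd_format(self, rng):
        s = summarize(rng.standard_normal(200))
        assert s.normal
        assert "±" in s.formatted

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0, 2.0])


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.statistic == 12.5  # n_a·n_b / 2
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.detail["method"] == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 6, rng.integers(3, 7))
            b = rng.integers(0, 6, rng.integers(3, 7))
            res = mann_whitney(a, b)
            assert res.detail["method"] == "exact"
            assert res.p_value == pytest.approx(oracle.mann_whitney_exact_p(a, b))

    def test_asymptotic_detects_shift(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 2.0
        res = mann_whitney(a, b)
        assert res.detail["method"] == "asymptotic"
        assert res.p_value < 1e-4

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFriedman:
    def test_identical_conditions_no_effect(self):
        triples = np.tile([[3.0, 3.0, 3.0]], (6, 1))
        res = friedman_with_posthoc(triples)
        assert res[0].statistic == 0.0
        assert res[0].p_value == 1.0

    def test_perfect_concordance_statistic(self):
        """Strict within-eye ordering in all 10 eyes: χ² = n(k−1) = 20."""
        triples = np.column_stack([np.arange(10), np.arange(10) + 10, np.arange(10) + 20])
        res = friedman_with_posthoc(triples)
        assert res[0].statistic == pytest.approx(20.0)

    def test_agrees_with_permutation_oracle(self):
        """The chi-square p matches a 10,000-permutation oracle in the
        decision-relevant tail (n = 12 eyes, moderate condition effect)."""
        data_rng = np.random.default_rng(7)
        for seed in range(2):
            data = data_rng.normal(0, 1, (12, 3)) + np.array([0.0, 0.4, 0.8])
            res = friedman_with_posthoc(data)
            p_perm = oracle.friedman_permutation_p(data, 10_000, seed=seed)
            assert res[0].p_value == pytest.approx(p_perm, abs=0.02)

    def test_bonferroni_is_exactly_three_p_capped(self, rng):
        data = rng.normal(0, 1, (15, 3)) + np.array([0.0, 0.2, 0.4])
        res = friedman_with_posthoc(data)
        for pair in res[1:]:
            assert pair.adjusted_p == min(1.0, 3.0 * pair.p_value)

    def test_dunn_z_formula(self):
        """Perfect ordering n=10: mean ranks 1,2,3, se = √(k(k+1)/(6n))."""
        triples = np.column_stack([np.arange(10), np.arange(10) + 10, np.arange(10) + 20])
        res = friedman_with_posthoc(triples)
        se = np.sqrt(3 * 4 / (6 * 10))
        z01 = next(r for r in res[1:] if r.test_name == "dunn_edematous_vs_non_edematous")
        assert z01.statistic == pytest.approx((1.0 - 2.0) / se)

    def test_incomplete_rows_dropped(self):
        data = np.array([[1.0, 2.0, 3.0]] * 5 + [[np.nan, 2.0, 3.0]])
        res = friedman_with_posthoc(data)
        assert res[0].n == (5,)
        assert res[0].detail["dropped"] == 1


class TestCorrelate:
    def test_perfect_linear(self, rng):
        x = rng.standard_normal(30)
        res = correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_spearman_with_ties_rank_arithmetic(self):
        """Midranks of y = [5,6,7,8,7] are [1,2,3.5,5,3.5]; the rank
        correlation is 8/√95 (Pearson correlation of the midranks)."""
        res = correlate([1, 2, 3, 4, 5], [5, 6, 7, 8, 7], method="spearman")
        assert res.r == pytest.approx(8.0 / np.sqrt(95.0))

    def test_gating_by_normality(self, rng):
        g1, g2 = rng.standard_normal(60), rng.standard_normal(60)
        assert correlate(g1, g2).method == "pearson"
        skewed = np.exp(3.0 * rng.standard_normal(60))
        assert correlate(g1, skewed).method == "spearman"

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate(np.ones(10), rng.standard_normal(10))


def _synthetic_cohort_table(seed: int) -> pd.DataFrame:
    """Cohort table assembled from the generator's statistical core."""
    spec = CohortSpec()
    rng = np.random.default_rng(seed)
    frames = []
    for group, n in (("control", 20), ("acute", 20), ("chronic", 15)):
        cov = sample_group_covariates(group, n, spec, rng, 33.66)
        cov["eye_id"] = [f"{group}_{i}" for i in range(n)]
        cov["rvo_type"] = "none" if group == "control" else "BRVO"
        cov["mlc_count"] = cov["planted_count"]
        cov["mlc_density"] = cov["planted_count"] / 33.66
        cov["mrt_um"] = cov["mrt_baseline_um"]
        if group == "control":
            cov[["density_edematous", "density_non_edematous", "density_whole"]] = np.nan
            cov["area_edematous_mm2"] = 0.0
        else:
            ratio = spec.marginals[group].edema_density_ratio
            triples = sample_region_triples(n, ratio, rng)
            cov[["density_edematous", "density_non_edematous", "density_whole"]] = triples
            cov["area_edematous_mm2"] = 9.0
        frames.append(cov)
    return pd.concat(frames, ignore_index=True)


class TestBuildReport:
    def test_tables_populated_and_valid(self):
        tables = build_report(_synthetic_cohort_table(1))
        groups = tables["groups"]
        assert set(groups.columns) >= {"variable", "acute", "chronic", "all_rvo", "control"}
        p = groups["p_rvo_vs_control"].dropna()
        assert ((0 <= p) & (p <= 1)).all()
        assert len(tables["regions"]) == 3
        assert ((0 <= tables["regions"]["friedman_p"]) & (tables["regions"]["friedman_p"] <= 1)).all()
        assert len(tables["correlations"]) > 0
        assert tables["correlations"]["r"].between(-1, 1).all()

    def test_deterministic(self):
        t1 = build_report(_synthetic_cohort_table(2))
        t2 = build_report(_synthetic_cohort_table(2))
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="mlc_count"):
            build_report(pd.DataFrame({"eye_id": [1], "group": ["acute"]}))

    def test_control_only_cohort(self):
        df = _synthetic_cohort_table(3)
        tables = build_report(df[df["group"] == "control"].reset_index(drop=True))
        assert (tables["groups"]["acute"] == "").all()
        assert len(tables["regions"]) == 0
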