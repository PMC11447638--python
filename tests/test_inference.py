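"""Permutation tests, FDR, effect sizes, regressions and classifiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neurodyn as nd
from neurodyn.inference import (permutation_mean_test, bh_fdr, reduce_rois,
                                cohens_f2, hierarchical_regression,
                                classify_outcomes)


def _brute_bh(p, alpha):
    """Step-up rule evaluated directly from its definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k_max = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


def _make_table(n, seed, beta_gini=0.0, outcome="y"):
    """Cohort table with outcome = beta * gini_z + noise."""
    rng = np.random.default_rng(seed)
    gini = rng.choice([32.0, 35.0, 38.0, 42.0, 44.5, 51.0, 53.0], size=n)
    gz = (gini - gini.mean()) / gini.std()
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "gini": gini,
        "age": rng.uniform(20, 80, n),
        "sex": rng.choice(["male", "female"], n),
        "education": rng.uniform(5, 20, n),
        "mmse": rng.integers(24, 31, n).astype(float),
        outcome: beta_gini * gz + np.sqrt(1 - min(beta_gini ** 2, 0.99))
        * rng.standard_normal(n),
    })
    return nd.CohortFeatureTable(df)


class TestPermutationMeanTest:
    def test_minimum_attainable_p(self):
        p = permutation_mean_test(np.ones(50), n_perm=5000, seed=0)
        assert p == pytest.approx(1 / 5001)

    def test_single_zero_value(self):
        assert permutation_mean_test(np.array([0.0]), seed=0) == 1.0

    def test_all_zero_input(self):
        assert permutation_mean_test(np.zeros(10), seed=0) == 1.0

    def test_null_p_values_approximately_uniform(self):
        """Type-I calibration: under a symmetric zero-mean null the p values
        are approximately uniform."""
        from scipy import stats
        rng = np.random.default_rng(11)
        ps = [permutation_mean_test(rng.standard_normal(20), n_perm=500,
                                    seed=int(rng.integers(2**31 - 1)))
              for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.03 <= rate <= 0.07


class TestBhFdr:
    @pytest.mark.parametrize("p, expected_n", [
        ([.01, .02, .03, .04], 4),
        ([.04, .04, .04, .5], 0),
        ([1.0], 0),
        ([], 0),
    ])
    def test_hand_worked_cases(self, p, expected_n):
        assert bh_fdr(p).sum() == expected_n

    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=6),
           st.sampled_from([0.01, 0.05, 0.1]))
    @settings(max_examples=300, deadline=None)
    def test_matches_step_up_definition_oracle(self, grid_p, alpha):
        p = np.array(grid_p) / 100.0
        np.testing.assert_array_equal(bh_fdr(p, alpha), _brute_bh(p, alpha))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            ours = bh_fdr(p, 0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, theirs)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestReduceRois:
    def test_signal_roi_retained_null_rois_not(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "roi_signal": rng.standard_normal(100) + 1.0,
            **{f"roi_null{i}": rng.standard_normal(100) for i in range(5)},
        })
        kept = reduce_rois(df, n_perm=1000, seed=3)
        assert "roi_signal" in kept

    def test_null_retention_rate_controlled(self):
        rng = np.random.default_rng(6)
        n_kept = 0
        for s in range(20):
            df = pd.DataFrame({f"r{i}": rng.standard_normal(40) for i in range(8)})
            n_kept += len(reduce_rois(df, n_perm=200, seed=s))
        assert n_kept / (20 * 8) <= 0.10

    def test_empty_table(self):
        assert reduce_rois(pd.DataFrame()) == []


class TestCohensF2:
    @pytest.mark.parametrize("r2, f2", [
        (0.2996, 0.4278),   # printed alongside its R2 in the source tables
        (0.16, 0.1905),
        (0.0, 0.0),
    ])
    def test_identity(self, r2, f2):
        assert cohens_f2(r2) == pytest.approx(f2, abs=5e-5)

    def test_monotone_and_small_r2_limit(self):
        grid = np.linspace(0, 0.95, 50)
        vals = [cohens_f2(r) for r in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert cohens_f2(1e-6) / 1e-6 == pytest.approx(1.0, rel=1e-5)

    def test_domain(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0)


class TestHierarchicalRegression:
    def test_noiseless_recovery(self):
        table = _make_table(200, seed=1)
        df = table.df.copy()
        df["y"] = -2.0 * (df["gini"] - df["gini"].mean()) / df["gini"].std(ddof=0)
        rep = hierarchical_regression(nd.CohortFeatureTable(df), "y", ["gini"])
        assert rep.r_squared > 1 - 1e-10
        assert rep.p_values["gini"] < 1e-10
        assert rep.estimates["gini"] == pytest.approx(-2.0, abs=1e-8)
        assert rep.f_squared > 1e9  # R2 -> 1 sends f2 to its cap

    def test_planted_negative_effect_recovered(self):
        table = _make_table(300, seed=2, beta_gini=-0.4)
        rep = hierarchical_regression(table, "y", ["gini"])
        assert rep.estimates["gini"] < 0
        assert rep.p_values["gini"] < 0.001

    def test_null_type_one_error_rate(self):
        hits = 0
        for s in range(100):
            rep = hierarchical_regression(_make_table(200, seed=100 + s), "y",
                                          ["gini"])
            hits += rep.p_values["gini"] < 0.05
        assert 1 <= hits <= 12  # ~5% +- binomial noise

    def test_interaction_term(self):
        table = _make_table(300, seed=3, beta_gini=-0.3)
        rep = hierarchical_regression(table, "y", ["gini", "age", "gini:age"])
        assert set(rep.estimates) == {"gini", "age", "gini:age"}

    def test_rank_deficient_design_named(self):
        table = _make_table(100, seed=4)
        df = table.df.copy()
        df["gini2"] = df["gini"]
        with pytest.raises(ValueError, match="collinear"):
            hierarchical_regression(nd.CohortFeatureTable(df), "y",
                                    ["gini", "gini2"])

    def test_listwise_deletion_reported(self):
        table = _make_table(100, seed=5)
        df = table.df.copy()
        df.loc[df.index[:10], "mmse"] = np.nan
        rep = hierarchical_regression(nd.CohortFeatureTable(df), "y",
                                      ["gini", "mmse"])
        assert rep.n_used == 90


class TestClassifyOutcomes:
    def test_separable_outcome_perfect_auc(self):
        table = _make_table(200, seed=6)
        df = table.df.copy()
        df["y"] = df["gini"]  # label is a deterministic function of gini
        rep = classify_outcomes(nd.CohortFeatureTable(df), "y", ["gini"],
                                k=3, seed=0)
        assert rep.mean_auc == pytest.approx(1.0, abs=1e-9)

    def test_null_outcome_chance_level(self):
        table = _make_table(400, seed=7)
        rep = classify_outcomes(table, "y", ["gini", "age"], k=5, seed=1)
        assert 0.4 <= rep.mean_auc <= 0.6

    def test_importances_normalized_and_ordered(self):
        rng = np.random.default_rng(8)
        table = _make_table(400, seed=8, beta_gini=-0.6)
        df = table.df.copy()
        df["y"] = df["y"] + 0.1 * (df["age"] - df["age"].mean()) / df["age"].std()
        rep = classify_outcomes(nd.CohortFeatureTable(df), "y", ["gini", "age"],
                                k=5, seed=2)
        assert sum(rep.importances.values()) == pytest.approx(1.0, abs=1e-6)
        assert rep.importances["gini"] > rep.importances["age"]

    def test_degenerate_outcome_rejected(self):
        table = _make_table(100, seed=9)
        df = table.df.copy()
        df["y"] = 1.0
        with pytest.raises(ValueError):
            classify_outcomes(nd.CohortFeatureTable(df), "y", ["gini"])

    def test_metrics_have_k_repeats(self):
        rep = classify_outcomes(_make_table(120, seed=10), "y", ["gini"],
                                k=4, seed=3)
        assert len(rep.auc) == len(rep.accuracy) == len(rep.f1) == 4
        assert all(0 <= v <= 1 for v in rep.auc + rep.accuracy + rep.precision
                   + rep.recall + rep.f1)
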