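"""Behavioral ANOVAs, Tukey post hocs, kappa, PAC feature correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emopac import groupstats, synth


def make_table(effects, subject_sd=0.4, noise_sd=0.3, n=20, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n):
        intercept = rng.normal(0, subject_sd)
        for cond, mean in effects.items():
            rows.append({"participant": f"s{p:02d}", "condition": cond,
                         "gender": "male" if p % 2 else "female",
                         "score": mean + intercept + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestAnova:
    def test_huge_separation_drives_eta_to_one(self):
        table = make_table({"neutral": 1.0, "happy": 5.0, "sad": 9.0},
                           subject_sd=0.0, noise_sd=1e-4)
        res = groupstats.oneway_anova(table, "score")
        assert res.p < 1e-12
        assert res.eta_squared_partial > 0.999

    def test_within_degrees_of_freedom(self):
        table = make_table({"a": 1.0, "b": 1.2, "c": 1.4}, n=26)
        res = groupstats.oneway_anova(table, "score", mode="within")
        assert res.df == (2, 50)

    def test_between_mode_matches_pooled_scipy(self):
        from scipy.stats import f_oneway

        table = make_table({"a": 1.0, "b": 1.5, "c": 1.1}, n=12, seed=3)
        res = groupstats.oneway_anova(table, "score", mode="between")
        groups = [g["score"].to_numpy() for _, g in table.groupby("condition")]
        F, p = f_oneway(*groups)
        assert res.F == pytest.approx(F)
        assert res.df == (2, 33)

    def test_type_one_error_near_alpha(self):
        rejections = 0
        n_seeds = 120
        for seed in range(n_seeds):
            table = make_table({"a": 2.0, "b": 2.0, "c": 2.0}, seed=seed)
            rejections += groupstats.oneway_anova(table, "score").p < 0.05
        assert rejections / n_seeds == pytest.approx(0.05, abs=0.045)

    def test_zero_variance_rejected(self):
        table = make_table({"a": 1.0, "b": 2.0, "c": 3.0},
                           subject_sd=0.0, noise_sd=0.0)
        with pytest.raises(ValueError):
            groupstats.oneway_anova(table, "score")

    def test_incomplete_crossing_rejected(self):
        table = make_table({"a": 1.0, "b": 2.0, "c": 3.0}, n=6).iloc[:-1]
        with pytest.raises(ValueError):
            groupstats.oneway_anova(table, "score", mode="within")


class TestTukey:
    def test_identical_conditions_not_flagged(self):
        table = make_table({"a": 2.0, "b": 2.0, "c": 6.0}, seed=5)
        ph = {tuple(sorted(c.pair)): c for c in
              groupstats.tukey_posthoc(table, "score")}
        assert ph[("a", "b")].p_adjusted > 0.2
        assert ph[("a", "c")].p_adjusted < 0.001
        assert ph[("b", "c")].p_adjusted < 0.001

    def test_adjusted_at_least_unadjusted(self):
        from scipy.stats import t as t_dist

        table = make_table({"a": 2.0, "b": 2.3, "c": 2.6}, seed=7)
        comparisons = groupstats.tukey_posthoc(table, "score")
        df = 2 * (table["participant"].nunique() - 1)
        for cmp in comparisons:
            p_unadj = 2 * t_dist.sf(abs(cmp.t), df)
            assert cmp.p_adjusted >= p_unadj - 1e-12

    def test_large_separation_significant(self):
        table = make_table({"a": 0.0, "b": 10.0, "c": 20.0},
                           subject_sd=0.5, noise_sd=1.0, seed=2)
        for cmp in groupstats.tukey_posthoc(table, "score"):
            assert cmp.p_adjusted < 0.001


class TestKappa:
    def test_identical_raters_give_one(self):
        a = np.tile([1, 2, 3, 4, 5], 10)
        assert groupstats.cohens_kappa(a, a.copy()).kappa == pytest.approx(1.0)

    def test_contingency_oracle(self):
        res = groupstats.kappa_from_table([[45, 5], [5, 45]])
        assert res.kappa == pytest.approx(0.8)
        assert res.observed_agreement == pytest.approx(0.9)
        assert res.expected_agreement == pytest.approx(0.5)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 6, 1000)
        b = rng.integers(1, 6, 1000)
        assert abs(groupstats.cohens_kappa(a, b).kappa) < 0.05

    def test_cross_check_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        a = rng.integers(1, 6, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(1, 6, 200))
        ours = groupstats.cohens_kappa(a, b).kappa
        theirs = sklearn_metrics.cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-12)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 16 - 1))
    def test_invariant_to_consistent_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 120)
        b = np.where(rng.random(120) < 0.6, a, rng.integers(0, 4, 120))
        relabel = {0: 10, 1: 7, 2: 99, 3: -1}
        ra = np.vectorize(relabel.get)(a)
        rb = np.vectorize(relabel.get)(b)
        assert groupstats.cohens_kappa(ra, rb).kappa == pytest.approx(
            groupstats.cohens_kappa(a, b).kappa, abs=1e-12)

    def test_single_category_rejected(self):
        ones = np.ones(10)
        with pytest.raises(ValueError):
            groupstats.cohens_kappa(ones, ones)


def feature_frame(values_by_feature, path="LF-LP"):
    rows = []
    for feature, values in values_by_feature.items():
        cond, pb, ab = feature.split("-")
        for i, v in enumerate(values):
            rows.append({"participant": f"s{i:02d}",
                         "gender": "male" if i % 2 else "female",
                         "condition": cond.lower(), "path": path,
                         "phase_band": pb, "amp_band": ab,
                         "feature": feature, "value": v})
    return pd.DataFrame(rows)


class TestCorrelations:
    def test_perfect_and_inverse_pairs(self):
        x = np.linspace(0, 1, 10)
        frame = feature_frame({"Happy-T-LG": x, "Happy-A-HG": 2 * x + 1,
                               "Sad-D-LG": -x})
        results = {(c.feature_a, c.feature_b): c
                   for c in groupstats.pac_correlations(frame)}
        assert results[("Happy-A-HG", "Happy-T-LG")].r == pytest.approx(1.0)
        assert results[("Happy-A-HG", "Sad-D-LG")].r == pytest.approx(-1.0)
        assert results[("Happy-A-HG", "Happy-T-LG")].stars == "***"

    def test_shared_latent_factor_recovered(self):
        rng = np.random.default_rng(3)
        loading, n = 0.8, 26
        rs = []
        for _ in range(40):
            z = rng.standard_normal(n)
            x = loading * z + np.sqrt(1 - loading ** 2) * rng.standard_normal(n)
            y = loading * z + np.sqrt(1 - loading ** 2) * rng.standard_normal(n)
            frame = feature_frame({"Happy-T-LG": x, "Happy-A-HG": y})
            (res,) = groupstats.pac_correlations(frame)
            rs.append(res.r)
        assert np.mean(rs) == pytest.approx(loading ** 2, abs=0.15)

    def test_gender_subgroups_and_min_n(self):
        x = np.arange(10.0)
        frame = feature_frame({"Happy-T-LG": x, "Sad-T-LG": x[::-1]})
        male = groupstats.pac_correlations(frame, group="male")
        assert all(c.group == "male" and c.n == 5 for c in male)
        tiny = feature_frame({"Happy-T-LG": np.arange(3.0)})
        with pytest.raises(ValueError):
            groupstats.pac_correlations(tiny)

    def test_zero_variance_feature_skipped(self):
        frame = feature_frame({"Happy-T-LG": np.arange(8.0),
                               "Sad-T-LG": np.ones(8)})
        with pytest.warns(UserWarning, match="zero-variance"):
            results = groupstats.pac_correlations(frame)
        assert results == []

    def test_correlation_pvalues_uniform_under_independence(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(400):
            x, y = rng.standard_normal((2, 20))
            frame = feature_frame({"Happy-T-LG": x, "Happy-A-HG": y})
            (res,) = groupstats.pac_correlations(frame)
            pvals.append(res.p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_holm_option_only_increases_p(self):
        rng = np.random.default_rng(11)
        frame = feature_frame({"Happy-T-LG": rng.standard_normal(12),
                               "Happy-A-HG": rng.standard_normal(12),
                               "Sad-T-LG": rng.standard_normal(12)})
        plain = {(c.feature_a, c.feature_b): c.p
                 for c in groupstats.pac_correlations(frame)}
        holm = {(c.feature_a, c.feature_b): c.p
                for c in groupstats.pac_correlations(frame, holm=True)}
        for pair in plain:
            assert holm[pair] >= plain[pair] - 1e-12


def test_pac_feature_table_from_matrices(coupled_dataset):
    from emopac import pac as pacmod

    m = pacmod.comodulogram(coupled_dataset, "LF-LP", "neutral", seed=0)
    table = groupstats.pac_feature_table(
        {("sub-00", "neutral", "LF-LP"): m}, {"sub-00": "female"})
    assert len(table) == 6  # 3 phase bands x 2 gamma bands
    theta_lg = table[(table.phase_band == "theta")
                     & (table.amp_band == "low_gamma")]["value"].iloc[0]
    assert theta_lg == pytest.approx(
        pacmod.band_feature(m, "theta", "low_gamma"))
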