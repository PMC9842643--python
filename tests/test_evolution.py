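"""Fitness-vs-evolutionary-outcome models: classification, logistic and
WLS fits, permutation test and rank comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from barfit.evolution import (
    BENEFICIAL,
    DELETERIOUS,
    NEUTRAL,
    classify_and_normalize,
    classify_fitness,
    establishment_logit,
    expression_wls,
    mutated_status,
    rank_compare,
    slope_permutation_test,
    split_by_median,
)


def toy_column(rng, n_neutral=150, n_benef=50, n_delet=40):
    s = pd.Series(
        np.concatenate(
            [
                rng.normal(0, 0.001, n_neutral),
                rng.uniform(0.01, 0.05, n_benef),
                -rng.uniform(0.01, 0.05, n_delet),
            ]
        ),
        index=[f"g{i}" for i in range(n_neutral + n_benef + n_delet)],
    )
    sig = pd.Series(
        [False] * n_neutral + [True] * (n_benef + n_delet), index=s.index
    )
    return s, sig


class TestClassification:
    def test_band_and_significance_conjunction(self):
        s = pd.Series([0.004, 0.004, 0.03, -0.02, 0.007])
        sig = pd.Series([False, True, True, True, False])
        classes = classify_fitness(s, sig)
        assert classes.tolist() == [
            NEUTRAL, BENEFICIAL, BENEFICIAL, DELETERIOUS, "excluded"
        ]

    def test_normalization_by_class_median(self):
        s = pd.Series([0.01, 0.02, 0.03, 0.001])
        sig = pd.Series([True, True, True, False])
        _, s_tilde = classify_and_normalize(s, sig, BENEFICIAL)
        assert s_tilde.iloc[2] == pytest.approx(1.5)  # 0.03 / median 0.02
        assert s_tilde.iloc[3] == pytest.approx(0.05)  # neutral retained

    def test_empty_class_raises(self):
        s = pd.Series([0.001, 0.002])
        sig = pd.Series([False, False])
        with pytest.raises(ValueError):
            classify_and_normalize(s, sig, BENEFICIAL)

    def test_scale_invariance_of_normalized_fitness(self):
        rng = np.random.default_rng(0)
        s, sig = toy_column(rng)
        _, t1 = classify_and_normalize(s, sig, BENEFICIAL, neutral_band=0.005)
        _, t2 = classify_and_normalize(
            s * 3, sig, BENEFICIAL, neutral_band=0.015
        )
        pd.testing.assert_series_equal(t1, t2)


class TestEstablishmentLogit:
    def simulate(self, rng, beta=1.0, beta0=-1.0):
        s, sig = toy_column(rng)
        _, s_tilde = classify_and_normalize(s, sig, BENEFICIAL)
        x = pd.Series(0.0, index=s.index)
        x.loc[s_tilde.index] = s_tilde
        p = 1 / (1 + np.exp(-(beta * x + beta0)))
        mutated = pd.Series(rng.random(len(s)) < p, index=s.index).astype(int)
        return s, sig, mutated

    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(1)
        betas, ps = [], []
        for _ in range(40):
            s, sig = toy_column(rng)
            mutated = pd.Series(
                rng.random(len(s)) < 0.3, index=s.index
            ).astype(int)
            res = establishment_logit(s, sig, mutated)
            benef = [r for r in res if r.target_class == BENEFICIAL][0]
            betas.append(benef.beta)
            ps.append(benef.beta_p)
        assert abs(np.mean(betas)) < 0.2
        assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8  # p roughly uniform

    def test_recovers_planted_slope_within_two_se(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            s, sig, mutated = self.simulate(rng, beta=1.0)
            res = establishment_logit(s, sig, mutated)
            benef = [r for r in res if r.target_class == BENEFICIAL][0]
            if abs(benef.beta - 1.0) <= 2 * benef.beta_se:
                hits += 1
        assert hits / n_sim >= 0.90

    def test_constant_response_flagged(self):
        rng = np.random.default_rng(3)
        s, sig = toy_column(rng)
        mutated = pd.Series(0, index=s.index)
        res = establishment_logit(s, sig, mutated)
        assert all("degenerate-response" in r.flags for r in res)

    def test_matches_statsmodels_reference_fit(self):
        rng = np.random.default_rng(4)
        s, sig, mutated = self.simulate(rng)
        res = establishment_logit(s, sig, mutated)
        benef = [r for r in res if r.target_class == BENEFICIAL][0]
        _, s_tilde = classify_and_normalize(s, sig, BENEFICIAL)
        ref = sm.Logit(
            mutated.loc[s_tilde.index].to_numpy(float),
            sm.add_constant(s_tilde.to_numpy()),
        ).fit(disp=0)
        assert benef.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert benef.beta_se == pytest.approx(ref.bse[1], abs=1e-6)


class TestExpressionWls:
    def simulate(self, rng, beta=0.5):
        s, sig = toy_column(rng)
        _, s_tilde = classify_and_normalize(s, sig, BENEFICIAL)
        var = pd.Series(rng.uniform(0.01, 0.3, len(s)) ** 2, index=s.index)
        de = pd.Series(rng.normal(0, np.sqrt(var)), index=s.index)
        de.loc[s_tilde.index] += beta * s_tilde
        return s, sig, de, var

    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(5)
        betas = []
        for _ in range(40):
            s, sig, de, var = self.simulate(rng, beta=0.0)
            res = expression_wls(s, sig, de, var)
            benef = [r for r in res if r.target_class == BENEFICIAL][0]
            betas.append(benef.beta / benef.beta_se)
        assert abs(np.mean(betas)) < 0.4

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            s, sig, de, var = self.simulate(rng, beta=0.5)
            res = expression_wls(s, sig, de, var)
            benef = [r for r in res if r.target_class == BENEFICIAL][0]
            if abs(benef.beta - 0.5) <= 2 * benef.beta_se:
                hits += 1
        assert hits / 100 >= 0.90

    def test_equal_weights_match_ols(self):
        rng = np.random.default_rng(7)
        s, sig, de, _ = self.simulate(rng)
        var = pd.Series(1.0, index=s.index)
        res = expression_wls(s, sig, de, var)
        benef = [r for r in res if r.target_class == BENEFICIAL][0]
        _, s_tilde = classify_and_normalize(s, sig, BENEFICIAL)
        ref = sm.OLS(
            de.loc[s_tilde.index].to_numpy(),
            sm.add_constant(s_tilde.to_numpy()),
        ).fit()
        assert benef.beta == pytest.approx(ref.params[1], abs=1e-10)

    def test_rejects_nonpositive_variances(self):
        rng = np.random.default_rng(8)
        s, sig, de, var = self.simulate(rng)
        var.iloc[0] = 0.0
        with pytest.raises(ValueError):
            expression_wls(s, sig, de, var)


class TestPermutationTest:
    def test_identical_intervals_give_large_p(self):
        rng = np.random.default_rng(9)
        s, sig = toy_column(rng)
        mutated = pd.Series(rng.random(len(s)) < 0.3, index=s.index).astype(int)
        obs, p = slope_permutation_test(
            s, sig, mutated, mutated, n_perm=50, rng=rng
        )
        assert obs == 0.0
        assert p == 1.0

    def test_planted_difference_reaches_minimum_p(self):
        rng = np.random.default_rng(10)
        s, sig = toy_column(rng, n_neutral=200, n_benef=100)
        _, s_tilde = classify_and_normalize(s, sig, BENEFICIAL)
        x = pd.Series(0.0, index=s.index)
        x.loc[s_tilde.index] = s_tilde
        pa = 1 / (1 + np.exp(-(3.0 * x - 1)))
        pb = 1 / (1 + np.exp(-(-3.0 * x - 1)))
        ma = pd.Series(rng.random(len(s)) < pa, index=s.index).astype(int)
        mb = pd.Series(rng.random(len(s)) < pb, index=s.index).astype(int)
        n_perm = 200
        obs, p = slope_permutation_test(s, sig, ma, mb, n_perm=n_perm, rng=rng)
        assert p == pytest.approx(1 / (n_perm + 1))

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(11)
        s, sig = toy_column(rng)
        m = pd.Series(0, index=s.index)
        with pytest.raises(ValueError):
            slope_permutation_test(s, sig, m, m, n_perm=0)

    def test_type_one_error_controlled(self):
        # null: both intervals drawn from the same establishment model
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 60
        for _ in range(n_sim):
            s, sig = toy_column(rng, n_neutral=80, n_benef=30, n_delet=0)
            p_est = 0.3
            ma = pd.Series(rng.random(len(s)) < p_est, index=s.index).astype(int)
            mb = pd.Series(rng.random(len(s)) < p_est, index=s.index).astype(int)
            _, p = slope_permutation_test(s, sig, ma, mb, n_perm=60, rng=rng)
            rejections += p <= 0.05
        assert rejections / n_sim <= 0.12


class TestRankCompare:
    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(13)
        groups = {
            "neutral": rng.normal(0, 1, 100),
            "beneficial": rng.normal(1, 1, 100),
        }
        df = rank_compare(groups)
        assert df.loc[0, "p"] < 0.05

    def test_identical_distributions_not_detected(self):
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(30):
            x = rng.normal(0, 1, 60)
            y = rng.normal(0, 1, 60)
            ps.append(rank_compare({"a": x, "b": y}).loc[0, "p"])
        assert np.mean(np.array(ps) < 0.05) <= 0.15

    def test_small_groups_skipped(self):
        df = rank_compare({"a": np.array([1.0]), "b": np.arange(10.0)})
        assert len(df) == 0

    def test_median_split_sizes_differ_by_at_most_one(self):
        s = pd.Series(np.random.default_rng(15).normal(size=11))
        lo, hi = split_by_median(s)
        assert abs(len(lo) - len(hi)) <= 1
        assert s[lo].max() <= s[hi].min()


class TestMutatedStatus:
    def test_filters_applied(self):
        clones = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "clone": ["c1", "c1", "c2", "c1"],
                "mutation_type": ["missense", "synonymous", "missense", "indel"],
            }
        )
        flags = mutated_status(
            clones,
            genes=["a", "b", "c", "d", "e"],
            clones=["c1"],
            preexisting={"d"},
        )
        assert flags.tolist() == [1, 0, 0, 0, 0]
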