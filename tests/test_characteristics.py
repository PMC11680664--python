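import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from forgetting.characteristics import (
    DOCUMENTED_DROPS,
    PREDICTORS_13,
    log_transform_delays,
    one_vs_rest_logistic,
    one_way_anova,
    predictor_correlation_matrix,
    reduce_predictors,
    tukey_pairwise,
)

from conftest import RETAINED_PREDICTORS


class TestCorrelationMatrix:
    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": rng.normal(size=30)})
        frame["y"] = frame["x"]
        frame["z"] = rng.normal(size=30)
        corr = predictor_correlation_matrix(frame, ["x", "y", "z"])
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_range_equals_longest_when_shortest_constant(self):
        longest = np.array([10.0, 100.0, 1000.0, 5000.0])
        frame = pd.DataFrame(
            {"shortest_ri": 1.0, "longest_ri": longest, "ri_range": longest - 1.0}
        )
        with pytest.warns(UserWarning, match="constant"):
            corr = predictor_correlation_matrix(
                frame, ["shortest_ri", "longest_ri", "ri_range"]
            )
        assert corr.loc["longest_ri", "ri_range"] == pytest.approx(1.0)
        assert np.isnan(corr.loc["shortest_ri", "longest_ri"])

    def test_planted_collinearity_visible_in_synthetic_corpus(self, covariate_corpus):
        frame = log_transform_delays(covariate_corpus.characteristics_frame())
        corr = predictor_correlation_matrix(frame, PREDICTORS_13)
        # range and average track the longest interval; learning tracks complexity
        assert corr.loc["longest_ri", "ri_range"] > 0.9
        assert corr.loc["longest_ri", "average_ri"] > 0.9
        assert corr.loc["complexity", "degree_of_learning"] > 0.7


class TestReducePredictors:
    def test_documented_mode_drops_13_to_9(self, covariate_corpus):
        frame = log_transform_delays(covariate_corpus.characteristics_frame())
        corr = predictor_correlation_matrix(frame, PREDICTORS_13)
        retained, log = reduce_predictors(corr)
        assert len(retained) == 9
        assert set(retained) == set(RETAINED_PREDICTORS)
        assert {entry["dropped"] for entry in log} == set(DOCUMENTED_DROPS)

    def test_no_high_correlations_all_retained_in_greedy_mode(self):
        corr = pd.DataFrame(
            np.eye(3) * 0.8 + 0.2, columns=list("abc"), index=list("abc")
        )
        retained, log = reduce_predictors(corr, mode="greedy")
        assert retained == list("abc") and log == []

    def test_greedy_mode_breaks_perfect_pair(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]],
            columns=list("abc"), index=list("abc"),
        )
        retained, log = reduce_predictors(corr, mode="greedy")
        assert len(retained) == 2 and "c" in retained
        assert len(log) == 1

    def test_greedy_mode_never_retains_collinear_pair(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(60, 3))
        frame = pd.DataFrame(base, columns=list("abc"))
        frame["d"] = frame["a"] * 0.97 + rng.normal(scale=0.1, size=60)
        frame["e"] = -frame["b"]
        corr = frame.corr()
        retained, _ = reduce_predictors(corr, threshold=0.7, mode="greedy")
        sub = corr.loc[retained, retained].abs().values
        np.fill_diagonal(sub, 0.0)
        assert sub.max() < 0.7


class TestAnova:
    def test_hand_computed_two_groups(self):
        # SSB = 1.5, SSW = 4, df (1, 4) -> F = 1.5, eta_p^2 = 1.5/5.5
        res = one_way_anova([1, 2, 3, 2, 3, 4], ["g1"] * 3 + ["g2"] * 3)
        assert res.f == pytest.approx(1.5)
        assert res.eta_p2 == pytest.approx(0.272727, abs=1e-6)
        assert res.df_between == 1 and res.df_within == 4

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f == pytest.approx(0.0)

    def test_equal_means_unequal_variance(self):
        res = one_way_anova([2, 2, 2, 0, 2, 4], ["a"] * 3 + ["b"] * 3)
        assert res.f == pytest.approx(0.0)

    def test_small_groups_excluded_with_notice(self):
        res = one_way_anova([1, 2, 3, 4, 9], ["a", "a", "b", "b", "c"])
        assert res.excluded_groups == ("c",)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=60)
        groups = list(np.repeat(["a", "b", "c"], 20))
        from scipy.stats import f_oneway

        ours = one_way_anova(values, groups)
        ref = f_oneway(values[:20], values[20:40], values[40:])
        assert ours.f == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_type_one_error_calibrated_under_shuffling(self, covariate_corpus):
        """Shuffled pattern labels should reject at the nominal 5% rate."""
        frame = covariate_corpus.characteristics_frame()
        labels = [covariate_corpus.labels[i].value for i in frame["dataset_id"]]
        values = frame["complexity"].to_numpy(dtype=float)
        rng = np.random.default_rng(11)
        rejections = sum(
            one_way_anova(values, rng.permutation(labels)).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestTukey:
    def test_identical_groups(self):
        results = tukey_pairwise([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        (res,) = results
        assert res.d == pytest.approx(0.0)
        assert res.p_adj > 0.95

    def test_cohens_d_definition(self):
        # means 0 and 1, pooled SD 1 -> d = 1
        g1 = [-1.0, 0.0, 1.0]
        g2 = [0.0, 1.0, 2.0]
        (res,) = tukey_pairwise(g1 + g2, ["a"] * 3 + ["b"] * 3)
        assert res.d == pytest.approx(1.0)

    def test_adjusted_p_matches_statsmodels(self):
        """Three-group toy case agrees with the reference HSD implementation."""
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(0.8, 1, 15), rng.normal(0.4, 1, 15)]
        )
        groups = list(np.repeat(["a", "b", "c"], 15))
        ours = {
            (r.group_a, r.group_b): r.p_adj for r in tukey_pairwise(values, groups)
        }
        ref = pairwise_tukeyhsd(values, groups)
        # statsmodels orders pairs the same way (sorted group names)
        for pair, p_ref in zip(
            [("a", "b"), ("a", "c"), ("b", "c")], ref.pvalues
        ):
            assert ours[pair] == pytest.approx(p_ref, abs=2e-3)

    def test_all_pairs_reported(self):
        values = list(range(12))
        groups = list(np.repeat(["a", "b", "c", "d"], 3))
        assert len(tukey_pairwise(values, groups)) == 6


class TestLogistic:
    @staticmethod
    def _null_frame(n=300, seed=0):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        labels = rng.choice(["a", "b"], size=n).tolist()
        return frame, labels

    def test_null_predictor_has_small_z(self):
        frame, labels = self._null_frame()
        results = one_vs_rest_logistic(frame, labels, "a", ["x1", "x2"])
        for res in results:
            assert abs(res.z) < 3.5
            assert not res.penalized

    def test_planted_coefficient_sign_recovered(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.normal(size=n)
        logits = -0.4 + 1.2 * x
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        frame = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
        labels = ["pos" if yi else "neg" for yi in y]
        (rx, rn) = one_vs_rest_logistic(frame, labels, "pos", ["x", "noise"])
        assert rx.coef > 0 and rx.p < 0.001
        assert abs(rn.z) < 3.5

    def test_duplicate_predictor_warns(self):
        frame, labels = self._null_frame()
        frame["x1_copy"] = frame["x1"]
        with pytest.warns(UserWarning, match="near-duplicate"):
            one_vs_rest_logistic(frame, labels, "a", ["x1", "x1_copy"])

    def test_too_few_positives_rejected(self):
        frame, labels = self._null_frame()
        labels = ["a"] * 5 + ["b"] * (len(labels) - 5)
        with pytest.raises(ValueError):
            one_vs_rest_logistic(frame, labels, "a", ["x1"])

    def test_perfect_separation_falls_back_to_penalized(self):
        frame = pd.DataFrame({"x": np.r_[np.zeros(15), np.ones(15)]})
        labels = ["neg"] * 15 + ["pos"] * 15
        results = one_vs_rest_logistic(frame, labels, "pos", ["x"])
        assert results[0].penalized
        assert results[0].coef > 0

    def test_planted_corpus_associations_recovered(self, covariate_corpus):
        """Ground-truth labels recover the planted covariate directions."""
        frame = log_transform_delays(covariate_corpus.characteristics_frame())
        labels = [covariate_corpus.labels[i].value for i in frame["dataset_id"]]

        def coef(category, predictor):
            results = one_vs_rest_logistic(
                frame, labels, category, RETAINED_PREDICTORS
            )
            return next(r for r in results if r.predictor == predictor)

        assert coef("linear", "longest_ri").coef > 0
        assert coef("power", "complexity").coef < 0
        assert coef("power", "multiple_study").coef < 0
        assert coef("increasing", "initial_memory").coef < 0
        assert coef("exponential_power", "initial_memory").coef > 0
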