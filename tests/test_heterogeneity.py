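from math import comb, sqrt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spothet import (
    NormalizedMatrix,
    ValidationError,
    classify_responders,
    control_reference_threshold,
    gene_distribution_stats,
    ks_gaussian_test,
    responder_condition_test,
    select_high_responding,
    skewness_screen,
)

from oracles import ks_statistic_direct, skewness_moments


class TestGeneDistributionStats:
    def test_symmetric_vector_zero_skew(self):
        _, _, skew = gene_distribution_stats([1, 2, 3])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_bernoulli_like_vector(self):
        _, _, skew = gene_distribution_stats([0, 0, 0, 1])
        assert skew == pytest.approx(2 / sqrt(3), rel=1e-12)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=50)
        _, _, s = gene_distribution_stats(x)
        _, _, s_pos = gene_distribution_stats(3.2 * x + 5)
        _, _, s_neg = gene_distribution_stats(-1.5 * x + 2)
        assert s_pos == pytest.approx(s, rel=1e-9)
        assert s_neg == pytest.approx(-s, rel=1e-9)

    def test_matches_moment_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = rng.normal(size=rng.integers(5, 60)) ** 3
            _, _, s = gene_distribution_stats(x)
            assert s == pytest.approx(skewness_moments(x), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            gene_distribution_stats([2.0, 2.0, 2.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError, match="n >= 3"):
            gene_distribution_stats([1.0, 2.0])


class TestKSGaussian:
    def test_exact_normal_quantiles_fit(self):
        n = 100
        x = stats.norm.ppf((np.arange(n) + 0.5) / n)
        d, p = ks_gaussian_test(x)
        assert d < 0.01
        assert p > 0.99

    def test_d_matches_direct_ecdf(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3, 2, size=40)
        d, _ = ks_gaussian_test(x)
        direct = ks_statistic_direct(
            x, lambda v: stats.norm.cdf(v, x.mean(), x.std(ddof=1)))
        assert d == pytest.approx(direct, abs=1e-12)

    def test_exponential_sample_rejected(self):
        rejections = 0
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.exponential(size=200)
            _, p = ks_gaussian_test(x)
            rejections += p < 0.05
        assert rejections >= 95

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError, match="n >= 5"):
            ks_gaussian_test([1.0, 2.0, 3.0])

    def test_lilliefors_more_conservative_than_asymptotic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60) + 0.3 * rng.exponential(size=60)
        _, p_asymp = ks_gaussian_test(x)
        _, p_lf = ks_gaussian_test(x, lilliefors=True)
        assert p_lf <= p_asymp + 1e-9


def norm_matrix(values, gene_ids=None):
    arr = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i:03d}" for i in range(arr.shape[0])]
    return NormalizedMatrix(genes, [f"s{j}" for j in range(arr.shape[1])], arr)


class TestSkewnessScreen:
    def test_mean_filter_is_strict(self):
        rng = np.random.default_rng(5)
        vals = np.vstack([np.full(30, 0.005) + rng.uniform(0, 1e-4, 30),
                          rng.lognormal(0, 1, size=(15, 30))])
        with pytest.warns(UserWarning, match="unstable"):
            table = skewness_screen(norm_matrix(vals), min_mean=0.01)
        assert not table.iloc[0]["passes_mean_filter"]
        assert table["passes_mean_filter"].sum() == 15

    def test_exactly_top_fraction_flagged(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(0, 1, size=(100, 40)) + 1.0
        table = skewness_screen(norm_matrix(vals), min_mean=0.01, top_frac=0.05)
        assert table["top_skew"].sum() == 5
        flagged = set(table[table["top_skew"]]["gene_id"])
        top5 = set(table.sort_values(["skewness", "gene_id"],
                                     ascending=[False, True]).head(5)["gene_id"])
        assert flagged == top5

    def test_planted_long_tail_gene_flagged(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            vals = rng.normal(10, 1, size=(100, 60))
            # long right tail: a quarter of spots at 4x the typical level
            tail = rng.normal(40, 4, size=15)
            vals[0, :15] = tail
            table = skewness_screen(norm_matrix(vals), min_mean=0.01, top_frac=0.05)
            hits += bool(table.iloc[0]["top_skew"])
        assert hits >= 45


class TestResponders:
    def test_threshold_is_strict(self):
        labels = classify_responders(pd.Series({"a": 0.0, "b": 0.5}), threshold=0.0)
        assert labels["a"] == "Non-responding"
        assert labels["b"] == "Responding"

    def test_all_zero_all_non_responding(self):
        labels = classify_responders(pd.Series({"a": 0.0, "b": 0.0}), threshold=0.0)
        assert (labels == "Non-responding").all()

    def test_control_reference_threshold_quantile(self):
        x = np.arange(101, dtype=float)
        assert control_reference_threshold(x, 0.95) == pytest.approx(95.0)
        with pytest.raises(ValidationError):
            control_reference_threshold([], 0.95)


class TestResponderConditionTest:
    def frame(self, losa_resp, losa_non, ctrl_resp, ctrl_non):
        rows = (
            [("Losa", "Responding")] * losa_resp
            + [("Losa", "Non-responding")] * losa_non
            + [("Ctrl", "Responding")] * ctrl_resp
            + [("Ctrl", "Non-responding")] * ctrl_non)
        return pd.DataFrame(rows, columns=["condition", "responder"])

    def test_identical_proportions_not_significant(self):
        _, p, _ = responder_condition_test(self.frame(5, 5, 5, 5))
        assert p > 0.5

    def test_perfect_separation_matches_enumeration(self):
        table, p, _ = responder_condition_test(self.frame(20, 0, 0, 20))
        np.testing.assert_array_equal(table.counts, [[20, 0], [0, 20]])
        assert p == pytest.approx(2 / comb(40, 20), rel=1e-9)

    def test_single_condition_rejected(self):
        with pytest.raises(ValidationError, match="both conditions"):
            responder_condition_test(self.frame(5, 5, 0, 0))


class TestSelectHighResponding:
    def test_top_quarter_of_eight(self):
        vals = {"S1": pd.Series({f"s{i}": float(i) for i in range(1, 9)})}
        out = select_high_responding(vals, 0.25)
        assert set(out["spot_id"]) == {"s8", "s7"}

    def test_full_fraction_keeps_all(self):
        vals = {"S1": pd.Series({"a": 1.0, "b": 2.0})}
        assert len(select_high_responding(vals, 1.0)) == 2

    def test_samples_ranked_independently(self):
        vals = {
            "S1": pd.Series({"a": 100.0, "b": 99.0, "c": 1.0, "d": 0.0}),
            "S2": pd.Series({"e": 5.0, "f": 4.0, "g": 1.0, "h": 0.0}),
        }
        out = select_high_responding(vals, 0.25)
        assert set(out["spot_id"]) == {"a", "e"}

    def test_output_size_is_sum_of_ceils(self):
        rng = np.random.default_rng(7)
        vals = {f"S{k}": pd.Series(rng.normal(size=n),
                                   index=[f"S{k}s{i}" for i in range(n)])
                for k, n in enumerate([7, 10, 3])}
        out = select_high_responding(vals, 0.25)
        import math
        assert len(out) == sum(math.ceil(0.25 * n) for n in [7, 10, 3])

    def test_empty_sample_skipped_with_warning(self):
        vals = {"S1": pd.Series(dtype=float), "S2": pd.Series({"a": 1.0})}
        with pytest.warns(UserWarning, match="S1"):
            out = select_high_responding(vals, 0.5)
        assert list(out["spot_id"]) == ["a"]

    def test_tie_break_by_spot_id(self):
        vals = {"S1": pd.Series({"z": 1.0, "a": 1.0, "m": 1.0, "b": 0.0})}
        out = select_high_responding(vals, 0.25)
        assert list(out["spot_id"]) == ["a"]
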