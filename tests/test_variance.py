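import numpy as np
import pandas as pd
import pytest

from repsel import (
    BootstrapConfig,
    ValidationError,
    aggregate_replicates,
    binomial_error_variance,
    bootstrap_statistic,
    component_variance,
    decompose,
    decompose_variance,
    relativize_matrix,
    signed_difference_test,
)
from repsel.variance import PAIRS, sign_test_pvalue

from conftest import make_aggregates


def gaussian_components(rng, n, cvs, mean=10.0):
    """Independent positive pseudo-components with given CVs; mRS = product."""
    df = pd.DataFrame(
        {c: rng.normal(mean, cv * mean, n) for c, cv in cvs.items()}
    )
    df["mRS"] = df.prod(axis=1)
    return df


class TestDecomposeVariance:
    def test_constant_component_zero_terms(self):
        rng = np.random.default_rng(0)
        df = gaussian_components(
            rng, 200, {"F": 0.04, "MS": 0.0, "STE": 0.04, "SFE": 0.04}
        )
        dec = decompose_variance(relativize_matrix(df))
        assert dec.variances_raw["MS"] == pytest.approx(0, abs=1e-24)
        for (a, b), v in dec.covariances.items():
            if "MS" in (a, b):
                assert v == pytest.approx(0, abs=1e-15)

    def test_small_cv_sum_identity(self):
        # oracle: direct Monte Carlo of the product at n = 1e5; at small CV the
        # variance of the relative product approaches the sum of variances
        # plus twice the covariances
        rng = np.random.default_rng(42)
        df = gaussian_components(
            rng, 100_000, {"F": 0.05, "MS": 0.05, "STE": 0.05, "SFE": 0.05}
        )
        dec = decompose_variance(relativize_matrix(df))
        assert (
            abs(dec.var_mrs_observed - dec.model_total) / dec.var_mrs_observed
            < 0.05
        )

    def test_pairwise_deletion_counts(self):
        rng = np.random.default_rng(1)
        df = gaussian_components(rng, 50, {"F": 0.1, "MS": 0.1, "STE": 0.1, "SFE": 0.1})
        df.loc[:9, "STE"] = np.nan
        df.loc[5:14, "SFE"] = np.nan
        rel = relativize_matrix(df)
        dec = decompose_variance(rel)
        assert dec.n_used["STE"] == 40
        assert dec.n_used["cov_STE:SFE"] == 50 - 10 - 5

    def test_percentages_sum_to_100(self, imputed_dataset):
        agg = aggregate_replicates(imputed_dataset)
        dec = decompose(agg)
        assert sum(dec.percentages.values()) == pytest.approx(100, abs=1e-9)

    def test_observed_denominator_option(self, imputed_dataset):
        agg = aggregate_replicates(imputed_dataset)
        dec = decompose(agg, denominator="observed")
        assert sum(dec.percentages.values()) == pytest.approx(
            100 * dec.model_total / dec.var_mrs_observed, rel=1e-9
        )

    def test_invalid_error_component_rejected(self):
        rng = np.random.default_rng(2)
        df = gaussian_components(rng, 30, {"F": 0.1, "MS": 0.1, "STE": 0.1, "SFE": 0.1})
        with pytest.raises(ValidationError, match="sampling-error"):
            decompose_variance(relativize_matrix(df), {"F": 0.01})

    def test_negative_corrected_variance_clipped(self, caplog):
        rng = np.random.default_rng(3)
        df = gaussian_components(rng, 30, {"F": 0.1, "MS": 0.1, "STE": 0.01, "SFE": 0.1})
        with caplog.at_level("WARNING"):
            dec = decompose_variance(relativize_matrix(df), {"STE": 1.0})
        assert dec.variances_corrected["STE"] == 0.0
        assert "clipped" in caplog.text

    def test_bootstrap_cis_attached(self, imputed_dataset):
        agg = aggregate_replicates(imputed_dataset)
        dec = decompose(agg, BootstrapConfig(iterations=200, seed=5))
        lo, hi = dec.ci["var_STE"]
        assert lo <= dec.variances_corrected["STE"] <= hi


class TestBinomialErrorVariance:
    def test_degenerate_proportions_zero_error(self):
        # every focal share is 0 or 1 -> binomial noise vanishes
        agg = make_aggregates(
            [(10, 5, 20, 20, 10, 10), (10, 5, 20, 20, 10, 10), (8, 4, 10, 10, 5, 5)]
        )
        assert binomial_error_variance(agg, "STE", "closed_form") == 0
        assert binomial_error_variance(agg, "STE", "monte_carlo", draws=50, seed=1) == 0

    def test_toy_closed_form_value(self):
        # 4 replicates, s_t=20, p=0.5, MS=1: proportion variance 0.0125,
        # component mean 0.5 -> relativized error variance 0.0125/0.25 = 0.05
        agg = make_aggregates([(5, 5, 20, 10, 10, 5)] * 4)
        e = binomial_error_variance(agg, "STE", "closed_form")
        assert e == pytest.approx(0.05, rel=1e-12)

    def test_toy_matches_independent_mc_oracle(self):
        agg = make_aggregates([(5, 5, 20, 10, 10, 5)] * 4)
        closed = binomial_error_variance(agg, "STE", "closed_form")
        # independent oracle: redraw focal sperm counts, recompute the
        # relativized component (observed mean 0.5 as the divisor), variance
        # attributable to redrawing
        rng = np.random.default_rng(7)
        draws = 100_000
        x = rng.binomial(20, 0.5, size=(draws, 4)) / 20.0  # MS = 1 divides out
        rel = x / 0.5
        v = rel.var(axis=1, ddof=1)  # observed base variance is exactly 0
        se = v.std(ddof=1) / np.sqrt(draws)
        assert abs(closed - v.mean()) < 3 * se
        # our monte_carlo estimator agrees with the same oracle
        mc = binomial_error_variance(agg, "STE", "monte_carlo", draws=20_000, seed=8)
        assert abs(mc - v.mean()) < 3 * se + 3 * v.std(ddof=1) / np.sqrt(20_000)

    def test_methods_agree_on_structured_data(self, imputed_dataset):
        agg = aggregate_replicates(imputed_dataset)
        for comp in ("STE", "SFE"):
            closed = binomial_error_variance(agg, comp, "closed_form")
            mc = binomial_error_variance(agg, comp, "monte_carlo", draws=3000, seed=11)
            assert mc == pytest.approx(closed, rel=0.25)

    def test_monotone_in_denominator(self):
        agg1 = make_aggregates([(5, 5, 20, 10, 10, 5), (5, 5, 20, 8, 10, 5)])
        agg2 = agg1.copy()
        agg2[["s_t", "s_f"]] = agg2[["s_t", "s_f"]] * 2  # same p-hat, doubled n
        e1 = binomial_error_variance(agg1, "STE", "closed_form")
        e2 = binomial_error_variance(agg2, "STE", "closed_form")
        assert e2 <= e1 / 2 + 1e-15

    def test_rejects_uncorrected_components(self):
        agg = make_aggregates([(5, 5, 20, 10, 10, 5)] * 3)
        for comp in ("F", "MS"):
            with pytest.raises(ValidationError):
                binomial_error_variance(agg, comp)


class TestBootstrapStatistic:
    def test_constant_statistic_degenerate_ci(self):
        df = pd.DataFrame({"x": [4.2] * 20})
        res = bootstrap_statistic(
            lambda d: d["x"].mean(), df, BootstrapConfig(iterations=100, seed=1)
        )
        assert res.ci == (pytest.approx(4.2), pytest.approx(4.2))

    def test_clt_interval_width(self):
        # oracle: CLT closed form for the CI width of a sample mean
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(0, 1, 150)})
        res = bootstrap_statistic(
            lambda d: d["x"].mean(), df, BootstrapConfig(iterations=10_000, seed=2)
        )
        width = res.ci[1] - res.ci[0]
        expected = 2 * 1.96 * df["x"].std(ddof=1) / np.sqrt(150)
        assert abs(width - expected) / expected < 0.10

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.normal(size=40)})
        cfg = BootstrapConfig(iterations=300, seed=77)
        a = bootstrap_statistic(lambda d: d["x"].var(ddof=1), df, cfg)
        b = bootstrap_statistic(lambda d: d["x"].var(ddof=1), df, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_failure_rate_guard(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        # the plug-in call itself must work, so fail only on resamples
        calls = {"n": 0}

        def mostly_bad(d):
            calls["n"] += 1
            if calls["n"] == 1:
                return 0.0
            raise RuntimeError("boom")

        with pytest.raises(ValidationError, match="undefined"):
            bootstrap_statistic(mostly_bad, df, BootstrapConfig(iterations=50, seed=3))

    def test_series_statistic(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x": rng.normal(size=60), "y": rng.normal(size=60)})
        res = bootstrap_statistic(
            lambda d: pd.Series({"mx": d["x"].mean(), "vy": d["y"].var(ddof=1)}),
            df,
            BootstrapConfig(iterations=200, seed=4),
        )
        assert set(res.ci.index) == {"mx", "vy"}
        assert res.draws.shape == (200, 2)

    def test_bootstrap_mean_converges_to_plugin(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.normal(size=80)})
        plug = df["x"].var(ddof=1) * (1 - 1 / 80)  # bootstrap expectation of var
        errs = {}
        for b in (100, 10_000):
            gaps = []
            for seed in range(5):
                res = bootstrap_statistic(
                    lambda d: d["x"].var(ddof=1),
                    df,
                    BootstrapConfig(iterations=b, seed=seed),
                )
                gaps.append(abs(res.draws.mean() - plug))
            errs[b] = np.mean(gaps)
        assert errs[10_000] < errs[100]


class TestSignedDifferenceTest:
    def test_self_comparison_p_is_one(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"STE": rng.normal(1, 0.3, 60)})
        res = signed_difference_test(
            df, "STE", "STE", BootstrapConfig(iterations=200, seed=5)
        )
        assert res["p_value"] == 1.0

    def test_sign_test_pvalue_rules(self):
        assert sign_test_pvalue(np.ones(100)) == pytest.approx(2 / 100)
        assert sign_test_pvalue(np.zeros(100)) == 1.0
        mixed = np.concatenate([np.ones(50), -np.ones(50)])
        assert sign_test_pvalue(mixed) == 1.0

    def test_power_at_4x_variance(self):
        # oracle: repeated simulation; 4x relative variance at n=150 should
        # essentially always reject (scaled to 60 runs to stay in budget)
        rng = np.random.default_rng(13)
        cfg = BootstrapConfig(iterations=300, seed=6)
        rejections = 0
        runs = 60
        for _ in range(runs):
            df = pd.DataFrame(
                {
                    "STE": rng.normal(1, 0.4, 150),
                    "MS": rng.normal(1, 0.2, 150),
                }
            )
            res = signed_difference_test(df, "STE", "MS", cfg)
            if res["p_value"] < 0.01:
                rejections += 1
        assert rejections >= 0.95 * runs

    def test_null_calibration_uniform_p(self):
        # oracle: null-calibration simulation; under identical distributions
        # the p-values over repeated datasets are approximately uniform
        # (scaled: 300 runs, B=250, n=100)
        rng = np.random.default_rng(14)
        cfg = BootstrapConfig(iterations=250, seed=7)
        pvals = []
        for _ in range(300):
            df = pd.DataFrame(
                {
                    "STE": rng.normal(1, 0.25, 100),
                    "MS": rng.normal(1, 0.25, 100),
                }
            )
            pvals.append(signed_difference_test(df, "STE", "MS", cfg)["p_value"])
        from scipy import stats

        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.01
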