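"""Weighted quantiles, GEE, Box-Cox adequacy and the signed-rank test."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hhsaf.estimation import (boxcox_check, fit_gee, level_distribution,
                              paired_compare, signed_rank_test, summarise,
                              weighted_quantile)
from hhsaf.instrument import score_responses
from hhsaf.synthetic import CountryProfile, GenerationConfig, generate_dataset


# ---------------------------------------------------------------------------
# weighted quantiles

class TestWeightedQuantile:
    def test_brute_force_cumulative_scan(self):
        # cumulative weights 0.1, 0.2, 1.0: first >= 0.5 is the value 3
        assert weighted_quantile([1, 2, 3], [1, 1, 8], 0.5) == 3.0

    def test_extremes(self):
        v, w = [5, 1, 9], [1, 2, 3]
        assert weighted_quantile(v, w, 0.0) == 1.0
        assert weighted_quantile(v, w, 1.0) == 9.0

    def test_equal_weights_reduces_to_sort_and_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            v = rng.integers(0, 100, size=rng.integers(1, 25)).astype(float)
            q = float(rng.uniform(0, 1))
            got = weighted_quantile(v, np.ones_like(v), q)
            # oracle: sort and scan the cumulative count, midpoint on a tie
            s = np.sort(v)
            n = len(s)
            cum = np.arange(1, n + 1) / n
            k = int(np.searchsorted(cum, q - 1e-12))
            k = min(k, n - 1)
            if abs(cum[k] - q) <= 1e-12 and k < n - 1:
                expected = (s[k] + s[k + 1]) / 2
            else:
                expected = s[k]
            assert got == expected

    def test_exact_tie_takes_midpoint(self):
        assert weighted_quantile([1, 2, 3, 4], [1, 1, 1, 1], 0.5) == 2.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_quantile([], [], 0.5)


class TestSummarise:
    def _scored(self, instrument, totals, income):
        """Build scored responses hitting exact totals via a uniform grid."""
        from conftest import make_response_row
        rows = []
        for i, (t, inc) in enumerate(zip(totals, income)):
            rows.append(make_response_row(f"r{i}", {}, income=inc))
        df = pd.DataFrame(rows)
        scores = pd.DataFrame({
            **{f"score_{el}": pd.array([t // 5 for t in totals], dtype="Int64")
               for el in ("system_change", "training_education",
                          "evaluation_feedback", "reminders_workplace",
                          "safety_climate")},
            **{f"complete_{el}": True
               for el in ("system_change", "training_education",
                          "evaluation_feedback", "reminders_workplace",
                          "safety_climate")},
            "total_score": pd.array([(t // 5) * 5 for t in totals],
                                    dtype="Int64"),
        })
        scores["level"] = "basic"
        return df, scores

    def test_equal_weights_reproduce_unweighted_median(self, instrument):
        totals = list(range(0, 505, 5))
        df, scores = self._scored(instrument, totals, ["high"] * len(totals))
        out = summarise(scores, pd.Series(1.0, index=scores.index))
        row = out[(out["measure"] == "total") & (out["stratum"] == "overall")]
        assert row["median"].iloc[0] == 250.0
        assert row["n"].iloc[0] == len(totals)

    def test_empty_stratum_emits_missing_row(self, instrument):
        df, scores = self._scored(instrument, [100, 200], ["high", "high"])
        df["income_level"] = pd.Categorical(df["income_level"],
                                            categories=["high", "low"])
        out = summarise(scores, pd.Series(1.0, index=scores.index),
                        strata_variables=["income_level"], meta=df)
        # categorical with an unobserved level is simply absent; observed works
        high = out[(out["stratum"] == "high") & (out["measure"] == "total")]
        assert high["n"].iloc[0] == 2

    def test_income_gap_recovery_on_synthetic_data(self, instrument):
        """Weighted-median high-low gap within +/-20 of the configured 140."""
        countries = tuple(
            CountryProfile(country_code=f"Y{i:02d}", who_region="europe",
                           income_level="high" if i % 2 == 0 else "low",
                           population=5_000_000, n_facilities=110)
            for i in range(10))
        cfg = GenerationConfig(
            countries=countries, income_effects={"high": 0.0, "low": -140.0},
            duplicate_rate=0.0, partial_rate=0.0, seed=2027)
        resp, _, _ = generate_dataset(cfg, instrument)
        scores = score_responses(resp, instrument)
        out = summarise(scores, pd.Series(1.0, index=scores.index),
                        strata_variables=["income_level"], meta=resp)
        med = out[(out["measure"] == "total")].set_index("stratum")["median"]
        assert med["high"] - med["low"] == pytest.approx(140.0, abs=20.0)


class TestLevelDistribution:
    def _scores(self, totals, levels):
        return pd.DataFrame({
            "total_score": pd.array(totals, dtype="Int64"),
            "level": levels})

    def test_all_advanced(self):
        s = self._scores([400] * 5, ["advanced"] * 5)
        out = level_distribution(s, pd.Series(1.0, index=s.index))
        assert out.set_index("level").loc["advanced", "proportion"] == 1.0

    def test_published_percentage_arithmetic(self):
        """Weighted 1254 of 3008 advanced -> 41.7% at one decimal."""
        prop = 1254 / 3008
        assert round(100 * prop, 1) == 41.7

    def test_proportions_invariant_to_weight_scaling(self):
        s = self._scores([100, 300, 400, 450], ["inadequate", "intermediate",
                                                "advanced", "advanced"])
        w = pd.Series([1.0, 2.0, 3.0, 4.0], index=s.index)
        a = level_distribution(s, w)["proportion"]
        b = level_distribution(s, 10 * w)["proportion"]
        assert np.allclose(a, b)
        assert a.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# GEE

def _gee_frame(rng, n=60, n_countries=12):
    df = pd.DataFrame({
        "country_code": [f"C{i % n_countries}" for i in range(n)],
        "income_level": rng.choice(["low", "lower_middle", "upper_middle",
                                    "high"], n),
        "who_region": rng.choice(["africa", "europe", "americas"], n),
        "nationally_coordinated": rng.choice([False, True], n),
        "facility_level": rng.choice(["primary", "secondary", "tertiary"], n),
        "facility_type": rng.choice(["public", "private"], n),
    })
    df["total_score"] = (250.0 + 60 * (df["facility_type"] == "private")
                         - 50 * (df["income_level"] == "low")
                         + rng.normal(0, 30, n))
    return df


class TestGee:
    def test_reduces_to_ols_with_singleton_clusters(self):
        """Independence + singleton clusters + unit weights = OLS."""
        rng = np.random.default_rng(5)
        df = _gee_frame(rng, n=80)
        df["country_code"] = [f"U{i}" for i in range(len(df))]  # singletons
        res = fit_gee(df, cov_struct="independence")
        # oracle: normal equations solved directly
        from hhsaf.estimation import DEFAULT_COVARIATES, _build_design
        X, _ = _build_design(df, DEFAULT_COVARIATES)
        X = X[["intercept"] + list(res.table["term"])]
        beta = np.linalg.solve(X.T @ X, X.T @ df["total_score"].to_numpy())
        np.testing.assert_allclose(res.table["estimate"].to_numpy(),
                                   beta[1:], rtol=1e-8)

    def test_duplicating_rows_with_half_weights_is_invariant(self):
        rng = np.random.default_rng(6)
        df = _gee_frame(rng, n=60)
        res1 = fit_gee(df, weights=pd.Series(1.0, index=df.index),
                       cov_struct="independence")
        df2 = pd.concat([df, df], ignore_index=True)
        res2 = fit_gee(df2, weights=pd.Series(0.5, index=df2.index),
                       cov_struct="independence")
        np.testing.assert_allclose(res1.table["estimate"].to_numpy(),
                                   res2.table["estimate"].to_numpy(),
                                   rtol=1e-6)

    def test_reference_categories_absent_from_table(self):
        rng = np.random.default_rng(7)
        res = fit_gee(_gee_frame(rng, n=100))
        terms = set(res.table["term"])
        for banned in ("income_level[high]", "who_region[africa]",
                       "facility_level[primary]", "facility_type[public]"):
            assert banned not in terms
        assert (res.table["ci_low"] <= res.table["ci_high"]).all()

    def test_single_cluster_rejected(self):
        rng = np.random.default_rng(8)
        df = _gee_frame(rng, n=30)
        df["country_code"] = "ONLY"
        with pytest.raises(ValueError, match="clusters"):
            fit_gee(df)

    def test_singular_design_lists_aliased_terms(self):
        rng = np.random.default_rng(9)
        df = _gee_frame(rng, n=40)
        df["facility_type"] = np.where(df["income_level"] == "low",
                                       "private", "public")
        df["income_level"] = np.where(df["facility_type"] == "private",
                                      "low", "high")
        with pytest.raises(ValueError, match="aliased"):
            fit_gee(df)


class TestBoxCox:
    def test_linear_gaussian_covers_lambda_one(self):
        """Profile interval contains 1 in >= 90% of replicates."""
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.uniform(0, 1, 120)
            y = 200 + 100 * x + rng.normal(0, 20, 120)
            bc = boxcox_check(y, x)
            hits += bc.ci_low <= 1.0 <= bc.ci_high
        assert hits >= 0.9 * n_rep

    def test_exponential_outcome_prefers_log(self):
        rng = np.random.default_rng(11)
        lams = []
        for _ in range(20):
            x = rng.uniform(0, 1, 150)
            y = np.exp(2 + 1.5 * x + rng.normal(0, 0.3, 150))
            lams.append(boxcox_check(y, x).lambda_hat)
        assert abs(np.mean(lams)) < 0.25

    def test_grid_maximiser_matches_brute_force(self):
        rng = np.random.default_rng(12)
        y = rng.gamma(4, 20, 200)
        bc = boxcox_check(y)
        assert bc.lambda_hat == bc.grid[int(np.argmax(bc.loglik))]

    def test_intercept_only_agrees_with_scipy_llf(self):
        rng = np.random.default_rng(13)
        y = rng.gamma(5, 10, 150)
        bc = boxcox_check(y)
        # scipy's boxcox_llf is the same profile likelihood for the
        # intercept-only model, up to a constant
        ours = bc.loglik
        theirs = np.array([scipy.stats.boxcox_llf(l, y) for l in bc.grid])
        assert np.argmax(ours) == np.argmax(theirs)

    def test_nonpositive_outcomes_shifted(self):
        y = np.array([-3.0, 0.0, 5.0, 10.0, 12.0, 20.0])
        bc = boxcox_check(y)
        assert bc.shift == 4.0


# ---------------------------------------------------------------------------
# signed-rank

def enumerate_signed_rank_p(diffs):
    """Exhaustive oracle: all 2^n sign assignments of the absolute ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2.0
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= abs(w_obs - mean) - 1e-9:
            count += 1
    return count / 2 ** n


class TestSignedRank:
    def test_example_vector_against_enumeration(self):
        d = [5, 3, 1, -2]
        got = signed_rank_test(d)
        assert got["p_value"] == pytest.approx(enumerate_signed_rank_p(d))

    def test_randomised_suite_matches_enumeration(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n = int(rng.integers(1, 11))
            d = rng.integers(-6, 7, size=n)
            got = signed_rank_test(d)
            if (d != 0).sum() == 0:
                assert np.isnan(got["p_value"])
            else:
                assert got["p_value"] == pytest.approx(
                    enumerate_signed_rank_p(d)), f"diffs {d}"

    def test_agrees_with_scipy_exact_when_no_ties(self):
        d = np.array([3.1, -1.2, 5.7, 8.4, -2.2, 0.6, 4.4, -7.9])
        ours = signed_rank_test(d)["p_value"]
        theirs = scipy.stats.wilcoxon(d, method="exact").pvalue
        assert ours == pytest.approx(theirs)

    def test_zeros_dropped(self):
        got = signed_rank_test([0, 0, 3, -1])
        assert got["n_nonzero"] == 2

    def test_all_zero_not_applicable(self):
        got = signed_rank_test([0.0, 0.0])
        assert np.isnan(got["p_value"])

    def test_large_n_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(15)
        d = rng.normal(0.3, 1, size=25)
        exact = signed_rank_test(d, exact_max_n=25)["p_value"]
        approx = signed_rank_test(d, exact_max_n=0)["p_value"]
        assert approx == pytest.approx(exact, abs=0.02)


class TestPairedCompare:
    def _pairs(self, t1, t2, income=None):
        df = pd.DataFrame({"facility_id": [f"f{i}" for i in range(len(t1))],
                           "total_1": t1, "total_2": t2})
        if income is not None:
            df["income_level"] = income
        return df

    def test_all_zero_differences_reported_not_tested(self):
        out = paired_compare(self._pairs([100, 200], [100, 200]))
        row = out.iloc[0]
        assert row["median_diff"] == 0.0
        assert np.isnan(row["p_value"])
        assert "not applicable" in row["note"]

    def test_median_of_differences_not_difference_of_medians(self):
        # pairing matters: medians 200 vs 210 but paired differences all +50
        t1 = [100, 200, 300]
        t2 = [150, 250, 350]
        out = paired_compare(self._pairs(t1, t2))
        assert out.iloc[0]["median_diff"] == 50.0

    def test_stratified_output_with_empty_stratum(self):
        out = paired_compare(
            self._pairs([100, 150], [120, 130], income=["high", "high"]),
            strata=["income_level"])
        assert set(out["stratum"]) == {"overall", "high"}

    def test_type_i_error_calibration_under_null(self):
        """With zero drift the p-values are uniform (KS check, 200 reps)."""
        rng = np.random.default_rng(16)
        pvals = []
        for _ in range(200):
            d = rng.normal(0, 12, size=60)
            pvals.append(signed_rank_test(d)["p_value"])
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
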