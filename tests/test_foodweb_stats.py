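"""Group summaries, OLS/AIC, sensitivity statistics, and the month shift.

Every numerically substantive path is checked against an independent
route: a sort-based quartile oracle, the explicit normal-equations
solution, statsmodels OLS, and a nested-grid-search confounder-strength
oracle for the robustness value.
"""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ipoc.foodweb_stats import (
    Encoding,
    RankDeficiencyError,
    compare_models,
    fit_ols,
    month_shift_check,
    monthly_summary,
    partial_r2,
    proportion_above,
    robustness_value,
    sensitivity,
    shift_months,
    species_summary,
    summarize_values,
)
from ipoc.hprint import run_pipeline

# --------------------------------------------------------------------------
# box-plot summaries
# --------------------------------------------------------------------------


def _oracle_quartiles(values):
    """Textbook linear-interpolation quartiles on the sorted sample."""
    v = sorted(values)
    n = len(v)

    def q(p):
        pos = p * (n - 1)
        lo, frac = int(math.floor(pos)), pos - math.floor(pos)
        hi = min(lo + 1, n - 1)
        return v[lo] + frac * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)


def test_quartiles_match_textbook_interpolation():
    s = summarize_values(("sp",), [10.0, 20.0, 30.0])
    assert (s.q1, s.median, s.q3) == (15.0, 20.0, 25.0)


def test_single_sample_group_is_degenerate():
    s = summarize_values(("sp",), [42.0])
    assert s.q1 == s.median == s.q3 == 42.0
    assert s.n == 1 and s.outlier_values == ()
    assert s.whisker_low == s.whisker_high == 42.0


@given(
    st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=60),
    st.sampled_from(["tukey", "minmax"]),
)
@settings(max_examples=150, deadline=None)
def test_summary_matches_sort_based_oracle(values, whiskers):
    s = summarize_values(("g",), values, whiskers)
    q1, med, q3 = _oracle_quartiles(values)
    assert s.q1 == pytest.approx(q1, abs=1e-9)
    assert s.median == pytest.approx(med, abs=1e-9)
    assert s.q3 == pytest.approx(q3, abs=1e-9)
    assert s.q1 <= s.median <= s.q3
    if whiskers == "minmax":
        assert s.whisker_low == min(values)
        assert s.whisker_high == max(values)
        assert s.outlier_values == ()
    else:
        iqr = q3 - q1
        expected_out = sorted(
            v for v in values if v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr
        )
        assert list(s.outlier_values) == pytest.approx(expected_out)
        inside = [v for v in values if v not in s.outlier_values]
        assert s.whisker_low == min(inside)
        assert s.whisker_high == max(inside)


def test_species_summary_one_group_per_species(make_sample):
    samples = [
        make_sample(sample_id=f"A{i}", species="Macoma calcarea",
                    taxon_group="benthic_invertebrate", habitat="benthic",
                    hbi3=float(i + 1))
        for i in range(3)
    ] + [
        make_sample(sample_id=f"B{i}", species="Boreogadus saida",
                    hbi3=2.0)
        for i in range(2)
    ]
    results, _ = run_pipeline(samples)
    groups = species_summary(results, samples)
    assert len(groups) == 2
    keys = {g.group_key for g in groups}
    assert ("benthic_invertebrate", "Macoma calcarea") in keys
    assert ("fish", "Boreogadus saida") in keys
    assert {g.n for g in groups} == {3, 2}


def test_monthly_summary_logs_missing_months(make_sample):
    samples = [
        make_sample(sample_id=f"S{i}", month=None if i < 2 else 7)
        for i in range(10)
    ]
    results, _ = run_pipeline(samples)
    groups, n_missing = monthly_summary(results, samples)
    assert n_missing == 2
    assert len(groups) == 1
    assert groups[0].group_key == (7,)
    assert groups[0].n == 8


def test_monthly_summary_requires_some_months(make_sample):
    samples = [make_sample(sample_id="S", month=None)]
    results, _ = run_pipeline(samples)
    with pytest.raises(ValueError):
        monthly_summary(results, samples)


def test_generator_coded_may_dip_appears_in_monthly_bins(default_dataset):
    """Pelagic iPOC is suppressed after the May bloom by construction; the
    May bin mean must fall below the April bin mean."""
    samples, _, results, _ = default_dataset
    groups, _ = monthly_summary(results, samples)
    means = {g.group_key[0]: g.mean for g in groups}
    assert means[5] < means[4]


# --------------------------------------------------------------------------
# threshold proportions
# --------------------------------------------------------------------------


def test_proportion_above_counts_strictly(make_sample):
    # iPOC values ~60.3, 40.9, 55.2 via chosen H-Prints
    hs = [40.0, 59.0, 45.0]
    samples = [
        make_sample(sample_id=f"S{i}", ip25=100.0 - h, hbi2=0.0, hbi3=h)
        for i, h in enumerate(hs)
    ]
    results, _ = run_pipeline(samples)
    count, prop = proportion_above(results, 50.0)
    assert count == 2
    assert prop == pytest.approx(2 / 3)


def test_proportion_above_zero_threshold_all_pelagic(make_sample):
    """Clamped pelagic-only values are exactly 0; strict inequality means
    none exceed a 0% threshold."""
    samples = [
        make_sample(sample_id=f"S{i}", ip25=0.0, hbi2=0.0, hbi3=1.0)
        for i in range(4)
    ]
    results, _ = run_pipeline(samples)
    count, prop = proportion_above(results, 0.0)
    assert (count, prop) == (0, 0.0)


def test_proportion_above_partition_sums_to_one(default_dataset):
    _, _, results, _ = default_dataset
    included = [r for r in results if r.included]
    count, prop = proportion_above(results, 50.0)
    below_or_equal = sum(1 for r in included if r.ipoc_pct <= 50.0)
    assert count + below_or_equal == len(included)


def test_proportion_above_needs_included_samples(make_sample):
    samples = [make_sample(ip25=0.0, hbi2=0.0, hbi3=0.0)]
    results, _ = run_pipeline(samples)
    with pytest.raises(ValueError):
        proportion_above(results, 50.0)


# --------------------------------------------------------------------------
# OLS / AIC
# --------------------------------------------------------------------------


def _frame(n, rng=None, with_month=True):
    rng = rng or np.random.default_rng(0)
    habitats = np.array(["pelagic", "mixed", "sympagic", "benthic"])
    return pd.DataFrame(
        {
            "habitat": rng.choice(habitats, size=n),
            "month": rng.integers(1, 13, size=n).astype(float),
            "year": rng.integers(1982, 2020, size=n).astype(float),
            "latitude": rng.uniform(55, 82, size=n),
        }
    )


def test_noiseless_line_recovered_exactly():
    df = pd.DataFrame(
        {"latitude": [55.0, 60.0, 65.0, 70.0, 75.0]}
    )
    df["ipoc_pct"] = 2.0 * df["latitude"]
    fit = fit_ols(df, ("latitude",))
    assert fit.coef("latitude") == pytest.approx(2.0, abs=1e-10)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)


def test_t_equals_coef_over_se():
    rng = np.random.default_rng(3)
    df = _frame(40, rng)
    df["ipoc_pct"] = 50 + 0.3 * df["latitude"] + rng.normal(0, 5, 40)
    fit = fit_ols(df, ("month", "latitude", "habitat"))
    for c in fit.columns:
        assert fit.t(c) == pytest.approx(fit.coef(c) / fit.se(c), rel=1e-12)


def test_small_system_matches_normal_equations_oracle():
    X = np.array(
        [[1, 0.0, 1.0], [1, 1.0, 0.5], [1, 2.0, -0.3],
         [1, 3.0, 0.9], [1, 4.0, -1.2], [1, 5.0, 0.4]]
    )
    y = np.array([1.0, 2.2, 2.9, 4.5, 4.6, 6.3])
    beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y
    df = pd.DataFrame({"latitude": X[:, 1], "year": X[:, 2], "ipoc_pct": y})
    fit = fit_ols(df, ("latitude", "year"))
    assert np.allclose(fit.coefficients, beta_oracle, rtol=1e-10)


def test_random_systems_match_oracle_and_statsmodels():
    """QR fit agrees with (X'X)^-1 X'y to 1e-8 and with statsmodels on
    coefficients, SEs, log-likelihood; our AIC also counts the error
    variance, so it exceeds statsmodels' by exactly 2."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        df = _frame(50, rng)
        df["ipoc_pct"] = (
            40 + 0.4 * df["latitude"] - 0.6 * df["month"]
            + rng.normal(0, 4, 50)
        )
        fit = fit_ols(df, ("month", "year", "latitude", "habitat"))
        X = np.column_stack(
            [
                np.ones(50),
                df["month"],
                df["year"],
                df["latitude"],
                df["habitat"].map(
                    {"pelagic": 0, "mixed": 1, "sympagic": 2, "benthic": 3}
                ),
            ]
        )
        y = df["ipoc_pct"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, beta, rtol=1e-8)
        smf = sm.OLS(y, X).fit()
        assert np.allclose(fit.coefficients, smf.params, rtol=1e-8)
        assert np.allclose(fit.standard_errors, smf.bse, rtol=1e-8)
        assert np.allclose(fit.p_values, smf.pvalues, rtol=1e-8, atol=1e-12)
        assert fit.log_likelihood == pytest.approx(smf.llf, rel=1e-10)
        assert fit.aic == pytest.approx(smf.aic + 2.0, rel=1e-10)


def test_aic_identity_holds_exactly():
    rng = np.random.default_rng(5)
    df = _frame(30, rng)
    df["ipoc_pct"] = rng.normal(50, 10, 30)
    fit = fit_ols(df, ("latitude",))
    assert fit.aic == pytest.approx(
        2 * fit.n_params - 2 * fit.log_likelihood, abs=1e-12
    )
    assert fit.n_params == 3  # intercept, slope, error variance


def test_rank_deficiency_names_collinear_terms():
    df = pd.DataFrame(
        {
            "latitude": [55.0, 60.0, 65.0, 70.0, 75.0, 80.0],
            "year": [55.0, 60.0, 65.0, 70.0, 75.0, 80.0],  # duplicate column
            "ipoc_pct": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
    with pytest.raises(RankDeficiencyError, match="year|latitude"):
        fit_ols(df, ("latitude", "year"))


def test_treatment_coding_reports_per_level_columns():
    rng = np.random.default_rng(9)
    df = _frame(80, rng)
    df["ipoc_pct"] = rng.normal(50, 10, 80)
    enc = Encoding(habitat_coding="treatment")
    fit = fit_ols(df, ("habitat",), encoding=enc)
    assert {"habitat[benthic]", "habitat[mixed]", "habitat[sympagic]"} <= set(
        fit.columns
    )


def test_nested_equal_rss_models_differ_by_two_per_parameter():
    """Add a regressor orthogonal to the smaller model's residual: RSS is
    unchanged, so AIC rises by exactly 2 for the extra parameter."""
    rng = np.random.default_rng(21)
    n = 40
    lat = rng.uniform(55, 82, n)
    y = 30 + 0.5 * lat + rng.normal(0, 3, n)
    Xs = np.column_stack([np.ones(n), lat])
    resid = y - Xs @ np.linalg.solve(Xs.T @ Xs, Xs.T @ y)
    extra = rng.normal(0, 1, n)
    # orthogonalize against the small design and its residual
    basis = np.column_stack([Xs, resid])
    extra -= basis @ np.linalg.lstsq(basis, extra, rcond=None)[0]
    df = pd.DataFrame({"latitude": lat, "year": extra, "ipoc_pct": y})
    small = fit_ols(df, ("latitude",))
    big = fit_ols(df, ("latitude", "year"))
    assert big.rss == pytest.approx(small.rss, rel=1e-10)
    assert big.aic - small.aic == pytest.approx(2.0, abs=1e-8)


def test_compare_models_ranks_and_breaks_ties():
    rng = np.random.default_rng(2)
    df = _frame(60, rng)
    df["year"] = df["month"]  # identical columns -> identical AIC
    df["ipoc_pct"] = 40 + 1.0 * df["month"] + rng.normal(0, 2, 60)
    fits = [fit_ols(df, f) for f in (("year",), ("month",))]
    ranked = compare_models(fits)
    assert ranked[0].fit.aic == ranked[1].fit.aic
    assert ranked[0].fit.formula == ("month",)  # lexicographic tie-break
    assert ranked[0].delta_aic == 0.0
    assert [r.rank for r in ranked] == [1, 2]


def test_compare_single_fit():
    df = _frame(20)
    df["ipoc_pct"] = np.arange(20, dtype=float)
    ranked = compare_models([fit_ols(df, ("latitude",))])
    assert len(ranked) == 1 and ranked[0].delta_aic == 0.0


def test_compare_rejects_different_responses():
    df1 = _frame(30)
    df1["ipoc_pct"] = np.arange(30, dtype=float)
    df2 = _frame(25)
    df2["ipoc_pct"] = np.arange(25, dtype=float)
    with pytest.raises(ValueError):
        compare_models([fit_ols(df1, ("latitude",)), fit_ols(df2, ("latitude",))])


# --------------------------------------------------------------------------
# sensitivity statistics
# --------------------------------------------------------------------------


def _rv_grid_oracle(t, df, alpha=1.0, q=1.0):
    """Nested grid search for the confounder strength that drives the
    bias-adjusted t statistic down to the significance threshold.

    A confounder with partial R2 = x with both treatment and outcome
    shifts the estimate by se*sqrt(df)*x/sqrt(1-x) and rescales the SE, so
    the adjusted statistic is (q-scaled) t_adj = (f_q - x/sqrt(1-x)) *
    sqrt(df-1) with f_q = q*|t|/sqrt(df).  The robustness value is the
    smallest x making |t_adj| <= t_crit(alpha, df-1).
    """
    fq = q * abs(t) / math.sqrt(df)
    t_crit = 0.0 if alpha >= 1 else abs(sps.t.ppf(alpha / 2, df - 1))

    def t_adj(x):
        return (fq - x / math.sqrt(1.0 - x)) * math.sqrt(df - 1)

    lo, hi = 0.0, 1.0 - 1e-12
    if t_adj(lo) <= t_crit:
        return 0.0
    for _ in range(4):  # nested refinement: 1e-2 -> 1e-8
        xs = np.linspace(lo, hi, 101)
        vals = np.array([t_adj(x) for x in xs])
        idx = int(np.argmax(vals <= t_crit))
        lo, hi = xs[idx - 1], xs[idx]
    return 0.5 * (lo + hi)


def test_rv_zero_when_no_effect():
    assert robustness_value(0.0, 100) == 0.0
    assert partial_r2(0.0, 100) == 0.0


def test_rv_approaches_one_as_partial_r2_approaches_one():
    assert partial_r2(1e9, 50) == pytest.approx(1.0, abs=1e-12)
    assert robustness_value(1e9, 50) == pytest.approx(1.0, rel=1e-6)


def test_rv_closed_form_matches_grid_oracle():
    rv = robustness_value(2.0, 100, q=1.0, alpha=1.0)
    oracle = _rv_grid_oracle(2.0, 100)
    assert rv == pytest.approx(oracle, abs=1e-6)


@pytest.mark.parametrize("t,df", [(1.0, 20), (2.0, 100), (4.8, 2100), (8.0, 50)])
def test_rv_alpha_matches_grid_oracle(t, df):
    rv = robustness_value(t, df, q=1.0, alpha=0.05)
    oracle = _rv_grid_oracle(t, df, alpha=0.05)
    assert rv == pytest.approx(oracle, abs=1e-6)


def test_partial_r2_matches_two_model_rss_route():
    """t^2/(t^2+df) must equal the variance-explained ratio from fitting
    with and without the treatment column."""
    rng = np.random.default_rng(17)
    df = _frame(200, rng)
    df["ipoc_pct"] = (
        45 + 2.0 * df["habitat"].map(
            {"pelagic": 0, "mixed": 1, "sympagic": 2, "benthic": 3}
        )
        + 0.3 * df["latitude"] + rng.normal(0, 6, 200)
    )
    full = fit_ols(df, ("latitude", "habitat"))
    restricted = fit_ols(df, ("latitude",))
    oracle = (restricted.rss - full.rss) / restricted.rss
    got = sensitivity(full, "habitat").partial_r2_outcome
    assert got == pytest.approx(oracle, rel=1e-10)


@given(st.floats(0.1, 50), st.floats(0.1, 50))
@settings(max_examples=100, deadline=None)
def test_rv_monotone_in_t(t1, t2):
    df = 120
    r1 = robustness_value(t1, df)
    r2 = robustness_value(t2, df)
    if t1 < t2:
        assert r1 <= r2 + 1e-12
    assert 0.0 <= r1 <= 1.0


def test_rv_alpha_never_exceeds_rv(default_dataset):
    samples, _, results, _ = default_dataset
    from ipoc.foodweb_stats import _included_frame

    df = _included_frame(results, samples).dropna(subset=["month"])
    fit = fit_ols(df, ("month", "latitude", "habitat", "month:habitat"))
    s = sensitivity(fit, "habitat", alpha=0.05)
    assert s.robustness_value_alpha <= s.robustness_value
    assert 0.0 <= s.partial_r2_outcome <= 1.0


def test_sensitivity_unknown_treatment():
    df = _frame(30)
    df["ipoc_pct"] = np.arange(30, dtype=float)
    fit = fit_ols(df, ("latitude",))
    with pytest.raises(KeyError):
        sensitivity(fit, "habitat")


# --------------------------------------------------------------------------
# month-shift robustness check
# --------------------------------------------------------------------------


def _shift_frame(n=400, seed=8):
    rng = np.random.default_rng(seed)
    df = _frame(n, rng)
    score = df["habitat"].map(
        {"pelagic": 0, "mixed": 1, "sympagic": 2, "benthic": 3}
    )
    df["ipoc_pct"] = (
        40 + 6.0 * score + 0.4 * df["latitude"] - 0.3 * df["month"] * score
        + rng.normal(0, 8, n)
    )
    return df


def test_shift_zero_is_identity():
    df = _shift_frame()
    cmp = month_shift_check(df, ("month", "latitude", "habitat"), shift=0)
    assert cmp.original.coefficients == cmp.shifted.coefficients


def test_shift_full_cycle_is_identity():
    df = _shift_frame()
    cmp = month_shift_check(df, ("month", "latitude", "habitat"), shift=-12)
    assert cmp.original.coefficients == cmp.shifted.coefficients
    assert (shift_months(df["month"], -12) == df["month"]).all()


def test_shift_wraparound_example():
    assert shift_months(pd.Series([1, 4, 12]), -3).tolist() == [10, 1, 9]


def test_shift_requires_month_term():
    df = _shift_frame()
    with pytest.raises(ValueError, match="month"):
        month_shift_check(df, ("latitude", "habitat"), shift=-3)


def test_shift_preserves_habitat_conclusion_on_balanced_data():
    """With months uniform over the year, relabeling them three months
    earlier must not flip the sign or significance of the habitat term."""
    df = _shift_frame(n=600)
    cmp = month_shift_check(
        df, ("month", "latitude", "habitat", "month:habitat"), shift=-3
    )
    t0, t1 = cmp.original.t("habitat"), cmp.shifted.t("habitat")
    assert np.sign(t0) == np.sign(t1) == 1.0
    assert cmp.original.p("habitat") < 0.001
    assert cmp.shifted.p("habitat") < 0.001
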