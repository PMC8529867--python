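"""LASSO-Cox selection, Cox fits, Kaplan-Meier and the endpoint analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from deltarad import phantoms, survival
from deltarad.survival import (
    SurvivalError,
    cox_fit,
    cox_partial_loglik,
    dichotomize,
    km_median,
    km_split,
    lasso_cox_select,
    run_endpoint_analysis,
)


# ---------------------------------------------------------------------------
# clinical dichotomization
# ---------------------------------------------------------------------------


def test_ldh_flag_uses_one_point_five_times_uln():
    flags = dichotomize(ldh_pre=700, ldh_post=700, n_sites=1, uln=450)
    assert flags["ldh_high"] is True  # 700 > 675
    flags = dichotomize(ldh_pre=675, ldh_post=675, n_sites=1, uln=450)
    assert flags["ldh_high"] is False  # boundary goes to the low group


def test_three_metastatic_sites_is_high():
    assert dichotomize(400, 400, n_sites=3, uln=450)["sites_high"] is True
    assert dichotomize(400, 400, n_sites=2, uln=450)["sites_high"] is False


def test_perc_ldh_boundary_goes_low():
    # as-printed: 100*(500-400)/500 = +20 exactly -> low group
    flags = dichotomize(500, 400, n_sites=1, uln=450)
    assert flags["perc_ldh"] == pytest.approx(20.0)
    assert flags["perc_ldh_high"] is False


def test_missing_uln_is_an_error():
    with pytest.raises(SurvivalError):
        dichotomize(400, 400, 1, uln=0)


# ---------------------------------------------------------------------------
# partial likelihood oracle
# ---------------------------------------------------------------------------


def naive_breslow_loglik(beta, X, time, event):
    lp = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += lp[i] - math.log(sum(math.exp(lp[j]) for j in risk))
    return ll


def test_partial_loglik_matches_naive_double_loop():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(5, 25))
        X = rng.normal(size=(n, 3))
        beta = rng.normal(size=3)
        time = np.round(rng.exponential(10, n), 1)  # rounding forces ties
        event = rng.random(n) < 0.7
        fast = cox_partial_loglik(beta, X, time, event)
        assert fast == pytest.approx(naive_breslow_loglik(beta, X, time, event), rel=1e-10)


# ---------------------------------------------------------------------------
# LASSO-Cox
# ---------------------------------------------------------------------------


def _toy_survival(n=120, beta=-0.8, seed=0, p_noise=4):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 1 + p_noise)),
        columns=["driver"] + [f"noise{i}" for i in range(p_noise)],
    )
    out = phantoms.draw_survival(
        X, {"driver": beta}, math.log(2) / 20, math.log(2) / 60, rng
    )
    return X, out["time_months"].to_numpy(), out["event"].to_numpy()


def test_huge_penalty_zeroes_every_coefficient():
    X, time, event = _toy_survival()
    sel = lasso_cox_select(X, time, event, alphas=[1e6, 1e5], seed=0)
    assert (sel.coef_path.to_numpy() == 0).all()


def test_collinear_duplicate_still_selected():
    X, time, event = _toy_survival(seed=3)
    X["driver_copy"] = X["driver"]
    sel = lasso_cox_select(X, time, event, seed=3)
    assert {"driver", "driver_copy"} & set(sel.selected)


def test_zero_variance_feature_dropped_with_warning():
    X, time, event = _toy_survival(seed=5)
    X["flat"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        sel = lasso_cox_select(X, time, event, seed=5)
    assert "flat" in sel.dropped_features


def test_rows_with_missing_values_dropped_and_counted():
    X, time, event = _toy_survival(seed=6)
    X.loc[X.index[:4], "noise0"] = np.nan
    sel = lasso_cox_select(X, time, event, seed=6)
    assert sel.n_dropped_rows == 4
    assert sel.n_used == len(X) - 4


def test_all_censored_outcome_rejected():
    X, time, _ = _toy_survival()
    with pytest.raises(SurvivalError, match="events"):
        lasso_cox_select(X, time, np.zeros(len(X), dtype=bool))


def test_near_zero_penalty_matches_unpenalized_cox():
    X, time, event = _toy_survival(n=150, seed=7, p_noise=2)
    sel = lasso_cox_select(X, time, event, alphas=[1e-6], seed=7)
    Xs = (X - X.mean()) / X.std(ddof=0)
    fit = cox_fit(Xs, time, event)
    for name in X.columns:
        assert sel.coef_path[sel.lambda_grid[0]][name] == pytest.approx(
            fit.summary.loc[name, "coef"], abs=0.02
        )


# ---------------------------------------------------------------------------
# Cox fits
# ---------------------------------------------------------------------------


def test_two_group_fit_recovers_rate_ratio_roughly():
    rng = np.random.default_rng(1)
    n = 400
    group = np.repeat([0.0, 1.0], n // 2)
    time = rng.exponential(1.0 / (0.05 * 2.0**group))
    fit = cox_fit(pd.DataFrame({"group": group}), time, np.ones(n, dtype=bool))
    assert 1.6 <= fit.hr("group") <= 2.4
    assert fit.summary.loc["group", "ci_low"] < fit.hr("group") < fit.summary.loc["group", "ci_high"]


def test_constant_covariate_rejected_unless_dropped():
    rng = np.random.default_rng(2)
    design = pd.DataFrame({"x": rng.normal(size=50), "flat": np.ones(50)})
    time = rng.exponential(10, 50)
    with pytest.raises(SurvivalError, match="constant"):
        cox_fit(design, time, np.ones(50, dtype=bool))
    fit = cox_fit(design, time, np.ones(50, dtype=bool), drop_constant=True)
    assert list(fit.summary.index) == ["x"]
    assert fit.notes


def test_hr_one_iff_zero_coefficient():
    rng = np.random.default_rng(3)
    design = pd.DataFrame({"x": rng.normal(size=200)})
    time = rng.exponential(10, 200)
    fit = cox_fit(design, time, np.ones(200, dtype=bool))
    assert math.exp(fit.summary.loc["x", "coef"]) == pytest.approx(fit.hr("x"))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_median_of_exponential_without_censoring():
    rng = np.random.default_rng(4)
    time = rng.exponential(12 / math.log(2), 500)
    assert 11.0 <= km_median(time, np.ones(500, dtype=bool)) <= 13.0


def test_km_estimator_equals_empirical_survival_without_censoring():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(5)
    time = rng.exponential(10, 80)
    kmf = KaplanMeierFitter().fit(time, np.ones(80))
    for t in np.quantile(time, [0.1, 0.5, 0.9]):
        assert kmf.survival_function_at_times(t).iloc[0] == pytest.approx(
            (time > t).mean()
        )


def test_identical_groups_give_zero_statistic_and_p_one():
    time = np.r_[np.arange(1.0, 11.0), np.arange(1.0, 11.0)]
    values = np.r_[np.zeros(10), np.ones(10)]
    result = km_split(values, time, np.ones(20, dtype=bool), cutoff=0.5)
    assert result.logrank_statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_one_sided_split_suggests_fixed_cutoff():
    time = np.arange(1.0, 11.0)
    with pytest.raises(SurvivalError, match="fixed cutoff"):
        km_split(np.full(10, 2.0), time, np.ones(10, dtype=bool), cutoff=5.0)


def test_median_split_separates_planted_groups():
    rng = np.random.default_rng(6)
    n = 200
    marker = np.r_[rng.normal(-1, 0.3, n // 2), rng.normal(1, 0.3, n // 2)]
    time = rng.exponential(1.0 / np.where(marker > 0, 0.1, 0.025))
    result = km_split(marker, time, np.ones(n, dtype=bool))
    assert result.cutoff_mode == "median"
    assert result.median_above < result.median_below
    assert result.p_value < 0.001


# ---------------------------------------------------------------------------
# endpoint orchestration
# ---------------------------------------------------------------------------


def test_tiny_cohort_refused_for_insufficient_events():
    spec = phantoms.CohortSpec(n_patients=2, lesions_per_patient=(1, 1), seed=0)
    table = phantoms.generate_cohort(spec).patient_table
    with pytest.raises(SurvivalError, match="insufficient events"):
        run_endpoint_analysis(table, survival.OS)


def test_endpoint_report_structure_on_small_cohort():
    spec = phantoms.CohortSpec(n_patients=40, seed=11)
    table = phantoms.generate_cohort(spec).patient_table
    report = run_endpoint_analysis(table, survival.OS, seed=11)
    assert report.endpoint == survival.OS
    assert report.n_patients == 40
    assert report.lasso_baseline.k_folds == 10
    # the four published report markers are always fitted
    for marker in ("kurtosis_ssf2", "kurtosis_ssf3", "perc_entropy_ssf4", "perc_entropy_ssf6"):
        assert marker in report.cox_fits
        assert f"{marker}@median" in report.km_results
    tab = survival.cox_table(report)
    assert {"endpoint", "model", "covariate", "hr", "p"} <= set(tab.columns)


def test_unknown_endpoint_rejected():
    with pytest.raises(SurvivalError, match="OS or PFS"):
        run_endpoint_analysis(pd.DataFrame(), "DFS")
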