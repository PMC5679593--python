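"""Parametric LoS regression: exclusion, screening, fitting, selection."""

import numpy as np
import pandas as pd
import pytest

from triage_econ import defaults
from triage_econ.los import (
    AFTModel,
    build_design,
    exclude_outliers,
    fit_aft,
    mean_cohort_los,
    predict_los,
    select_family,
    univariate_screen,
)


def _lognormal_frame(rng, n=5000, intercept=2.0, beta=0.5, sigma=0.6):
    x = rng.random(n)
    return pd.DataFrame(
        {
            "peak_hours": x,
            "soc_los": np.exp(intercept + beta * x + sigma * rng.standard_normal(n)),
        }
    )


# ---------------------------------------------------------------- exclusion


def test_exclude_outliers_direct_threshold():
    retained, report = exclude_outliers([3.0, 70.0, 101.0, 5.0])
    assert list(retained) == [3.0, 5.0]
    assert report.n_excluded == 2
    assert report.excluded_values == (70.0, 101.0)


def test_exclude_outliers_identity_below_cap():
    values = [1.0, 64.9, 65.0]
    retained, report = exclude_outliers(values)
    assert list(retained) == values
    assert report.n_excluded == 0


def test_exclude_outliers_empty_input():
    retained, report = exclude_outliers([])
    assert len(retained) == 0 and report.n_excluded == 0


# ---------------------------------------------------------------- fitting


def test_lognormal_fit_recovers_parameters(rng):
    df = _lognormal_frame(rng)
    m = fit_aft(df, ["peak_hours"], family="lognormal")
    assert 1.95 <= m.params.loc["intercept", "coef"] <= 2.05
    assert m.params.loc["peak_hours", "coef"] == pytest.approx(0.5, abs=0.05)
    assert m.scale == pytest.approx(0.6, abs=0.03)
    assert m.n == 5000


def test_misspecified_exponential_has_higher_aic(rng):
    df = _lognormal_frame(rng)
    ln = fit_aft(df, ["peak_hours"], family="lognormal")
    ex = fit_aft(df, ["peak_hours"], family="exponential")
    assert ex.aic > ln.aic


def test_weibull_nests_exponential_in_likelihood(rng):
    """The selected richer model can never have lower log-likelihood than
    its nested special case on the same data."""
    df = _lognormal_frame(rng, n=2000)
    wb = fit_aft(df, ["peak_hours"], family="weibull")
    ex = fit_aft(df, ["peak_hours"], family="exponential")
    assert wb.loglik >= ex.loglik - 1e-6


def test_constant_column_reported_by_name():
    df = pd.DataFrame(
        {
            "peak_hours": np.zeros(100),
            "soc_los": np.exp(np.random.default_rng(0).normal(2.0, 0.5, 100)),
        }
    )
    with pytest.raises(ValueError, match="peak_hours"):
        fit_aft(df, ["peak_hours"], family="lognormal")


def test_nonpositive_los_rejected():
    df = pd.DataFrame({"peak_hours": [1.0, 2.0], "soc_los": [3.0, 0.0]})
    with pytest.raises(ValueError, match="positive"):
        fit_aft(df, ["peak_hours"])


def test_factor_design_uses_reference_coding(small_cohort):
    X, names = build_design(small_cohort.patients, ["site", "dyspnea"])
    assert "site[Detroit]" not in names  # reference level fixed at zero
    assert "dyspnea[yes]" in names and "dyspnea[no]" not in names
    assert X.shape[1] == 1 + 11 + 1


def test_fit_against_lifelines_oracle(rng):
    """Independent MLE cross-check: lifelines' log-normal AFT on the same
    uncensored data must land on the same coefficients."""
    lifelines = pytest.importorskip("lifelines")
    df = _lognormal_frame(rng, n=2000)
    mine = fit_aft(df, ["peak_hours"], family="lognormal")

    ll_df = pd.DataFrame(
        {"T": df["soc_los"], "E": 1, "peak_hours": df["peak_hours"]}
    )
    f = lifelines.LogNormalAFTFitter()
    f.fit(ll_df, duration_col="T", event_col="E")
    assert mine.params.loc["peak_hours", "coef"] == pytest.approx(
        f.params_[("mu_", "peak_hours")], abs=1e-3
    )
    assert mine.params.loc["intercept", "coef"] == pytest.approx(
        f.params_[("mu_", "Intercept")], abs=1e-3
    )


def test_weibull_fit_against_lifelines_oracle(rng):
    lifelines = pytest.importorskip("lifelines")
    n = 2000
    x = rng.random(n)
    # weibull AFT: log T = 1.5 + 0.4 x + 0.5 * Gumbel_min
    eps = np.log(rng.exponential(size=n))
    df = pd.DataFrame({"x": 0.0 + x, "soc_los": np.exp(1.5 + 0.4 * x + 0.5 * eps)})
    df = df.rename(columns={"x": "peak_hours"})
    mine = fit_aft(df, ["peak_hours"], family="weibull")
    f = lifelines.WeibullAFTFitter()
    f.fit(
        pd.DataFrame({"T": df["soc_los"], "E": 1, "peak_hours": df["peak_hours"]}),
        duration_col="T",
        event_col="E",
    )
    assert mine.params.loc["peak_hours", "coef"] == pytest.approx(
        f.params_[("lambda_", "peak_hours")], abs=2e-3
    )


# ---------------------------------------------------------------- screening


def test_screen_keeps_planted_strong_effect(rng):
    n = 2000
    dysp = rng.random(n) < 0.3
    df = pd.DataFrame(
        {
            "dyspnea": np.where(dysp, "yes", "no"),
            "soc_los": np.exp(2.0 + 0.5 * dysp + 0.6 * rng.standard_normal(n)),
        }
    )
    res = univariate_screen(df, "dyspnea", alpha=0.10)
    assert res.keep and res.p_value < 1e-6


def test_screen_alpha_one_always_keeps(rng):
    df = _lognormal_frame(rng, n=200, beta=0.0)
    assert univariate_screen(df, "peak_hours", alpha=1.0).keep


def test_screen_constant_covariate_dropped_with_warning():
    df = pd.DataFrame(
        {
            "dyspnea": ["no"] * 100,
            "soc_los": np.exp(np.random.default_rng(1).normal(2, 0.5, 100)),
        }
    )
    with pytest.warns(UserWarning, match="constant"):
        res = univariate_screen(df, "dyspnea")
    assert not res.keep


# ---------------------------------------------------------------- selection


def test_lognormal_data_selects_lognormal_consistently(rng):
    """AIC selection picks the generating family in nearly all replicates."""
    wins = 0
    reps = 25
    for _ in range(reps):
        df = _lognormal_frame(rng, n=3000)
        sel = select_family(
            df,
            ["peak_hours"],
            families=("lognormal", "weibull", "loglogistic", "exponential"),
        )
        wins += sel.chosen == "lognormal"
    assert wins / reps >= 0.95


def test_single_family_selected_trivially(rng):
    df = _lognormal_frame(rng, n=500)
    sel = select_family(df, ["peak_hours"], families=("weibull",))
    assert sel.chosen == "weibull"


def test_exponential_data_selects_exponential_or_unit_shape_weibull(rng):
    x = rng.random(3000)
    df = pd.DataFrame(
        {"peak_hours": x, "soc_los": rng.exponential(np.exp(1.0 + 0.3 * x))}
    )
    sel = select_family(
        df, ["peak_hours"], families=("exponential", "weibull", "lognormal")
    )
    assert sel.chosen in ("exponential", "weibull")
    if sel.chosen == "weibull":
        assert sel.models["weibull"].scale == pytest.approx(1.0, abs=0.05)


def test_selection_table_reports_medians(rng):
    df = _lognormal_frame(rng, n=1000)
    sel = select_family(df, ["peak_hours"], families=("lognormal", "weibull"))
    assert {"median_fitted", "median_observed"} <= set(sel.table.columns)
    ln = sel.table.loc["lognormal"]
    assert ln["median_fitted"] == pytest.approx(ln["median_observed"], rel=0.1)


# ---------------------------------------------------------------- prediction


def test_median_prediction_closed_form_at_reference():
    """A log-symmetric family's median is exp(linear predictor); at the
    reference covariate pattern that is exp(intercept)."""
    coeffs = defaults.LOS_COEFFS_NONAMI
    df = pd.DataFrame(
        {
            "site": ["Detroit"],
            "age_category": ["<=65"],
            "peak_hours": [0.0],
            "dyspnea": ["no"],
            "pain_intensity_positive": ["0"],
            "hr_category": ["normal"],
            "chf_history": ["no"],
        }
    )
    model = _model_from_coeffs(coeffs, defaults.NONAMI_COVARIATES, sigma=0.6)
    assert predict_los(model, df, "median")[0] == pytest.approx(
        np.exp(2.0077), rel=1e-9
    )


def _model_from_coeffs(coeffs, covariates, sigma):
    template = pd.DataFrame(
        {
            "site": ["Detroit"],
            "age_category": ["<=65"],
            "peak_hours": [0.0],
            "dyspnea": ["no"],
            "pain_intensity_positive": ["0"],
            "hr_category": ["normal"],
            "chf_history": ["no"],
        }
    )
    _, names = build_design(template, covariates)
    params = pd.DataFrame(
        {
            "coef": [coeffs.get(nm, 0.0) for nm in names],
            "se": 0.0,
            "ci_lower": 0.0,
            "ci_upper": 0.0,
            "p_value": 1.0,
        },
        index=names,
    )
    return AFTModel(
        family="lognormal",
        params=params,
        scale=sigma,
        scale_ci=(sigma, sigma),
        loglik=0.0,
        aic=0.0,
        bic=0.0,
        n=0,
        covariates=tuple(covariates),
    )


def test_zero_site_coefficient_equals_reference_prediction():
    model = _model_from_coeffs(
        {"intercept": 2.0, "site[Heidelberg]": 0.0}, ("site",), sigma=0.5
    )
    base = {
        "age_category": "<=65",
        "peak_hours": 0.0,
        "dyspnea": "no",
        "pain_intensity_positive": "0",
        "hr_category": "normal",
        "chf_history": "no",
    }
    ref = pd.DataFrame([{**base, "site": "Detroit"}])
    other = pd.DataFrame([{**base, "site": "Heidelberg"}])
    assert predict_los(model, ref, "mean")[0] == pytest.approx(
        predict_los(model, other, "mean")[0]
    )


def test_predicted_mean_matches_simulation(rng):
    """Simulation oracle: fit a cohort drawn from a known model and compare
    the predicted population mean with the empirical mean."""
    df = _lognormal_frame(rng, n=20_000)
    m = fit_aft(df, ["peak_hours"], family="lognormal")
    assert mean_cohort_los(m, df) == pytest.approx(
        df["soc_los"].mean(), rel=0.03
    )


def test_median_monotone_in_covariate(rng):
    df = _lognormal_frame(rng, n=1000, beta=0.5)
    m = fit_aft(df, ["peak_hours"], family="lognormal")
    grid = pd.DataFrame({"peak_hours": np.linspace(0, 1, 11)})
    med = predict_los(m, grid, "median")
    assert (np.diff(med) > 0).all()
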