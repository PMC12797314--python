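"""Vital-rate regression fitting, selection, mixture and establishment."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import cactipm as c
from cactipm.vitalrates import ExtrapolationWarning, rate_records


def records_frame(size, response, individual=None, year=None, plot=None):
    n = len(size)
    return pd.DataFrame(
        {
            "size": size,
            "response": response,
            "individual": np.zeros(n, int) if individual is None else individual,
            "year": np.zeros(n, int) if year is None else year,
            "plot": np.zeros(n, int) if plot is None else plot,
        }
    )


# ---------------------------------------------------------------------------
# fit_vital_rate
# ---------------------------------------------------------------------------


def test_logistic_coefficients_recovered_within_three_se():
    rng = np.random.default_rng(101)
    n = 5000
    z = rng.uniform(0, 60, n)
    y = rng.binomial(1, expit(-1 + 0.08 * z))
    model = c.fit_vital_rate(records_frame(z, y), c.spec_for("s"), form="linear")
    sm = pytest.importorskip("statsmodels.api")
    X = np.column_stack([np.ones(n), z])
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    for est, true, se in zip(model.coef, (-1.0, 0.08), ref.bse):
        assert abs(est - true) < 3 * se


def test_all_ones_response_signals_separation():
    z = np.linspace(1, 60, 100)
    with pytest.raises(c.SeparationError, match="separation"):
        c.fit_vital_rate(records_frame(z, np.ones(100)), c.spec_for("s"), form="linear")


def test_noiseless_linear_growth_recovered_exactly():
    z = np.linspace(1, 60, 200)
    y = 1.5 + 0.9 * z
    model = c.fit_vital_rate(records_frame(z, y), c.spec_for("G_u"), form="linear")
    np.testing.assert_allclose(model.coef, [1.5, 0.9], atol=1e-8)
    assert model.resid_sd == pytest.approx(0.0, abs=1e-6)


def test_insufficient_observations_raise():
    z = np.linspace(1, 10, 5)
    with pytest.raises(c.FitError, match="observations"):
        c.fit_vital_rate(records_frame(z, np.r_[1, 0, 1, 0, 1]), c.spec_for("s"))


# ---------------------------------------------------------------------------
# stepwise_select
# ---------------------------------------------------------------------------


def _grouped_binary(rng, n=2500, year_sd=0.0, plot_sd=0.0, ind_sd=0.0):
    z = rng.uniform(0, 60, n)
    year = rng.integers(0, 20, n)
    plot = rng.integers(0, 3, n)
    ind = rng.integers(0, 400, n)
    eta = (
        -0.5
        + 0.05 * z
        + rng.normal(0, year_sd, 20)[year]
        + rng.normal(0, plot_sd, 3)[plot]
        + rng.normal(0, ind_sd, 400)[ind]
    )
    y = rng.binomial(1, expit(eta))
    return records_frame(z, y, individual=ind, year=year, plot=plot)


def test_stepwise_eliminates_spurious_random_effects():
    rng = np.random.default_rng(7)
    rec = _grouped_binary(rng)  # zero variance everywhere
    model = c.stepwise_select(rec, c.spec_for("s"))
    assert model.random_effects == () or set(model.random_effects) <= {"_spline"}


def test_stepwise_retains_strong_year_effect():
    rng = np.random.default_rng(8)
    rec = _grouped_binary(rng, n=4000, year_sd=1.2)
    model = c.stepwise_select(rec, c.spec_for("s"))
    assert "year" in model.random_effects
    assert len(model.year_modes) == 20
    # conditional modes are centred
    assert np.mean(list(model.year_modes.values())) == pytest.approx(0.0, abs=0.15)


def test_selected_model_has_minimal_aic_over_trail():
    rng = np.random.default_rng(9)
    rec = _grouped_binary(rng, n=2000, year_sd=0.5)
    model = c.stepwise_select(rec, c.spec_for("s"))
    assert model.aic <= min(aic for _, _, aic in model.selection_trail) + 1e-9


# ---------------------------------------------------------------------------
# offspring distribution, recruits and p_r
# ---------------------------------------------------------------------------


def test_mixture_recovers_low_mean_component():
    rng = np.random.default_rng(21)
    sizes = np.r_[rng.normal(10, 2, 1000), rng.normal(30, 4, 1000)]
    dist = c.fit_offspring_distribution(sizes)
    assert abs(dist.mean - 10.0) < 0.5
    assert dist.weight == pytest.approx(0.5, abs=0.1)


def test_mixture_on_two_point_sample():
    sizes = np.r_[np.full(30, 5.0), np.full(20, 40.0)]
    dist, mask = c.identify_recruits(sizes)
    assert dist.mean == pytest.approx(5.0, abs=1e-3)
    assert mask[:30].all() and not mask[30:].any()


def test_mixture_returns_smaller_mean_regardless_of_order():
    rng = np.random.default_rng(22)
    sizes = np.r_[rng.normal(28, 3, 400), rng.normal(9, 2, 400)]
    for arr in (sizes, sizes[::-1], np.sort(sizes)):
        dist = c.fit_offspring_distribution(arr)
        assert dist.mean < float(np.mean(arr))
        assert abs(dist.mean - 9.0) < 0.6


@pytest.mark.parametrize(
    "sizes, match",
    [(np.full(50, 8.0), "degenerate"), (np.arange(5, dtype=float), ">= 10")],
)
def test_mixture_input_errors(sizes, match):
    with pytest.raises(ValueError, match=match):
        c.fit_offspring_distribution(sizes)


@pytest.mark.parametrize(
    "recruits, structures, expected",
    [([5], [50], 0.1), ([0, 0], [30, 20], 0.0), ([2, 3], [20, 30], 0.1)],
)
def test_recruit_probability_pooled_ratio(recruits, structures, expected):
    assert c.estimate_recruit_probability(recruits, structures) == pytest.approx(expected)


def test_recruit_probability_errors():
    with pytest.raises(ValueError, match="zero reproductive structures"):
        c.estimate_recruit_probability([1, 2], [0, 0])
    with pytest.raises(ValueError, match="length"):
        c.estimate_recruit_probability([1], [10, 20])


# ---------------------------------------------------------------------------
# predict_rate
# ---------------------------------------------------------------------------


def _bare_model(rate, coef, support=(0.0, 60.0)):
    from cactipm.vitalrates import TABLE_STRUCTURE

    return c.VitalRateModel(
        rate=rate,
        link=TABLE_STRUCTURE[rate][0],
        family=TABLE_STRUCTURE[rate][1],
        form="linear",
        coef=np.asarray(coef, float),
        spline=None,
        spline_coef=None,
        sigma2={},
        year_modes={},
        resid_sd=1.0 if rate in ("G_u", "G_r") else None,
        aic=0.0,
        loglik=0.0,
        n_obs=100,
        support=support,
    )


def test_predict_zero_logit_gives_half():
    m = _bare_model("s", [0.0, 0.0])
    np.testing.assert_allclose(c.predict_rate(m, [5.0, 30.0, 55.0]), 0.5)


def test_predict_log_intercept_gives_constant():
    m = _bare_model("b", [np.log(2.0), 0.0])
    # flower counts use the zero-truncated mean: mu / (1 - exp(-mu)) at mu = 2
    expected = 2.0 / (1.0 - np.exp(-2.0))
    np.testing.assert_allclose(c.predict_rate(m, [10.0, 40.0]), expected, rtol=1e-12)


def test_predict_positive_slope_is_monotone():
    m = _bare_model("s", [-2.0, 0.05])
    out = c.predict_rate(m, np.linspace(1, 59, 40))
    assert np.all(np.diff(out) > 0)
    assert np.all((out > 0) & (out < 1))


def test_predict_flags_extrapolation():
    m = _bare_model("s", [0.0, 0.01], support=(5.0, 50.0))
    with pytest.warns(ExtrapolationWarning):
        c.predict_rate(m, [60.0])
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        c.predict_rate(m, [60.0], warn=False)


# ---------------------------------------------------------------------------
# response-curve recovery on generator output
# ---------------------------------------------------------------------------


def test_all_rates_recovered_from_generated_census(default_params):
    """Fitted response curves track the ground truth across the size range."""
    params = dataclasses.replace(default_params, n_individuals=200, n_years=31)
    census = c.apply_censoring_rule(c.generate_population(params, seed=11))
    rates = c.fit_all_rates(census, selection="direct")
    obs_sizes = census.loc[census["alive"] == 1, "size_mm"]
    lo, hi = np.quantile(obs_sizes, [0.05, 0.95])
    z = np.linspace(lo, hi, 60)
    truth = {
        "s": default_params.s, "p_b": default_params.p_b, "r": default_params.r,
        "u": default_params.u, "b": default_params.b,
        "G_u": default_params.g_u_mean, "G_r": default_params.g_r_mean,
    }
    for rate in ("s", "p_b", "r", "u"):
        fit = rates.models[rate].predict(z, warn=False)
        mae = float(np.mean(np.abs(fit - truth[rate](z))))
        assert mae <= 0.05, (rate, mae)
    for rate in ("b", "G_u", "G_r"):
        model = rates.models[rate]
        zz = np.clip(z, model.support[0], model.support[1])
        fit = model.predict(zz, warn=False)
        rel = float(np.mean(np.abs(fit - truth[rate](zz)) / np.abs(truth[rate](zz))))
        assert rel <= 0.10, (rate, rel)


def test_rate_records_condition_survival_on_not_contracting(small_census):
    rec_s = rate_records(small_census, "s")
    rec_r = rate_records(small_census, "r")
    # survival records exclude contractors, so they are fewer than r records
    assert len(rec_s) < len(rec_r)
    assert set(rec_s["response"].unique()) <= {0.0, 1.0}


def test_serialized_model_round_trips(small_census):
    rec = rate_records(small_census, "s")
    model = c.fit_vital_rate(rec, c.spec_for("s"), form="smooth", random_effects=("year",))
    clone = c.VitalRateModel.from_dict(model.to_dict())
    z = np.linspace(1, 60, 50)
    np.testing.assert_allclose(
        clone.predict(z, warn=False), model.predict(z, warn=False), rtol=1e-12
    )
    assert clone.year_modes == model.year_modes
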