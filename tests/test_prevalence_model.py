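"""Logit-scale prevalence fit, predictions and Lexis-direction derivative."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from previnc.prevalence_model import (
    age_group_midpoints,
    fit_prevalence,
    lexis_derivative,
    linear_predictor,
    natural_spline_basis,
    natural_spline_basis_deriv,
    predict_prevalence,
)

SEXES = ("male", "female")


def _table_from_surface(eta_fn, years=range(2009, 2018), age_los=range(0, 110, 5),
                        N=1_000_000):
    rows = []
    for year in years:
        for sex in SEXES:
            for lo in age_los:
                mid = lo + 2.5
                p = float(expit(eta_fn(year, mid, sex)))
                rows.append({"year": year, "sex": sex, "age_lo": lo,
                             "age_hi": lo + 4, "population": N, "cases": N * p,
                             "prevalence_percent": 100 * p})
    return pd.DataFrame(rows)


def test_age_group_midpoints_open_ended():
    mids = age_group_midpoints([20, 90], [24, np.nan])
    assert list(mids) == [22.5, 92.5]


def test_spline_basis_interpolates_and_differentiates():
    knots = np.arange(2.5, 108, 5.0)
    x = np.linspace(2.5, 107.5, 301)
    B = natural_spline_basis(x, knots)
    assert B.shape == (301, len(knots))
    # derivative columns match a central finite difference
    h = 1e-5
    num = (natural_spline_basis(x + h, knots) - natural_spline_basis(x - h, knots)) / (2 * h)
    assert np.max(np.abs(num - natural_spline_basis_deriv(x, knots))) < 1e-5


def test_exactly_representable_surface_reproduced():
    # logit-linear in age, linear in year: inside the model space
    eta = lambda t, a, s: -8.0 + 0.05 * a + 0.01 * (t - 2013) + (0.3 if s == "male" else 0.0)
    table = _table_from_surface(eta)
    fit = fit_prevalence(table)
    for sex in SEXES:
        ages = np.array([22.5, 47.5, 92.5])
        p, se = predict_prevalence(fit, 2013, ages, sex)
        assert np.max(np.abs(p - expit(eta(2013, ages, sex)))) < 1e-8
        # noise-free representable data: SE collapses with estimated dispersion
        assert np.all(se < 1e-6)


def test_fit_ignores_prevalence_percent_units():
    eta = lambda t, a, s: -6.0 + 0.03 * a
    t1 = _table_from_surface(eta)
    t2 = t1.copy()
    t2["prevalence_percent"] = t2["prevalence_percent"] / 100.0  # proportion units
    f1, f2 = fit_prevalence(t1), fit_prevalence(t2)
    for sex in SEXES:
        np.testing.assert_allclose(f1.by_sex[sex].coef, f2.by_sex[sex].coef)


def test_noise_free_s1_logit_residuals_small(noise_free_fits):
    fit, _ = noise_free_fits
    for sex in SEXES:
        assert np.max(np.abs(fit.by_sex[sex].resid_logit)) < 0.02


def test_duplicated_rows_shrink_se_by_sqrt2():
    eta = lambda t, a, s: -7.0 + 0.04 * a + 0.005 * (t - 2013)
    rng = np.random.default_rng(3)
    table = _table_from_surface(eta)
    table["cases"] = table["cases"] * (1 + 0.01 * rng.standard_normal(len(table)))
    doubled = pd.concat([table, table], ignore_index=True)
    f1 = fit_prevalence(table, dispersion="fixed")
    f2 = fit_prevalence(doubled, dispersion="fixed")
    ages = np.array([32.5, 62.5, 92.5])
    for sex in SEXES:
        np.testing.assert_allclose(f1.by_sex[sex].coef, f2.by_sex[sex].coef,
                                   rtol=1e-5, atol=1e-7)
        _, se1 = linear_predictor(f1, 2013, ages, sex)
        _, se2 = linear_predictor(f2, 2013, ages, sex)
        np.testing.assert_allclose(se2, se1 / np.sqrt(2.0), rtol=1e-5)


def test_zero_prevalence_stratum_continuity_corrected(caplog):
    eta = lambda t, a, s: -8.0 + 0.05 * a
    table = _table_from_surface(eta, years=(2009, 2017))
    table.loc[table.index[:2], "cases"] = 0.0
    with caplog.at_level(logging.WARNING):
        fit = fit_prevalence(table)
    assert "continuity-corrected" in caplog.text
    for sex in SEXES:
        assert np.all(np.isfinite(fit.by_sex[sex].coef))


def test_fit_preconditions():
    eta = lambda t, a, s: -8.0 + 0.05 * a
    with pytest.raises(ValueError, match="years"):
        fit_prevalence(_table_from_surface(eta, years=(2013,)))
    with pytest.raises(ValueError, match="age groups"):
        fit_prevalence(_table_from_surface(eta, age_los=(20, 25, 30)))


def test_prediction_window_enforced(noise_free_fits):
    fit, _ = noise_free_fits
    with pytest.raises(ValueError, match="window"):
        predict_prevalence(fit, 2013, [112.0], "male")


def test_se_eta_deterministic(noise_free_fits):
    fit, _ = noise_free_fits
    a = np.array([52.5, 72.5])
    _, se1 = linear_predictor(fit, 2013, a, "female")
    _, se2 = linear_predictor(fit, 2013, a, "female")
    np.testing.assert_array_equal(se1, se2)


def test_symmetric_eta_perturbation_second_order():
    # mean of expit(eta +/- s) returns to expit(eta) within the curvature bound
    eta, s = -2.0, 0.3
    avg = 0.5 * (expit(eta + s) + expit(eta - s))
    assert abs(avg - expit(eta)) <= 0.5 * s**2 * 0.0962 + 1e-12


def test_lexis_derivative_zero_for_flat_surface():
    table = _table_from_surface(lambda t, a, s: -3.0)
    fit = fit_prevalence(table)
    D = lexis_derivative(fit, 2013, np.array([42.5, 72.5]), "male")
    assert np.max(np.abs(D)) < 1e-10


def test_lexis_derivative_logistic_closed_form():
    beta = 0.05
    table = _table_from_surface(lambda t, a, s: -8.0 + beta * a)
    fit = fit_prevalence(table)
    ages = np.array([42.5, 62.5, 82.5])
    p = expit(-8.0 + beta * ages)
    exact = p * (1 - p) * beta
    D_an = lexis_derivative(fit, 2013, ages, "male", mode="analytic")
    np.testing.assert_allclose(D_an, exact, rtol=1e-6)
    # finite difference differs only by the O(h^2) third-derivative term
    D_fd = lexis_derivative(fit, 2013, ages, "male", mode="fd")
    h = 4.0
    third = np.array([
        (expit(-8 + beta * (a + h)) - expit(-8 + beta * (a - h))) / (2 * h)
        for a in ages])
    np.testing.assert_allclose(D_fd, third, rtol=1e-8)
    assert np.max(np.abs(D_fd - exact) / exact) < beta**2 * h**2  # loose O(h^2) bound


def test_fd_and_analytic_modes_agree_on_s1(noise_free_fits, grid):
    fit, _ = noise_free_fits
    for sex in SEXES:
        fd = lexis_derivative(fit, 2013, grid.support_ages, sex, mode="fd")
        an = lexis_derivative(fit, 2013, grid.support_ages, sex, mode="analytic")
        assert np.max(np.abs(fd - an)) < 1e-3


def test_lexis_derivative_tracks_truth(noise_free_fits, noise_free_bundle, grid):
    fit, _ = noise_free_fits
    truth = noise_free_bundle.truth
    ages = grid.support_ages[(grid.support_ages >= 30) & (grid.support_ages <= 85)]
    for sex in SEXES:
        D = lexis_derivative(fit, 2013, ages, sex)
        D_true = truth.lexis_derivative(ages, sex)
        assert np.max(np.abs(D / D_true - 1.0)) < 0.05


def test_derivative_stencil_span_check(noise_free_fits):
    fit, _ = noise_free_fits
    with pytest.raises(ValueError, match="stencil"):
        lexis_derivative(fit, 2013, np.array([52.5]), "male", half_step=6.0)
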