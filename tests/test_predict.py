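import numpy as np
import pytest

from dlnmx.basis import BasisSpec, eval_basis
from dlnmx.history import ExposureProfile
from dlnmx.predict import (
    cumulative_effect,
    predict_exposure_curve,
    predict_grid,
    predict_lag_curve,
    risk_trajectory,
)
from conftest import toy_fit


@pytest.fixture
def toy_dlnm(rng):
    """2x2 cross-basis on 3 lags with hand-set coefficients."""
    fx = BasisSpec(kind="bspline", degree=2, knots=(), boundary=(0, 10))
    wl = BasisSpec(kind="bspline", degree=1, knots=(), boundary=(0, 2), intercept=True)
    eta = np.array([0.3, -0.2, 0.1, 0.4])
    vcov = rng.normal(size=(4, 4))
    vcov = vcov @ vcov.T / 10 + np.eye(4) * 0.01
    return toy_fit(fx, wl, np.arange(3), eta, vcov)


def brute_contribution(fit, x, lag, x0=0.0):
    t = fit.term("x")
    fxv = eval_basis(np.array([x]), t.fx_spec).values[0]
    fx0 = eval_basis(np.array([x0]), t.fx_spec).values[0]
    clv = eval_basis(np.array([float(lag)]), t.wl_spec).values[0]
    total, idx = 0.0, 0
    for j in range(fxv.size):
        for k in range(clv.size):
            total += fit.eta[idx] * (fxv[j] - fx0[j]) * clv[k]
            idx += 1
    return total


def test_lag_curve_matches_brute_force(toy_dlnm):
    beta, se = predict_lag_curve(toy_dlnm, x_p=4.0)
    expected = [brute_contribution(toy_dlnm, 4.0, l) for l in range(3)]
    np.testing.assert_allclose(beta, expected, atol=1e-12)
    assert np.all(se >= 0)


def test_exposure_curve_matches_brute_force(toy_dlnm):
    xg = np.linspace(0, 10, 7)
    beta, se = predict_exposure_curve(toy_dlnm, lag_p=1, x_grid=xg)
    expected = [brute_contribution(toy_dlnm, x, 1) for x in xg]
    np.testing.assert_allclose(beta, expected, atol=1e-12)


def test_curve_at_reference_is_zero(toy_dlnm):
    beta, _ = predict_lag_curve(toy_dlnm, x_p=0.0, x0=0.0)
    np.testing.assert_allclose(beta, 0.0, atol=1e-14)
    beta, _ = predict_lag_curve(toy_dlnm, x_p=3.0, x0=3.0)
    np.testing.assert_allclose(beta, 0.0, atol=1e-12)


def test_dlm_constant_lag_curve_is_flat():
    """Linear f, constant w: unit exposure contributes eta_1 at every lag."""
    fit = toy_fit(
        BasisSpec(kind="linear", boundary=(0, 10)),
        BasisSpec(kind="constant"),
        np.arange(2, 41),
        np.array([0.25]),
    )
    beta, _ = predict_lag_curve(fit, x_p=1.0)
    np.testing.assert_allclose(beta, 0.25, atol=1e-14)


def test_grid_slices_match_curves(toy_dlnm):
    xg = np.linspace(0, 10, 5)
    grid = predict_grid(toy_dlnm, xg)
    for i, x in enumerate(xg):
        b, s = predict_lag_curve(toy_dlnm, x)
        np.testing.assert_allclose(grid.betahat[i], b, atol=1e-12)
        np.testing.assert_allclose(grid.se[i], s, atol=1e-12)
    b, s = predict_exposure_curve(toy_dlnm, lag_p=2, x_grid=xg)
    np.testing.assert_allclose(grid.betahat[:, 2], b, atol=1e-12)


def test_zero_coefficients_zero_surface(toy_dlnm):
    toy_dlnm.eta = np.zeros_like(toy_dlnm.eta)
    grid = predict_grid(toy_dlnm, np.linspace(0, 10, 4))
    np.testing.assert_array_equal(grid.betahat, 0.0)


def test_cumulative_effect_closed_form():
    """Constant-lag DLM with HR 1.031 per 100 units: 160 units -> HR 1.031^1.6."""
    fit = toy_fit(
        BasisSpec(kind="linear", boundary=(0, 250)),
        BasisSpec(kind="constant"),
        np.arange(2, 41),
        np.array([np.log(1.031) / 100.0]),
    )
    lags = np.arange(2, 41)
    q = np.where(lags <= 9, 20.0, 0.0)
    beta, se = cumulative_effect(fit, q)
    assert np.exp(beta) == pytest.approx(1.031**1.6, abs=1e-12)
    assert np.exp(beta) == pytest.approx(1.05, abs=0.005)


def test_cumulative_reference_history_is_zero(toy_dlnm):
    beta, se = cumulative_effect(toy_dlnm, np.zeros(3), x0=0.0)
    assert beta == 0.0
    assert se >= 0.0


def test_cumulative_equals_sum_of_lag_contributions(toy_dlnm, rng):
    q = rng.uniform(0, 10, size=3)
    beta, _ = cumulative_effect(toy_dlnm, q)
    total = sum(brute_contribution(toy_dlnm, q[l], l) for l in range(3))
    assert beta == pytest.approx(total, abs=1e-10)


def test_cumulative_additivity_for_linear_fx(rng):
    fit = toy_fit(
        BasisSpec(kind="linear", boundary=(0, 100)),
        BasisSpec(kind="bspline", degree=2, knots=(), boundary=(0, 4), intercept=True),
        np.arange(5),
        rng.normal(size=3),
    )
    q1, q2 = rng.uniform(0, 20, size=5), rng.uniform(0, 20, size=5)
    b1, _ = cumulative_effect(fit, q1)
    b2, _ = cumulative_effect(fit, q2)
    b12, _ = cumulative_effect(fit, q1 + q2)
    assert b12 == pytest.approx(b1 + b2, abs=1e-10)


def test_cumulative_length_mismatch(toy_dlnm):
    with pytest.raises(ValueError, match="length"):
        cumulative_effect(toy_dlnm, np.zeros(5))


def test_out_of_range_prediction_raises(toy_dlnm):
    with pytest.raises(ValueError, match="outside"):
        predict_lag_curve(toy_dlnm, x_p=11.0)


def test_delta_method_matches_parametric_bootstrap(toy_dlnm, rng):
    """SEs equal the empirical SD of predictions under eta ~ N(etahat, V)."""
    q = rng.uniform(0, 10, size=3)
    beta, se = cumulative_effect(toy_dlnm, q)
    draws = rng.multivariate_normal(toy_dlnm.eta, toy_dlnm.vcov, size=40000)
    from dlnmx.predict import cumulative_b

    b = cumulative_b(toy_dlnm.term("x"), q)
    sims = draws @ b
    assert np.std(sims) == pytest.approx(se, rel=0.03)


def test_trajectory_zero_profile():
    fit = toy_fit(
        BasisSpec(kind="linear", boundary=(0, 50)),
        BasisSpec(kind="constant"),
        np.arange(0, 41),
        np.array([0.01]),
    )
    prof = ExposureProfile("z", 1, np.zeros(80))
    traj = risk_trajectory(fit, prof, np.arange(1, 70))
    np.testing.assert_array_equal(traj["loghr"].to_numpy(), 0.0)


def test_trajectory_washout_after_lag_window(pulse_profile):
    """Once the last exposure leaves the lag window the cumulative HR returns to 1."""
    fit = toy_fit(
        BasisSpec(kind="linear", boundary=(0, 50)),
        BasisSpec(kind="bspline", degree=2, knots=(13.3,), boundary=(0, 40), right_constrained=True),
        np.arange(0, 41),
        np.array([0.05, 0.02]),
    )
    traj = risk_trajectory(fit, pulse_profile, np.array([10, 30, 56, 57, 60]))
    assert traj.loc[0, "loghr"] != 0.0
    # exposure ends in year 15; from year 15 + 40 + 1 = 56 onwards history is empty
    np.testing.assert_allclose(traj.loc[2:, "loghr"], 0.0, atol=1e-12)
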