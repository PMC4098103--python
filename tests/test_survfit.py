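import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from dlnmx.basis import BasisSpec
from dlnmx.history import ExposureProfile
from dlnmx.survfit import (
    CountingProcessData,
    aic_bic,
    expand_cohort,
    fit_cox,
    select_model,
)
from conftest import toy_fit


def simple_data(times, events, X):
    """One row per subject, entry at 0."""
    times = np.asarray(times, dtype=float)
    return CountingProcessData(
        subject=np.arange(times.size),
        start=np.zeros(times.size),
        stop=times,
        event=np.asarray(events),
        X=np.asarray(X, dtype=float),
        column_names=[f"x{i}" for i in range(np.asarray(X).shape[1])],
    )


def test_null_model_loglik_closed_form():
    """With no covariates and no ties, logL = -sum log(risk-set size)."""
    times = [1.0, 2.0, 3.0, 4.0]
    events = [1, 0, 1, 0]
    data = simple_data(times, events, np.empty((4, 0)))
    fit = fit_cox(data)
    # risk sets at t=1 (4 subjects) and t=3 (2 subjects)
    assert fit.loglik == pytest.approx(-(np.log(4) + np.log(2)), abs=1e-12)
    assert fit.df_total == 0


def test_single_covariate_matches_brute_force_oracle():
    """Newton solution equals direct 1-D maximization of the partial likelihood."""
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([1, 1, 0, 1, 0])
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])

    def negll(beta):
        ll = 0.0
        for t, e in zip(times, events):
            if not e:
                continue
            at_risk = times >= t
            i = np.flatnonzero(times == t)[0]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
        return -ll

    res = minimize_scalar(negll, bounds=(-5, 5), method="bounded")
    fit = fit_cox(simple_data(times, events, x[:, None]))
    assert fit.eta[0] == pytest.approx(res.x, abs=1e-5)
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-9)


def test_agreement_with_lifelines_time_varying(rng):
    """Efron partial likelihood matches lifelines' CoxTimeVaryingFitter with ties."""
    lifelines = pytest.importorskip("lifelines")
    rows = []
    for i in range(50):
        t_end = int(rng.integers(2, 8))
        ev = rng.random() < 0.6
        for s in range(t_end):
            rows.append((i, s, s + 1, int(ev and s == t_end - 1), rng.normal(), rng.normal()))
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "x1", "x2"])
    data = CountingProcessData(
        subject=df["id"].to_numpy(),
        start=df["start"].to_numpy(),
        stop=df["stop"].to_numpy(),
        event=df["event"].to_numpy(),
        X=df[["x1", "x2"]].to_numpy(),
        column_names=["x1", "x2"],
    )
    fit = fit_cox(data)
    ctv = lifelines.CoxTimeVaryingFitter()
    ctv.fit(df, id_col="id", start_col="start", stop_col="stop", event_col="event")
    np.testing.assert_allclose(fit.eta, ctv.params_.values, atol=1e-6)
    np.testing.assert_allclose(fit.loglik, ctv.log_likelihood_, atol=1e-6)
    np.testing.assert_allclose(np.sqrt(np.diag(fit.vcov)), ctv.standard_errors_.values, atol=1e-5)


def test_efron_equals_breslow_without_ties(rng):
    times = np.sort(rng.uniform(0, 10, size=30))
    events = rng.random(30) < 0.5
    events[0] = True
    X = rng.normal(size=(30, 2))
    d = simple_data(times, events, X)
    fe = fit_cox(d, ties="efron")
    fb = fit_cox(d, ties="breslow")
    np.testing.assert_allclose(fe.eta, fb.eta, atol=1e-10)
    np.testing.assert_allclose(fe.loglik, fb.loglik, atol=1e-10)


def test_row_order_invariance(rng):
    times = rng.uniform(0, 10, size=40)
    events = rng.random(40) < 0.5
    events[np.argmax(times)] = True
    X = rng.normal(size=(40, 3))
    d1 = simple_data(times, events, X)
    perm = rng.permutation(40)
    d2 = CountingProcessData(
        subject=perm,
        start=np.zeros(40),
        stop=times[perm],
        event=events[perm],
        X=X[perm],
        column_names=d1.column_names,
    )
    np.testing.assert_allclose(fit_cox(d1).eta, fit_cox(d2).eta, atol=1e-8)


def test_rank_deficient_design_raises(rng):
    times = np.sort(rng.uniform(0, 10, size=20))
    events = np.ones(20, dtype=bool)
    x = rng.normal(size=20)
    X = np.column_stack([x, 2.0 * x])
    with pytest.raises(np.linalg.LinAlgError, match="rank deficient|singular"):
        fit_cox(simple_data(times, events, X))


@pytest.mark.parametrize(
    "loglik, k, d, aic_expected, bic_expected",
    [
        (-1112.0, 6, 258, 2236.0, 2257.3),
        (-1111.45, 8, 258, 2238.9, 2267.3),
    ],
)
def test_aic_bic_reproduces_criterion_arithmetic(loglik, k, d, aic_expected, bic_expected):
    fit = toy_fit(
        BasisSpec(kind="linear"), BasisSpec(kind="constant"), np.arange(2, 41), np.zeros(1)
    )
    fit.loglik, fit.df_total, fit.n_events = loglik, k, d
    aic, bic = aic_bic(fit)
    assert aic == pytest.approx(aic_expected, abs=0.05)
    assert bic == pytest.approx(bic_expected, abs=0.05)
    # identity BIC - AIC = (log d - 2) k
    assert bic - aic == pytest.approx((np.log(d) - 2) * k, abs=1e-10)


def test_aic_bic_edge_cases():
    fit = toy_fit(BasisSpec(kind="linear"), BasisSpec(kind="constant"), np.arange(3), np.zeros(1))
    fit.loglik, fit.df_total, fit.n_events = -10.0, 0, 5
    assert aic_bic(fit) == (20.0, 20.0)
    fit.n_events = 0
    with pytest.raises(ValueError):
        aic_bic(fit)


# ---------------------------------------------------------------------------
# Cohort expansion


def small_cohort():
    subjects = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c"],
            "entry_age": [30, 30, 30],
            "exit_age": [50, 45, 40],
            "event": [1, 0, 0],
            "entry_year": [1950, 1951, 1952],
        }
    )
    rng = np.random.default_rng(5)
    profiles = [
        ExposureProfile(s, 20, rng.uniform(0, 100, size=40)) for s in ["a", "b", "c"]
    ]
    smoking = [ExposureProfile(s, 20, rng.uniform(0, 3, size=30), extend="hold") for s in ["a", "b", "c"]]
    return subjects, profiles, smoking


def test_expand_cohort_risk_sets():
    subjects, profiles, smoking = small_cohort()
    exp = expand_cohort(subjects, profiles, smoking)
    # single event at age 50: only subject 'a' still at risk there
    assert exp.n_rows == 1
    assert list(exp.rows["subject"]) == ["a"]
    assert exp.rows["event"].all()


def test_expand_cohort_censored_before_events_contribute_nothing():
    subjects, profiles, smoking = small_cohort()
    subjects.loc[0, "exit_age"] = 44  # event at 44; c (censored at 40) not at risk
    exp = expand_cohort(subjects, profiles, smoking)
    assert set(exp.rows["subject"]) == {"a", "b"}


def test_expand_cohort_shift_property():
    """Consecutive risk-set ages obey the history shift identity."""
    subjects, profiles, smoking = small_cohort()
    subjects["event"] = [1, 1, 0]
    subjects.loc[1, "exit_age"] = 49
    exp = expand_cohort(subjects, profiles, smoking)
    ra = exp.rows.reset_index(drop=True)
    q = exp.Q_radon.Q
    i50 = ra.index[(ra["subject"] == "a") & (ra["age"] == 50)][0]
    i49 = ra.index[(ra["subject"] == "a") & (ra["age"] == 49)][0]
    np.testing.assert_array_equal(q[i50, 1:], q[i49, :-1])


def test_select_model_returns_argmin_per_criterion():
    subjects, profiles, _ = small_cohort()
    subjects["event"] = [1, 1, 1]
    subjects["exit_age"] = [50, 48, 46]
    exp = expand_cohort(subjects, profiles, None, calendar=None)
    cands = [
        (BasisSpec(kind="linear"), BasisSpec(kind="constant")),
        (BasisSpec(kind="linear"), BasisSpec(kind="step", knots=(20.0,), intercept=True)),
    ]
    best_aic, best_bic, table = select_model(cands, exp)
    ok = table[table["AIC"].notna()]
    assert best_aic.df_total == table.loc[ok["AIC"].idxmin(), "df_total"]
    assert best_bic.df_total == table.loc[ok["BIC"].idxmin(), "df_total"]


def test_select_model_single_candidate():
    subjects, profiles, _ = small_cohort()
    subjects["event"] = [0, 1, 0]  # event at 45 with subjects a, b at risk
    exp = expand_cohort(subjects, profiles, None, calendar=None)
    cands = [(BasisSpec(kind="linear"), BasisSpec(kind="constant"))]
    best_aic, best_bic, table = select_model(cands, exp)
    assert best_aic is best_bic
    assert len(table) == 1
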