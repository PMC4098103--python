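"""Simulation study: candidate grid, per-replicate fits, performance metrics.

Each replicate cohort is fitted with a 36-model grid of cross-bases (6
exposure bases x 6 lag bases), the best models under AIC and BIC are
retained, and performance is summarized on an overall cumulative effect
``beta_c`` evaluated for a random subject at a random time late in
follow-up:

* relative bias      mean[(betahat_i - beta_i) / beta_i]
* coverage           mean[ I(|betahat_i - beta_i| <= z * SE_i) ]
* relative RMSE      sqrt(mean[((betahat_i - beta_i) / beta_i)^2])

plus the empirical rejection rates of the hypotheses of a linear
exposure-response (``H0: f(x) = x``) and a constant lag structure
(``H0: w(l) = c``) -- the share of replicates whose selected model carries a
non-linear or non-constant term -- and the average selected df per
dimension.

The heavy lifting per replicate (36 design matrices over every risk set) is
done on a per-subject-per-year grid by a sliding-window contraction, which
is algebraically identical to :func:`dlnmx.crossbasis.build_crossbasis`
applied to the stacked histories (tested against it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .basis import BasisSpec, eval_basis
from .history import exposure_history
from .predict import cumulative_b
from .simulate import L_SIM, T_MAX, X_MAX, Scenario, SimulatedCohort, scenario, simulate_dataset, true_cumulative
from .survfit import ConvergenceError, CrossBasisTerm, FittedDLNM, aic_bic, fit_stacked

__all__ = [
    "candidate_grid",
    "fit_candidates",
    "evaluate_replicate",
    "aggregate",
    "run_study",
    "StudyResult",
]

EXPOSURE_KNOT_POSITIONS = (3.3, 5.0, 6.7)
LAG_KNOT_POSITIONS = (13.3, 20.0, 26.7)


def candidate_grid(
    exposure_knots: tuple[float, ...] = EXPOSURE_KNOT_POSITIONS,
    lag_knots: tuple[float, ...] = LAG_KNOT_POSITIONS,
    x_boundary: tuple[float, float] = (0.0, X_MAX),
    lag_boundary: tuple[float, float] = (0.0, float(L_SIM)),
) -> list[tuple[BasisSpec, BasisSpec]]:
    """The 36-model grid: 6 exposure bases x 6 lag bases.

    Exposure: linear, or quadratic B-splines without intercept with 0 knots,
    1 knot at each candidate position, or 2 knots (first and last position).
    Lag: constant, or quadratic B-splines *with* intercept, same knot
    pattern.  Cross-basis df ranges from 1x1 = 1 to 4x5 = 20.
    """
    def bs(knots, boundary, intercept):
        return BasisSpec(kind="bspline", degree=2, knots=knots, boundary=boundary, intercept=intercept)

    fx_list = [BasisSpec(kind="linear", boundary=x_boundary), bs((), x_boundary, False)]
    fx_list += [bs((k,), x_boundary, False) for k in exposure_knots]
    fx_list += [bs((exposure_knots[0], exposure_knots[-1]), x_boundary, False)]

    wl_list = [BasisSpec(kind="constant", boundary=lag_boundary), bs((), lag_boundary, True)]
    wl_list += [bs((k,), lag_boundary, True) for k in lag_knots]
    wl_list += [bs((lag_knots[0], lag_knots[-1]), lag_boundary, True)]

    return [(fx, wl) for fx in fx_list for wl in wl_list]


def _is_nonlinear(fx: BasisSpec) -> bool:
    return fx.kind != "linear"


def _is_nonconstant(wl: BasisSpec) -> bool:
    return wl.kind != "constant"


# ---------------------------------------------------------------------------
# Fast per-replicate design construction


def _risk_layout(cohort: SimulatedCohort):
    """Risk-set stacked (subject, year) indices for every event time.

    Subjects sorted by time descending; the risk set of the j-th ascending
    event time is the first ``n_j`` subjects of that ordering.  Returns
    (subject index per row, year index per row, group id, event flag).
    """
    times = cohort.time
    ev_times = np.sort(times[cohort.status == 1])
    order = np.argsort(-times, kind="stable")
    sorted_times = times[order]
    sub_rows, yr_rows, grp, evf = [], [], [], []
    for j, t in enumerate(ev_times):
        n_at_risk = int(np.searchsorted(-sorted_times, -t, side="right"))
        members = order[:n_at_risk]
        sub_rows.append(members)
        yr = int(np.clip(np.floor(t), 1, T_MAX))
        yr_rows.append(np.full(n_at_risk, yr - 1))
        grp.append(np.full(n_at_risk, j))
        evf.append(times[members] == t)
    return (
        np.concatenate(sub_rows),
        np.concatenate(yr_rows),
        np.concatenate(grp),
        np.concatenate(evf),
    )


def _design_grids(cohort: SimulatedCohort, grid) -> dict[int, np.ndarray]:
    """Per-candidate (ns, 100, df) cross-basis values on the full time grid."""
    X = np.stack([p.intensity for p in cohort.profiles])  # (ns, 100)
    fx_specs, wl_specs = [], []
    for fx, wl in grid:
        if fx not in fx_specs:
            fx_specs.append(fx)
        if wl not in wl_specs:
            wl_specs.append(wl)
    lag = np.arange(L_SIM + 1, dtype=float)
    C = {wl: eval_basis(lag, wl).values for wl in wl_specs}
    out: dict[int, np.ndarray] = {}
    ns = X.shape[0]
    for fx in fx_specs:
        F = eval_basis(X.ravel(), fx).values.reshape(ns, T_MAX, -1)  # (ns, 100, vx)
        Fp = np.pad(F, ((0, 0), (L_SIM, 0), (0, 0)))
        # window axis m = 0..L: F[t - L + m]; lag l = L - m
        win = np.lib.stride_tricks.sliding_window_view(Fp, L_SIM + 1, axis=1)  # (ns,100,vx,L+1)
        for wl in wl_specs:
            Crev = np.ascontiguousarray(C[wl][::-1])  # (L+1, vl)
            V = win @ Crev  # (ns, 100, vx, vl)
            Wflat = V.reshape(ns, T_MAX, -1)
            for idx, (f2, w2) in enumerate(grid):
                if f2 == fx and w2 == wl:
                    out[idx] = Wflat
    return out


def fit_candidates(
    cohort: SimulatedCohort,
    grid: list[tuple[BasisSpec, BasisSpec]] | None = None,
    ties: str = "efron",
) -> pd.DataFrame:
    """Fit every candidate cross-basis to one replicate.

    Returns a table with one row per candidate (fit object, AIC, BIC, df);
    failed candidates carry NaN criteria and the error message.
    """
    if grid is None:
        grid = candidate_grid()
    sub, yr, group, evf = _risk_layout(cohort)
    designs = _design_grids(cohort, grid)
    records = []
    for i, (fx, wl) in enumerate(grid):
        Xi = designs[i][sub, yr]
        terms = {"x": CrossBasisTerm("x", fx, wl, np.arange(L_SIM + 1), 0, Xi.shape[1])}
        try:
            fit = fit_stacked(Xi, group, evf, ties=ties, terms=terms)
            aic, bic = aic_bic(fit)
            err = ""
        except (np.linalg.LinAlgError, ConvergenceError, ValueError) as e:
            fit, aic, bic, err = None, np.nan, np.nan, str(e)
        records.append(
            {
                "model": i,
                "fx": fx,
                "wl": wl,
                "df_fx": fx.dimension,
                "df_wl": wl.dimension,
                "df": fx.dimension * wl.dimension,
                "AIC": aic,
                "BIC": bic,
                "fit": fit,
                "error": err,
            }
        )
    return pd.DataFrame(records)


def _select(table: pd.DataFrame, criterion: str) -> pd.Series:
    ok = table[table[criterion].notna()]
    if ok.empty:
        raise RuntimeError("all candidate models failed")
    return ok.sort_values([criterion, "df", "model"], kind="stable").iloc[0]


def evaluate_replicate(
    cohort: SimulatedCohort,
    scen: Scenario,
    rng: np.random.Generator,
    grid: list[tuple[BasisSpec, BasisSpec]] | None = None,
) -> dict:
    """Fit the grid, select by AIC/BIC, and score one random cumulative effect.

    The effect summary is evaluated for a random subject at a random integer
    time between 41 and 100, so the whole span of simulated exposure
    histories contributes to the performance metrics.
    """
    table = fit_candidates(cohort, grid)
    subj = int(rng.integers(0, cohort.ns))
    t_eval = int(rng.integers(41, T_MAX + 1))
    q_h = exposure_history(cohort.profiles[subj], t_eval, 0, L_SIM)
    beta_true = true_cumulative(q_h, scen)
    rec = {"subject": subj, "t_eval": t_eval, "beta_true": beta_true}
    for crit in ("AIC", "BIC"):
        row = _select(table, crit)
        fit: FittedDLNM = row["fit"]
        b = cumulative_b(fit.term("x"), q_h, x0=0.0)
        beta_hat = float(b @ fit.eta)
        se = float(np.sqrt(max(b @ fit.vcov @ b, 0.0)))
        rec.update(
            {
                f"beta_{crit}": beta_hat,
                f"se_{crit}": se,
                f"df_fx_{crit}": int(row["df_fx"]),
                f"df_wl_{crit}": int(row["df_wl"]),
                f"nonlin_{crit}": _is_nonlinear(row["fx"]),
                f"nonconst_{crit}": _is_nonconstant(row["wl"]),
            }
        )
    rec["n_events"] = cohort.n_events
    rec["n_failed"] = int(table["AIC"].isna().sum())
    return rec


@dataclass
class StudyResult:
    """Per-replicate records plus the aggregated performance table."""

    scenario_name: str
    ns: int
    m: int
    records: pd.DataFrame
    summary: pd.DataFrame


def aggregate(records: pd.DataFrame, alpha: float = 0.05, two_sided: bool = True) -> pd.DataFrame:
    """Aggregate per-replicate records into bias/coverage/RMSE and rates.

    Replicates with ``|beta_true|`` below 1e-8 are excluded from the
    *relative* metrics (they would divide by zero) but still count toward
    coverage and rejection rates.
    """
    z = norm.ppf(1 - alpha / 2) if two_sided else norm.ppf(1 - alpha)
    rows = []
    for crit in ("AIC", "BIC"):
        bt = records["beta_true"].to_numpy()
        bh = records[f"beta_{crit}"].to_numpy()
        se = records[f"se_{crit}"].to_numpy()
        ok = np.abs(bt) > 1e-8
        rel = (bh[ok] - bt[ok]) / bt[ok]
        rows.append(
            {
                "criterion": crit,
                "rel_bias": float(rel.mean()) if ok.any() else np.nan,
                "coverage": float(np.mean(np.abs(bh - bt) <= z * se)),
                "rel_rmse": float(np.sqrt(np.mean(rel**2))) if ok.any() else np.nan,
                "reject_linear": float(records[f"nonlin_{crit}"].mean()),
                "reject_constant": float(records[f"nonconst_{crit}"].mean()),
                "avg_df_fx": float(records[f"df_fx_{crit}"].mean()),
                "avg_df_wl": float(records[f"df_wl_{crit}"].mean()),
                "n_rel_excluded": int((~ok).sum()),
                "m": len(records),
            }
        )
    return pd.DataFrame(rows).set_index("criterion")


def run_study(
    scenario_name: str,
    ns: int = 400,
    m: int = 50,
    seed: int = 0,
    grid: list[tuple[BasisSpec, BasisSpec]] | None = None,
    magnitude: float | None = None,
) -> StudyResult:
    """Run ``m`` replicates of one scenario and aggregate performance.

    One independent random substream is spawned per replicate, so results
    are reproducible for a given ``(seed, m)`` and replicates are
    exchangeable.
    """
    kwargs = {} if magnitude is None else {"magnitude": magnitude}
    scen = scenario(scenario_name, **kwargs)
    if grid is None:
        grid = candidate_grid()
    streams = np.random.SeedSequence(seed).spawn(m)
    records = []
    for r in range(m):
        rng = np.random.default_rng(streams[r])
        cohort = simulate_dataset(scen, ns, rng)
        rec = evaluate_replicate(cohort, scen, rng, grid)
        rec["replicate"] = r
        records.append(rec)
    df = pd.DataFrame(records)
    return StudyResult(scenario_name=scenario_name, ns=ns, m=m, records=df, summary=aggregate(df))
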