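"""Cox proportional-hazards fitting for DLNM cross-basis terms.

Cohort data are expanded to counting-process form (one row per subject per
risk-set time at which the subject is at risk, with the time-varying
cross-basis covariates evaluated at that time), the partial likelihood is
maximized by Newton-Raphson with the Efron correction for tied event times,
and fits are ranked by AIC/BIC adapted to survival analysis:

    AIC = -2 logL + 2 k          BIC = -2 logL + log(d) k

where ``k`` counts *all* estimated regression coefficients and ``d`` is the
number of uncensored events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .basis import BasisSpec
from .crossbasis import build_crossbasis, crossbasis_df
from .history import ExposureProfile, HistoryMatrix, build_history_matrix

__all__ = [
    "CountingProcessData",
    "FittedDLNM",
    "CrossBasisTerm",
    "CohortExpansion",
    "expand_cohort",
    "fit_cox",
    "aic_bic",
    "select_model",
    "ConvergenceError",
]

SMOKING_FX_DEFAULT = BasisSpec(kind="nspline", knots=(2.5,), intercept=False)
SMOKING_WL_DEFAULT = BasisSpec(kind="step", knots=(20.0,), intercept=True)


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed; carries the iteration trace of log-likelihoods."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message}; log-likelihood trace: {trace}")
        self.trace = trace


@dataclass
class CrossBasisTerm:
    """Metadata tying a block of coefficients to its cross-basis definition."""

    name: str
    fx_spec: BasisSpec
    wl_spec: BasisSpec
    lag_grid: np.ndarray
    start: int
    stop: int

    @property
    def sl(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class CountingProcessData:
    """Counting-process rows: (subject, start, stop] intervals with covariates.

    ``X[i]`` holds the covariate values of ``subject[i]`` over the interval
    ``(start[i], stop[i]]``; ``event[i]`` marks the interval ending in the
    subject's event.  Terms map coefficient blocks to cross-basis metadata.
    """

    subject: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray
    X: np.ndarray
    column_names: list[str] = field(default_factory=list)
    terms: dict[str, CrossBasisTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.stop.size:
            raise ValueError(f"X has shape {self.X.shape}, expected ({self.stop.size}, k)")
        if np.any(self.start >= self.stop):
            raise ValueError("each interval must satisfy start < stop")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class FittedDLNM:
    """A fitted Cox model with cross-basis terms.

    ``eta``/``vcov`` are the coefficient vector and its model-based
    covariance (inverse observed information); ``loglik`` the maximized
    partial log-likelihood; ``terms`` the cross-basis bookkeeping used by the
    prediction module.
    """

    eta: np.ndarray
    vcov: np.ndarray
    loglik: float
    df_total: int
    n_events: int
    terms: dict[str, CrossBasisTerm] = field(default_factory=dict)
    column_names: list[str] = field(default_factory=list)
    n_iter: int = 0

    def term(self, name: str | None = None) -> CrossBasisTerm:
        if not self.terms:
            raise ValueError("model has no cross-basis terms")
        if name is None:
            return next(iter(self.terms.values()))
        return self.terms[name]

    def to_dict(self) -> dict:
        return {
            "eta": self.eta.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "df_total": self.df_total,
            "n_events": self.n_events,
            "column_names": list(self.column_names),
            "terms": {
                n: {
                    "fx_spec": t.fx_spec.to_dict(),
                    "wl_spec": t.wl_spec.to_dict(),
                    "lag_grid": np.asarray(t.lag_grid).tolist(),
                    "start": t.start,
                    "stop": t.stop,
                }
                for n, t in self.terms.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDLNM":
        terms = {
            n: CrossBasisTerm(
                name=n,
                fx_spec=BasisSpec.from_dict(t["fx_spec"]),
                wl_spec=BasisSpec.from_dict(t["wl_spec"]),
                lag_grid=np.asarray(t["lag_grid"]),
                start=t["start"],
                stop=t["stop"],
            )
            for n, t in d.get("terms", {}).items()
        }
        return cls(
            eta=np.asarray(d["eta"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float),
            loglik=float(d["loglik"]),
            df_total=int(d["df_total"]),
            n_events=int(d["n_events"]),
            terms=terms,
            column_names=list(d.get("column_names", [])),
        )


# ---------------------------------------------------------------------------
# Cohort expansion


class CohortExpansion:
    """Risk-set expansion of a cohort, radon cross-basis left parameterizable.

    Holds the exposure histories at every (subject, risk-set age) pair plus
    the fixed confounder columns (smoking cross-basis, linear calendar time);
    :meth:`design` assembles the full counting-process data for one choice of
    the radon cross-basis.
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        start: np.ndarray,
        Q_radon: HistoryMatrix,
        Q_smoking: HistoryMatrix | None,
        calendar: np.ndarray | None,
        smoking_fx: BasisSpec = SMOKING_FX_DEFAULT,
        smoking_wl: BasisSpec = SMOKING_WL_DEFAULT,
    ):
        self.rows = rows  # columns: subject, age, event
        self.start = start
        self.Q_radon = Q_radon
        self.Q_smoking = Q_smoking
        self.calendar = calendar
        self._confounders: list[tuple[str, np.ndarray]] = []
        self._smoking_term: tuple[BasisSpec, BasisSpec, np.ndarray] | None = None
        if Q_smoking is not None:
            cb = build_crossbasis(Q_smoking, smoking_fx, smoking_wl)
            self._smoking_term = (cb.fx_spec, cb.wl_spec, cb.W)
        if calendar is not None:
            # center calendar time for numerical conditioning; the Cox partial
            # likelihood is invariant to covariate shifts
            self._confounders.append(("calendar_year", np.asarray(calendar, float) - np.mean(calendar)))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def design(self, fx_spec: BasisSpec, wl_spec: BasisSpec, name: str = "radon") -> CountingProcessData:
        cb = build_crossbasis(self.Q_radon, fx_spec, wl_spec)
        blocks = [cb.W]
        names = cb.column_names(prefix=name)
        terms = {name: CrossBasisTerm(name, cb.fx_spec, cb.wl_spec, cb.lag_grid, 0, cb.df)}
        pos = cb.df
        if self._smoking_term is not None:
            sfx, swl, Wz = self._smoking_term
            blocks.append(Wz)
            names += [f"smoking_{j}_{k}" for j in range(sfx.dimension) for k in range(swl.dimension)]
            terms["smoking"] = CrossBasisTerm("smoking", sfx, swl, self.Q_smoking.lag_grid, pos, pos + Wz.shape[1])
            pos += Wz.shape[1]
        for cname, col in self._confounders:
            blocks.append(col[:, None])
            names.append(cname)
            pos += 1
        return CountingProcessData(
            subject=self.rows["subject"].to_numpy(),
            start=self.start,
            stop=self.rows["age"].to_numpy(dtype=float),
            event=self.rows["event"].to_numpy(dtype=bool),
            X=np.hstack(blocks),
            column_names=names,
            terms=terms,
        )


def expand_cohort(
    subjects: pd.DataFrame,
    radon_profiles: list[ExposureProfile],
    smoking_profiles: list[ExposureProfile] | None = None,
    lag_window: tuple[int, int] = (2, 40),
    smoking_lag_window: tuple[int, int] = (2, 40),
    smoking_fx: BasisSpec = SMOKING_FX_DEFAULT,
    smoking_wl: BasisSpec = SMOKING_WL_DEFAULT,
    calendar: str | None = "entry_year",
) -> CohortExpansion:
    """Expand a cohort to one row per subject per risk-set age.

    ``subjects`` needs columns ``subject_id, entry_age, exit_age, event`` and
    (if ``calendar`` is set) ``entry_year``.  Age is the time axis with
    delayed entry at the cohort entry age: a subject is at risk at age ``a``
    when ``entry_age < a <= exit_age``.  Calendar time enters as a linear
    term evaluated at the risk-set age.
    """
    req = {"subject_id", "entry_age", "exit_age", "event"}
    missing = req - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table is missing columns {sorted(missing)}")
    if np.any(subjects["exit_age"].to_numpy() <= subjects["entry_age"].to_numpy()):
        raise ValueError("exit_age must exceed entry_age for every subject")

    ev = subjects[subjects["event"].astype(bool)]
    event_ages = np.unique(ev["exit_age"].to_numpy())
    entry = subjects["entry_age"].to_numpy()
    exit_ = subjects["exit_age"].to_numpy()
    sid = subjects["subject_id"].to_numpy()
    is_event = subjects["event"].to_numpy(dtype=bool)

    rec_subj, rec_age, rec_event = [], [], []
    for a in event_ages:
        at_risk = (entry < a) & (a <= exit_)
        idx = np.flatnonzero(at_risk)
        rec_subj.append(sid[idx])
        rec_age.append(np.full(idx.size, a))
        rec_event.append(is_event[idx] & (exit_[idx] == a))
    if not rec_subj:
        raise ValueError("cohort contains no events")
    rows = pd.DataFrame(
        {
            "subject": np.concatenate(rec_subj),
            "age": np.concatenate(rec_age),
            "event": np.concatenate(rec_event),
        }
    )
    # disjoint per-subject intervals: start at the previous risk-set age (or entry)
    entry_by_id = dict(zip(sid, entry))
    start = np.empty(len(rows))
    prev: dict = {}
    for i, (s, a) in enumerate(zip(rows["subject"], rows["age"])):
        start[i] = prev.get(s, entry_by_id[s])
        prev[s] = a

    pts = list(zip(rows["subject"], rows["age"].astype(int)))
    l0, L = lag_window
    Q_radon = build_history_matrix(radon_profiles, pts, l0, L)
    Q_smoking = None
    if smoking_profiles is not None:
        Q_smoking = build_history_matrix(smoking_profiles, pts, *smoking_lag_window)
    cal = None
    if calendar is not None:
        if calendar not in subjects.columns:
            raise ValueError(f"subject table is missing calendar column {calendar!r}")
        year_by_id = dict(zip(sid, subjects[calendar].to_numpy(dtype=float)))
        cal = np.array(
            [year_by_id[s] + (a - entry_by_id[s]) for s, a in zip(rows["subject"], rows["age"])]
        )
    return CohortExpansion(rows, start, Q_radon, Q_smoking, cal, smoking_fx, smoking_wl)


# ---------------------------------------------------------------------------
# Partial likelihood


def _risk_groups(data: CountingProcessData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map counting-process rows to risk-set-stacked layout.

    Returns (row_take, group_id, event_flag) with rows sorted by risk set:
    row ``i`` of the original data joins the risk set of every event time in
    ``(start_i, stop_i]`` (covariates are constant within a row's interval).
    """
    times = np.unique(data.stop[data.event])
    if times.size == 0:
        raise ValueError("at least one event is required")
    lo = np.searchsorted(times, data.start, side="right")
    hi = np.searchsorted(times, data.stop, side="right")
    counts = hi - lo
    row_take = np.repeat(np.arange(data.stop.size), counts)
    # group ids: for row i, the consecutive run lo[i] .. hi[i]-1
    offs = np.concatenate([[0], np.cumsum(counts)])
    group = np.arange(offs[-1]) - np.repeat(offs[:-1], counts) + np.repeat(lo, counts)
    ev = np.zeros(offs[-1], dtype=bool)
    last = offs[1:] - 1
    ev[last[counts > 0]] = data.event[counts > 0] & np.isin(data.stop[counts > 0], times)
    order = np.argsort(group, kind="stable")
    return row_take[order], group[order], ev[order]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    q, r = np.linalg.qr(X - X.mean(axis=0))
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = np.flatnonzero(diag <= tol)
    return [names[i] if i < len(names) else f"col{i}" for i in bad]


class _GroupIndex:
    """Precomputed risk-set bookkeeping shared across Newton iterations."""

    def __init__(self, group: np.ndarray, event: np.ndarray, ties: str):
        self.starts = np.flatnonzero(np.diff(group, prepend=group[0] - 1))
        counts = np.diff(np.append(self.starts, group.size))
        self.gix = np.repeat(np.arange(self.starts.size), counts)
        d = np.add.reduceat(event.astype(float), self.starts).astype(int)
        if np.any(d == 0):
            raise ValueError("every risk set must contain at least one event")
        # (group, r) pairs, r = 0..d_g-1 (Efron within-tie adjustment)
        G = self.starts.size
        self.pair_g = np.repeat(np.arange(G), d)
        pair_r = np.arange(self.pair_g.size) - np.repeat(np.cumsum(d) - d, d)
        rod = pair_r / np.repeat(d, d)
        if ties == "breslow":
            rod = np.zeros_like(rod)
        elif ties != "efron":
            raise ValueError(f"unknown ties method {ties!r}")
        self.rod = rod
        self.n_groups = G


def partial_loglik(
    X: np.ndarray,
    group: np.ndarray,
    event: np.ndarray,
    eta: np.ndarray,
    ties: str = "efron",
    derivatives: bool = True,
    _gi: "_GroupIndex | None" = None,
):
    """Efron/Breslow partial log-likelihood and derivatives on stacked risk sets.

    Rows must be sorted by ``group`` (one group per event time).  Returns
    ``(loglik, gradient, information)`` -- the information matrix is the
    negative Hessian.
    """
    gi = _gi if _gi is not None else _GroupIndex(group, event, ties)
    starts, gix, pair_g, rod = gi.starts, gi.gix, gi.pair_g, gi.rod
    k = X.shape[1]
    lp = X @ eta if k else np.zeros(X.shape[0])
    # per-group max-centering keeps the exponentials in range
    m = np.maximum.reduceat(lp, starts)
    w = np.exp(lp - m[gix])
    S = np.add.reduceat(w, starts)
    wD = np.where(event, w, 0.0)
    SD = np.add.reduceat(wD, starts)
    G = gi.n_groups
    denom = S[pair_g] - rod * SD[pair_g]
    ll = float(lp[event].sum() - (np.log(denom) + m[pair_g]).sum())
    if not derivatives:
        return ll, None, None

    if k == 0:
        return ll, np.zeros(0), np.zeros((0, 0))
    U = np.add.reduceat(w[:, None] * X, starts, axis=0)  # (G, k)
    UD = np.add.reduceat(wD[:, None] * X, starts, axis=0)
    mu = (U[pair_g] - rod[:, None] * UD[pair_g]) / denom[:, None]  # (P, k)
    grad = X[event].sum(axis=0) - mu.sum(axis=0)

    inv_denom = 1.0 / denom
    a = np.zeros(G)
    b = np.zeros(G)
    np.add.at(a, pair_g, inv_denom)
    np.add.at(b, pair_g, rod * inv_denom)
    rw = w * (a[gix] - np.where(event, b[gix], 0.0))
    info = (X * rw[:, None]).T @ X - mu.T @ mu
    return ll, grad, info


def fit_cox(
    data: CountingProcessData,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> FittedDLNM:
    """Maximize the Cox partial likelihood by Newton-Raphson with step-halving.

    Uses the Efron tie correction by default (``ties="breslow"`` for
    cross-checks).  Raises :class:`ConvergenceError` on failure and a
    ``LinAlgError``-derived message naming collinear columns on rank
    deficiency.
    """
    row_take, group, event = _risk_groups(data)
    return fit_stacked(
        data.X[row_take],
        group,
        event,
        ties=ties,
        max_iter=max_iter,
        tol=tol,
        column_names=list(data.column_names),
        terms=dict(data.terms),
        n_events=data.n_events,
    )


def fit_stacked(
    X: np.ndarray,
    group: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
    column_names: list[str] | None = None,
    terms: dict | None = None,
    n_events: int | None = None,
) -> FittedDLNM:
    """Newton-Raphson on pre-stacked risk sets (rows sorted by risk-set id)."""
    column_names = column_names or []
    terms = terms or {}
    if n_events is None:
        n_events = int(np.asarray(event).sum())
    k = X.shape[1]
    eta = np.zeros(k)
    gi = _GroupIndex(group, event, ties)
    ll, grad, info = partial_loglik(X, group, event, eta, ties=ties, _gi=gi)
    trace = [ll]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if k == 0:
            break
        try:
            cf = cho_factor(info)
        except np.linalg.LinAlgError as e:
            bad = _collinear_columns(X, column_names)
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (singular information); "
                f"suspect columns: {bad}"
            ) from e
        step = cho_solve(cf, grad)
        new_eta, new = eta, None
        for _ in range(40):
            cand = eta + step
            ll_new, g_new, i_new = partial_loglik(X, group, event, cand, ties=ties, _gi=gi)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                new_eta, new = cand, (ll_new, g_new, i_new)
                break
            step = step / 2.0
        if new is None:
            raise ConvergenceError("step-halving failed to improve the log-likelihood", trace)
        ll_new, grad, info = new
        eta = new_eta
        trace.append(ll_new)
        if abs(ll_new - ll) <= tol * (abs(ll_new) + 0.1):
            ll = ll_new
            break
        ll = ll_new
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)

    if k:
        try:
            vcov = cho_solve(cho_factor(info), np.eye(k))
        except np.linalg.LinAlgError as e:
            bad = _collinear_columns(X, column_names)
            raise np.linalg.LinAlgError(
                f"information matrix singular at the optimum; suspect columns: {bad}"
            ) from e
        vcov = (vcov + vcov.T) / 2.0
    else:
        vcov = np.zeros((0, 0))
    return FittedDLNM(
        eta=eta,
        vcov=vcov,
        loglik=ll,
        df_total=k,
        n_events=n_events,
        terms=terms,
        column_names=column_names,
        n_iter=n_iter,
    )


def aic_bic(fit: FittedDLNM) -> tuple[float, float]:
    """Survival-adapted information criteria; the BIC penalty uses log(d)."""
    d = fit.n_events
    if d == 0:
        raise ValueError("AIC/BIC require at least one uncensored event")
    k = fit.df_total
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + np.log(d) * k
    return aic, bic


def select_model(
    candidates: list[tuple[BasisSpec, BasisSpec]],
    data: CohortExpansion,
    ties: str = "efron",
    name: str = "radon",
) -> tuple[FittedDLNM, FittedDLNM, pd.DataFrame]:
    """Fit every candidate cross-basis and return the AIC- and BIC-best fits.

    Ties on the criterion value are broken toward the smaller model (lower
    ``k``), then candidate order.  Returns the full criterion table as a
    third element.
    """
    records = []
    fits: list[FittedDLNM | None] = []
    for i, (fx, wl) in enumerate(candidates):
        try:
            fit = fit_cox(data.design(fx, wl, name=name), ties=ties)
            aic, bic = aic_bic(fit)
            records.append(
                {
                    "model": i + 1,
                    "fx": fx.kind,
                    "wl": wl.kind,
                    "df_cb": crossbasis_df(fx, wl),
                    "df_total": fit.df_total,
                    "loglik": fit.loglik,
                    "AIC": aic,
                    "BIC": bic,
                    "error": "",
                }
            )
            fits.append(fit)
        except (np.linalg.LinAlgError, ConvergenceError, ValueError) as e:
            records.append(
                {
                    "model": i + 1,
                    "fx": fx.kind,
                    "wl": wl.kind,
                    "df_cb": crossbasis_df(fx, wl),
                    "df_total": np.nan,
                    "loglik": np.nan,
                    "AIC": np.nan,
                    "BIC": np.nan,
                    "error": str(e),
                }
            )
            fits.append(None)
    table = pd.DataFrame(records)
    ok = table["AIC"].notna()
    if not ok.any():
        raise RuntimeError("all candidate models failed to fit")

    def _best(col: str) -> FittedDLNM:
        sub = table[ok].sort_values([col, "df_total", "model"], kind="stable")
        return fits[int(sub.index[0])]

    return _best("AIC"), _best("BIC"), table
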