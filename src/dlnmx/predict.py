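"""Prediction from fitted DLNMs.

All risk summaries are linear combinations ``b' eta`` of the fitted
cross-basis coefficients, with standard errors from the delta-method
quadratic form ``sqrt(b' V b)``.  Exposure-basis rows are centered on a
reference exposure ``x0`` (default 0), so every summary is a log-hazard
ratio relative to a subject held at ``x0``: the predicted curve is exactly
zero at ``x = x0`` and HR(x0) = 1.

Available summaries:

* :func:`predict_lag_curve` -- risk contributions along lags for a fixed
  exposure intensity ``x_p`` (the lag-response curve);
* :func:`predict_exposure_curve` -- risk along exposure for a fixed lag
  (the exposure-response curve);
* :func:`predict_grid` -- the full bidimensional exposure-lag-response
  surface;
* :func:`cumulative_effect` -- the overall cumulative log-HR of an entire
  exposure history, summing lag-specific contributions;
* :func:`risk_trajectory` -- cumulative effects evaluated along an exposure
  profile, showing how risk evolves in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .basis import center_basis_row, eval_basis
from .history import ExposureProfile, exposure_history
from .survfit import CrossBasisTerm, FittedDLNM

__all__ = [
    "PredictionGrid",
    "predict_lag_curve",
    "predict_exposure_curve",
    "predict_grid",
    "cumulative_effect",
    "risk_trajectory",
]


@dataclass
class PredictionGrid:
    """Log-HR contributions and SEs over an (exposure x lag) grid."""

    x_values: np.ndarray
    lag_values: np.ndarray
    betahat: np.ndarray  # (n_x, n_lag)
    se: np.ndarray
    x0: float
    cumulative: tuple[float, float] | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.betahat)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + level / 2.0)
        return np.exp(self.betahat - z * self.se), np.exp(self.betahat + z * self.se)

    def to_frame(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = self.ci(level)
        xx, ll = np.meshgrid(self.x_values, self.lag_values, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "lag": ll.ravel(),
                "loghr": self.betahat.ravel(),
                "se": self.se.ravel(),
                "hr": self.hr.ravel(),
                "hr_lo": lo.ravel(),
                "hr_hi": hi.ravel(),
            }
        )


def _cb_block(fit: FittedDLNM, term: str | None) -> tuple[CrossBasisTerm, np.ndarray, np.ndarray]:
    t = fit.term(term)
    sl = t.sl
    return t, fit.eta[sl], fit.vcov[sl, sl] if fit.vcov.size else np.zeros((0, 0))


def _centered_fx(t: CrossBasisTerm, x: np.ndarray, x0: float) -> np.ndarray:
    spec = t.fx_spec
    r0 = center_basis_row(spec, x0)
    return eval_basis(np.asarray(x, dtype=float), spec).values - r0


def _grid_b(t: CrossBasisTerm, x: np.ndarray, lags: np.ndarray, x0: float) -> np.ndarray:
    """b-vectors B[x, lag, (j,k)] = (f_j(x) - f_j(x0)) * c_k(lag)."""
    R = _centered_fx(t, x, x0)  # (nx, vx)
    C = eval_basis(np.asarray(lags, dtype=float), t.wl_spec).values  # (nl, vl)
    B = np.einsum("xj,lk->xljk", R, C)
    return B.reshape(R.shape[0], C.shape[0], -1)


def _apply(B: np.ndarray, eta: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta = B @ eta
    var = np.einsum("...i,ij,...j->...", B, V, B)
    return beta, np.sqrt(np.maximum(var, 0.0))


def predict_lag_curve(
    fit: FittedDLNM,
    x_p: float,
    lag_grid: np.ndarray | None = None,
    x0: float = 0.0,
    term: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lag-response curve at exposure intensity ``x_p`` (centered at ``x0``)."""
    t, eta, V = _cb_block(fit, term)
    lags = t.lag_grid if lag_grid is None else np.asarray(lag_grid)
    B = _grid_b(t, np.array([x_p]), lags, x0)[0]
    return _apply(B, eta, V)


def predict_exposure_curve(
    fit: FittedDLNM,
    lag_p: float,
    x_grid: np.ndarray,
    x0: float = 0.0,
    term: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exposure-response curve at lag ``lag_p`` (centered at ``x0``)."""
    t, eta, V = _cb_block(fit, term)
    B = _grid_b(t, np.asarray(x_grid), np.array([lag_p]), x0)[:, 0]
    return _apply(B, eta, V)


def predict_grid(
    fit: FittedDLNM,
    x_grid: np.ndarray,
    lag_grid: np.ndarray | None = None,
    x0: float = 0.0,
    term: str | None = None,
) -> PredictionGrid:
    """Bidimensional risk surface over exposure x lag."""
    t, eta, V = _cb_block(fit, term)
    lags = t.lag_grid if lag_grid is None else np.asarray(lag_grid)
    B = _grid_b(t, np.asarray(x_grid), lags, x0)
    beta, se = _apply(B, eta, V)
    return PredictionGrid(
        x_values=np.asarray(x_grid, dtype=float),
        lag_values=np.asarray(lags, dtype=float),
        betahat=beta,
        se=se,
        x0=x0,
    )


def cumulative_b(t: CrossBasisTerm, q_h: np.ndarray, x0: float = 0.0) -> np.ndarray:
    """The b-vector of the overall cumulative effect of history ``q_h``."""
    q = np.asarray(q_h, dtype=float)
    if q.size != t.lag_grid.size:
        raise ValueError(f"history has length {q.size}, lag grid has {t.lag_grid.size}")
    R = _centered_fx(t, q, x0)  # (nl, vx)
    C = eval_basis(t.lag_grid.astype(float), t.wl_spec).values  # (nl, vl)
    return np.einsum("lj,lk->jk", R, C).ravel()


def cumulative_effect(
    fit: FittedDLNM,
    q_h: np.ndarray,
    x0: float = 0.0,
    term: str | None = None,
) -> tuple[float, float]:
    """Overall cumulative log-HR of an exposure history, with its SE.

    Equals the sum over lags of the lag-specific contributions evaluated at
    the actual (time-varying) exposures, relative to a constant-``x0``
    history.
    """
    t, eta, V = _cb_block(fit, term)
    b = cumulative_b(t, q_h, x0)
    beta = float(b @ eta)
    se = float(np.sqrt(max(b @ V @ b, 0.0)))
    return beta, se


def risk_trajectory(
    fit: FittedDLNM,
    profile: ExposureProfile,
    eval_times: np.ndarray,
    x0: float = 0.0,
    term: str | None = None,
) -> pd.DataFrame:
    """Cumulative effect of a profile's history at each evaluation time."""
    t, _, _ = _cb_block(fit, term)
    l0, L = int(t.lag_grid[0]), int(t.lag_grid[-1])
    rows = []
    for tt in np.asarray(eval_times):
        q = exposure_history(profile, int(tt), l0, L)
        beta, se = cumulative_effect(fit, q, x0=x0, term=term)
        rows.append({"time": tt, "loghr": beta, "se": se, "hr": np.exp(beta)})
    return pd.DataFrame(rows)
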