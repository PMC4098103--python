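"""Cross-basis construction: the tensor-product design matrix of a DLNM.

Given a history matrix ``Q`` (one exposure history per row), an exposure
basis ``f(x)`` and a lag basis ``w(l)``, the cross-basis row for history
``q`` is

    W[(j, k)] = sum_l  f_j(q_l) * c_k(l)

i.e. ``vec(R^T C)`` with ``R`` the exposure basis evaluated on the history
and ``C`` the lag basis evaluated on the lag grid.  With a linear exposure
basis this reduces exactly to the distributed-lag-model design ``Q C``; with
additionally a constant lag basis it reduces to the traditional unweighted
cumulative exposure (row sums of ``Q``).

Column order: exposure-basis index ``j`` varies slowest, lag-basis index
``k`` fastest; prediction code relies on this layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSpec, eval_basis
from .history import HistoryMatrix

__all__ = ["CrossBasis", "build_crossbasis", "crossbasis_df"]


@dataclass
class CrossBasis:
    """N x (v_x * v_l) cross-basis matrix plus the metadata needed to predict."""

    W: np.ndarray
    fx_spec: BasisSpec
    wl_spec: BasisSpec
    lag_grid: np.ndarray
    column_order: list[tuple[int, int]] = field(default_factory=list)

    @property
    def df(self) -> int:
        return self.W.shape[1]

    def column_names(self, prefix: str = "cb") -> list[str]:
        return [f"{prefix}_{j}_{k}" for j, k in self.column_order]

    def to_frame(self, prefix: str = "cb"):
        """Regression-agnostic export of the design matrix with headed columns."""
        import pandas as pd

        return pd.DataFrame(self.W, columns=self.column_names(prefix))


def crossbasis_df(fx_spec: BasisSpec, wl_spec: BasisSpec) -> int:
    """Degrees of freedom of the cross-basis: v_x * v_l."""
    return fx_spec.dimension * wl_spec.dimension


def cross_rows(F: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Lag-summed tensor product: F is (N, n_lags, v_x), C is (n_lags, v_l)."""
    n = F.shape[0]
    return np.einsum("nlj,lk->njk", F, C, optimize=True).reshape(n, -1)


def build_crossbasis(
    Q: HistoryMatrix | np.ndarray,
    fx_spec: BasisSpec,
    wl_spec: BasisSpec,
    lag_grid: np.ndarray | None = None,
) -> CrossBasis:
    """Build the cross-basis design matrix from exposure histories.

    ``fx_spec`` must carry no intercept: with one, each of the ``v_l`` lag
    columns would be reproduced by the intercept column's products and the
    regression coefficients would not be identifiable.  The exposure-basis
    boundary defaults to the observed range of ``Q``.
    """
    if isinstance(Q, HistoryMatrix):
        lag_grid = Q.lag_grid
        Qm = Q.Q
    else:
        Qm = np.asarray(Q, dtype=float)
        if lag_grid is None:
            raise ValueError("lag_grid is required when Q is a bare matrix")
        lag_grid = np.asarray(lag_grid)
    if Qm.ndim != 2 or Qm.shape[1] != lag_grid.size:
        raise ValueError(f"Q has shape {Qm.shape}, expected (*, {lag_grid.size})")
    if not np.all(np.isfinite(Qm)):
        raise ValueError("exposure histories must be finite")
    if fx_spec.intercept:
        raise ValueError(
            "identifiability: the exposure basis f(x) must be defined without an "
            "intercept (the cross-basis would be rank deficient)"
        )

    qlo, qhi = float(Qm.min()), float(Qm.max())
    if qhi <= qlo:  # degenerate observed range
        qhi = qlo + 1.0
    fx_spec = fx_spec.with_boundary(qlo, qhi)
    wl_spec = wl_spec.with_boundary(lag_grid.min(), lag_grid.max())

    C = eval_basis(lag_grid, wl_spec).values
    F = eval_basis(Qm.ravel(), fx_spec).values.reshape(Qm.shape + (-1,))
    W = cross_rows(F, C)

    v_x, v_l = fx_spec.dimension, wl_spec.dimension
    order = [(j, k) for j in range(v_x) for k in range(v_l)]

    nonzero = np.abs(W).max(axis=0) > 0
    if nonzero.any() and W.shape[0] >= int(nonzero.sum()):
        rank = np.linalg.matrix_rank(W[:, nonzero])
        if rank < int(nonzero.sum()):
            offending = [order[i] for i in np.flatnonzero(nonzero)]
            warnings.warn(
                f"cross-basis is rank deficient (rank {rank} < {int(nonzero.sum())} "
                f"non-constant columns) among column pairs {offending}",
                stacklevel=2,
            )
    return CrossBasis(W=W, fx_spec=fx_spec, wl_spec=wl_spec, lag_grid=np.asarray(lag_grid), column_order=order)
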