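"""Exposure histories on a discrete lag grid.

The risk at time ``t`` depends on the vector of past exposure intensities
``q_{x,t} = (x_{t-l0}, ..., x_{t-L})`` -- the *exposure history* over the lag
window ``[l0, L]``.  This module builds such histories from per-subject
exposure profiles, using a yearly discretization: lag ``l`` refers to the
exposure received during year ``t - l``, and times before the profile start
contribute zero exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExposureProfile",
    "HistoryMatrix",
    "exposure_history",
    "build_history_matrix",
    "expand_intervals",
]


@dataclass
class ExposureProfile:
    """Per-subject intensity series on an integer time grid.

    ``intensity[j]`` is the exposure rate (e.g. WLM/year) during year
    ``start_time + j``.  Outside the recorded span the rate is zero, except
    with ``extend="hold"`` where the last recorded rate persists after the
    end of the series (used for smoking, reported only up to the last
    questionnaire age).
    """

    subject_id: object
    start_time: int
    intensity: np.ndarray
    extend: str = "zero"  # "zero" | "hold"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        if self.extend not in ("zero", "hold"):
            raise ValueError("extend must be 'zero' or 'hold'")

    def rate_at(self, times: np.ndarray | int) -> np.ndarray:
        """Intensity at integer time(s), applying the extension rule."""
        t = np.atleast_1d(np.asarray(times, dtype=int))
        idx = t - self.start_time
        n = self.intensity.size
        out = np.zeros(t.shape, dtype=float)
        inside = (idx >= 0) & (idx < n)
        out[inside] = self.intensity[idx[inside]]
        if self.extend == "hold" and n:
            out[idx >= n] = self.intensity[-1]
        return out


@dataclass
class HistoryMatrix:
    """N x (L - l0 + 1) matrix of exposure histories.

    ``Q[i, j]`` is the intensity of row ``i``'s subject at time
    ``t_i - (l0 + j)``; columns follow ``lag_grid = l0..L``.
    """

    Q: np.ndarray
    lag_grid: np.ndarray
    row_index: list = field(default_factory=list)

    @property
    def n_lags(self) -> int:
        return self.Q.shape[1]

    def to_frame(self):
        """Audit export: one row per evaluation point, one column per lag."""
        import pandas as pd

        df = pd.DataFrame(self.Q, columns=[f"lag{int(l)}" for l in self.lag_grid])
        if self.row_index:
            df.insert(0, "subject", [s for s, _ in self.row_index])
            df.insert(1, "time", [t for _, t in self.row_index])
        return df


def exposure_history(profile: ExposureProfile, t: int, l0: int, L: int) -> np.ndarray:
    """History vector ``(x_{t-l0}, ..., x_{t-L})`` for one subject at time t."""
    if not 0 <= l0 <= L:
        raise ValueError(f"lag window requires 0 <= l0 <= L, got [{l0}, {L}]")
    lags = np.arange(l0, L + 1)
    return profile.rate_at(int(t) - lags)


def build_history_matrix(
    profiles: Iterable[ExposureProfile],
    eval_points: Sequence[tuple[object, int]],
    l0: int,
    L: int,
) -> HistoryMatrix:
    """Stack exposure histories for (subject, time) evaluation points.

    Row order matches ``eval_points``; an unknown subject id raises.
    """
    if not 0 <= l0 <= L:
        raise ValueError(f"lag window requires 0 <= l0 <= L, got [{l0}, {L}]")
    by_id = {p.subject_id: p for p in profiles}
    lags = np.arange(l0, L + 1)
    Q = np.empty((len(eval_points), lags.size))
    for i, (sid, t) in enumerate(eval_points):
        if sid not in by_id:
            raise KeyError(f"unknown subject id {sid!r}")
        Q[i] = by_id[sid].rate_at(int(t) - lags)
    return HistoryMatrix(Q=Q, lag_grid=lags, row_index=list(eval_points))


def expand_intervals(
    interval_starts: np.ndarray,
    cumulative: np.ndarray,
    width: int = 5,
) -> tuple[int, np.ndarray]:
    """Expand cumulative exposure over fixed-width age intervals to yearly rates.

    Cohort files report cumulative exposure at the start of consecutive
    ``width``-year age intervals; the increment accrued within each interval
    is allocated uniformly to its years (increment / width).  Returns the
    first covered age and the yearly rate series.
    """
    starts = np.asarray(interval_starts, dtype=int)
    cum = np.asarray(cumulative, dtype=float)
    if starts.size != cum.size or starts.size == 0:
        raise ValueError("interval starts and cumulative values must be equal-length, non-empty")
    order = np.argsort(starts)
    starts, cum = starts[order], cum[order]
    if np.any(np.diff(starts) != width):
        raise ValueError(f"age intervals must be consecutive with width {width}, got starts {starts}")
    increments = np.diff(np.concatenate([[0.0], cum]))
    if np.any(increments < -1e-9):
        raise ValueError("cumulative exposure must be non-decreasing across intervals")
    rates = np.repeat(np.maximum(increments, 0.0) / width, width)
    return int(starts[0]), rates
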