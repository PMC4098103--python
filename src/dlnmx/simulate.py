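"""Simulation of survival data with protracted time-varying exposures.

Subjects receive random exposure *spells* over ``t = 1..100`` with
intensities in ``[0, 10]``.  A true exposure-lag-response association of the
independent form ``f_s(x) * w_s(l)`` over the lag window ``0..40`` converts
each subject's history into a time-varying cumulative log-hazard
contribution.  Event and censoring times are then married to subjects by a
permutational algorithm: candidate times are sorted in ascending order and
each *event* time is assigned to a not-yet-assigned subject with probability
proportional to ``exp`` of that subject's true cumulative effect at that
time, while each *censoring* time is assigned uniformly among the remaining
subjects.  Under a null association this reduces to a uniform random
permutation of times over subjects.

Nine scenarios combine exposure-response shapes {linear, plateau,
exponential} with lag-response shapes {constant, decay, peak}.  Every
lag-response curve is normalized to unit sum over the lag window and every
exposure-response curve to ``f(10) = 1``, so a single magnitude parameter
sets the overall signal strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .history import ExposureProfile

__all__ = [
    "Scenario",
    "SimulatedCohort",
    "scenario",
    "SCENARIO_NAMES",
    "gen_profiles",
    "true_cumulative",
    "cumulative_series",
    "permutational_assign",
    "simulate_dataset",
]

T_MAX = 100
L_SIM = 40
X_MAX = 10.0

# Overall signal magnitude: the log-HR of a subject exposed at the maximum
# intensity over the whole lag window, relative to an unexposed subject.
# 6.0 yields cumulative hazard ratios up to ~e^2-e^3 across realistic
# histories (strong-carcinogen territory) and near-unit power for detecting
# non-constant lag structures at a few hundred events.
DEFAULT_MAGNITUDE = 6.0

# Spell model: occupational-like serially correlated exposure.  The rate and
# duration give ~50% exposed years per subject, so a 41-year lag window
# almost always contains some exposure and cumulative effects are rarely
# degenerate at zero.
SPELL_RATE = 5.0        # mean number of exposure spells per subject
SPELL_DURATION_P = 0.1  # geometric duration parameter (mean 10 years)

# Lag-response shape constants (years).
DECAY_TAU = 10.0
PEAK_CENTER = 15.0
PEAK_WIDTH = 7.0


@dataclass(frozen=True)
class Scenario:
    """A true exposure-lag-response association ``f_s(x) * w_s(l)``."""

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    w: np.ndarray = field(repr=False)  # weights on lags 0..L_SIM, sum 1
    magnitude: float = DEFAULT_MAGNITUDE

    @property
    def lag_grid(self) -> np.ndarray:
        return np.arange(self.w.size)

    def fw(self, x: np.ndarray, lag_idx: np.ndarray) -> np.ndarray:
        return self.magnitude * self.f(np.asarray(x, dtype=float)) * self.w[lag_idx]


def _f_linear(x):
    return x / X_MAX


def _f_plateau(x):
    return np.log1p(x) / np.log1p(X_MAX)


def _f_exponential(x, kappa=X_MAX / 3.0):
    return np.expm1(x / kappa) / np.expm1(X_MAX / kappa)


def _w_constant():
    return np.full(L_SIM + 1, 1.0 / (L_SIM + 1))


def _w_decay():
    w = np.exp(-np.arange(L_SIM + 1) / DECAY_TAU)
    return w / w.sum()


def _w_peak():
    l = np.arange(L_SIM + 1)
    w = np.exp(-((l - PEAK_CENTER) ** 2) / (2 * PEAK_WIDTH**2))
    w = np.maximum(w - w[-1], 0.0)  # zero-anchored at the last lag
    return w / w.sum()


_F = {"linear": _f_linear, "plateau": _f_plateau, "exponential": _f_exponential}
_W = {"constant": _w_constant, "decay": _w_decay, "peak": _w_peak}

SCENARIO_NAMES = tuple(f"{fx}-{wl}" for fx in _F for wl in _W)


def scenario(name: str, magnitude: float = DEFAULT_MAGNITUDE) -> Scenario:
    """Look up one of the nine scenarios, e.g. ``"plateau-decay"``."""
    try:
        fx, wl = name.split("-")
        f, w = _F[fx], _W[wl]()
    except (ValueError, KeyError):
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}") from None
    return Scenario(name=name, f=f, w=w, magnitude=magnitude)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_profiles(ns: int, seed) -> list[ExposureProfile]:
    """Random exposure profiles on ``t = 1..100``.

    Each subject receives a Poisson number of spells with uniform start,
    geometric duration and uniform(0, 10) intensity; overlapping spells take
    the maximum intensity so values stay within ``[0, 10]``.
    """
    if ns < 2:
        raise ValueError("at least 2 subjects are required")
    rng = _as_rng(seed)
    profiles = []
    for i in range(ns):
        x = np.zeros(T_MAX)
        for _ in range(rng.poisson(SPELL_RATE)):
            start = rng.integers(1, T_MAX + 1)
            dur = rng.geometric(SPELL_DURATION_P)
            inten = rng.uniform(0.0, X_MAX)
            lo, hi = start - 1, min(start - 1 + dur, T_MAX)
            x[lo:hi] = np.maximum(x[lo:hi], inten)
        profiles.append(ExposureProfile(subject_id=i, start_time=1, intensity=x))
    return profiles


def true_cumulative(q: np.ndarray, scen: Scenario) -> float:
    """True cumulative effect sum_l f_s(q_l) w_s(l) of a history on lags 0..40."""
    q = np.asarray(q, dtype=float)
    if q.size != scen.w.size:
        raise ValueError(f"history has length {q.size}, expected {scen.w.size}")
    return float(scen.magnitude * np.dot(scen.f(q), scen.w))


def cumulative_series(profiles: Sequence[ExposureProfile], scen: Scenario) -> np.ndarray:
    """True cumulative effect of every subject at every integer time 1..100."""
    X = np.stack([p.intensity for p in profiles])
    F = scen.magnitude * scen.f(X)
    Fp = np.pad(F, ((0, 0), (L_SIM, 0)))
    win = np.lib.stride_tricks.sliding_window_view(Fp, L_SIM + 1, axis=1)
    return win @ scen.w[::-1]


def _effect_at(effect_series: np.ndarray, t: float) -> np.ndarray:
    """Column of the effect series for a (possibly non-integer) time."""
    yr = int(np.clip(np.floor(t), 1, T_MAX))
    return effect_series[:, yr - 1]


@dataclass
class SimulatedCohort:
    """Simulated survival cohort: profiles, assigned times and true effects."""

    profiles: list[ExposureProfile]
    time: np.ndarray
    status: np.ndarray  # 1 event, 0 censored
    effect_series: np.ndarray  # (ns, 100) true cumulative effect at t = 1..100
    scenario_name: str = ""
    seed: object = None

    @property
    def ns(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


def permutational_assign(
    event_times: np.ndarray,
    censor_times: np.ndarray,
    effect_series: np.ndarray,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign candidate times to subjects proportionally to their hazard.

    Times are processed in ascending order; each event time goes to an
    unassigned subject sampled with probability proportional to ``exp`` of
    the subject's true cumulative effect at that time, each censoring time
    uniformly.  Returns per-subject ``(time, status)`` arrays.
    """
    rng = _as_rng(seed)
    ev = np.asarray(event_times, dtype=float)
    ce = np.asarray(censor_times, dtype=float)
    ns = effect_series.shape[0]
    n_times = ev.size + ce.size
    if n_times > ns:
        raise ValueError(f"{n_times} candidate times for only {ns} subjects")
    times = np.concatenate([ev, ce])
    flags = np.concatenate([np.ones(ev.size, bool), np.zeros(ce.size, bool)])
    order = np.argsort(times, kind="stable")

    unassigned = np.ones(ns, dtype=bool)
    out_time = np.full(ns, np.nan)
    out_status = np.zeros(ns, dtype=int)
    for t, is_event in zip(times[order], flags[order]):
        pool = np.flatnonzero(unassigned)
        if is_event:
            b = _effect_at(effect_series, t)[pool]
            p = np.exp(b - b.max())
            p /= p.sum()
            pick = rng.choice(pool, p=p)
        else:
            pick = rng.choice(pool)
        unassigned[pick] = False
        out_time[pick] = t
        out_status[pick] = int(is_event)
    if unassigned.any():
        raise ValueError("every subject must receive a candidate time")
    return out_time, out_status


def simulate_dataset(
    scen: Scenario | str,
    ns: int,
    seed,
    censor_frac: float = 0.25,
) -> SimulatedCohort:
    """Generate one replicate cohort under a scenario.

    Candidate times are uniform on ``(1, 100]``; each subject is marked for
    censoring independently with probability ``censor_frac`` (the remainder
    become events), and the permutational algorithm marries times to
    subjects.
    """
    if isinstance(scen, str):
        scen = scenario(scen)
    rng = _as_rng(seed)
    profiles = gen_profiles(ns, rng)
    effect = cumulative_series(profiles, scen)
    censored = rng.random(ns) < censor_frac
    times = rng.uniform(1.0, float(T_MAX), size=ns)  # continuous, ties a.s. absent
    ev_times = times[~censored]
    ce_times = times[censored]
    time, status = permutational_assign(ev_times, ce_times, effect, rng)
    return SimulatedCohort(
        profiles=profiles,
        time=time,
        status=status,
        effect_series=effect,
        scenario_name=scen.name,
        seed=seed,
    )
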