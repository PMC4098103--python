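"""One-dimensional basis transformations for the exposure and lag dimensions.

A distributed lag non-linear model is assembled from two one-dimensional
function spaces: an exposure-response basis ``f(x)`` and a lag-response basis
``w(l)``.  This module evaluates both kinds of basis on arbitrary points and
handles the boundary constraints that matter for lag structures:

* *left constraint* -- excluding the intercept from a spline basis forces the
  fitted curve through zero at the left boundary of the lag window (null risk
  at the shortest lag);
* *right constraint* -- dropping the terminal B-spline function forces the
  curve to zero at the end of the lag window (null risk for the most distant
  exposures).

Supported kinds: ``linear``, ``constant``, ``step`` (piecewise constant),
``threshold`` (hinge), ``bspline`` (B-splines of configurable degree),
``nspline`` (natural cubic splines) and ``logshift`` (``log(x + shift)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline, CubicSpline

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "eval_basis",
    "drop_intercept",
    "apply_right_constraint",
    "center_basis_row",
]

_KINDS = ("linear", "constant", "step", "threshold", "bspline", "nspline", "logshift")
_SPLINE_KINDS = ("bspline", "nspline")


@dataclass(frozen=True)
class BasisSpec:
    """Definition of a one-dimensional basis transformation.

    Parameters
    ----------
    kind : str
        One of ``linear``, ``constant``, ``step``, ``threshold``, ``bspline``,
        ``nspline``, ``logshift``.
    degree : int
        Spline degree (``bspline`` only; quadratic by default).
    knots : tuple of float
        Interior knots (splines), cut-offs (``step``) or hinge locations
        (``threshold``); strictly increasing, strictly inside ``boundary``.
    boundary : (float, float), optional
        Support of the basis.  Required for spline kinds at evaluation time;
        for other kinds it only gates evaluation (no silent extrapolation
        when set).
    intercept : bool
        Whether the basis spans the constant function.  For splines,
        ``intercept=False`` removes the left-terminal function so every basis
        column vanishes at the left boundary (left constraint).  For ``step``,
        ``intercept=False`` drops the indicator of the lowest stratum, making
        it the reference level.
    right_constrained : bool
        B-splines only: drop the right-terminal function so the basis
        vanishes at the right boundary.
    shift : float
        Offset of the ``logshift`` transformation ``f(x) = log(x + shift)``.
    """

    kind: str
    degree: int = 2
    knots: tuple[float, ...] = ()
    boundary: tuple[float, float] | None = None
    intercept: bool = False
    right_constrained: bool = False
    shift: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}; expected one of {_KINDS}")
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        if self.boundary is not None:
            lo, hi = (float(b) for b in self.boundary)
            if not lo < hi:
                raise ValueError(f"boundary must be an increasing pair, got {self.boundary}")
            object.__setattr__(self, "boundary", (lo, hi))
        kn = np.asarray(self.knots)
        if kn.size and np.any(np.diff(kn) <= 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")
        if self.boundary is not None and kn.size:
            lo, hi = self.boundary
            if self.kind in _SPLINE_KINDS and (kn[0] <= lo or kn[-1] >= hi):
                raise ValueError(
                    f"interior knots {self.knots} must lie strictly inside boundary {self.boundary}"
                )
        if self.right_constrained and self.kind != "bspline":
            raise ValueError("right constraint applies to B-spline bases only")
        if self.kind == "bspline" and self.degree < 1:
            raise ValueError("bspline degree must be >= 1")
        if self.kind == "step" and not self.knots:
            raise ValueError("step basis requires at least one cut-off")
        if self.kind == "threshold" and not self.knots:
            raise ValueError("threshold basis requires at least one hinge location")
        if self.dimension < 1:
            raise ValueError(f"basis dimension must be >= 1 (spec {self})")

    @property
    def dimension(self) -> int:
        """Number of basis functions v implied by the spec."""
        if self.kind in ("linear", "constant", "logshift"):
            return 1
        if self.kind == "step":
            return len(self.knots) + int(self.intercept)
        if self.kind == "threshold":
            return len(self.knots)
        if self.kind == "bspline":
            v = len(self.knots) + self.degree + int(self.intercept)
            return v - int(self.right_constrained)
        if self.kind == "nspline":
            return len(self.knots) + 1 + int(self.intercept)
        raise AssertionError(self.kind)

    def with_boundary(self, lo: float, hi: float) -> "BasisSpec":
        """Return a copy with the boundary filled in if not already set."""
        if self.boundary is not None:
            return self
        return replace(self, boundary=(float(lo), float(hi)))

    def to_dict(self) -> dict:
        """Flat mapping used by config files and serialized fits."""
        return {
            "kind": self.kind,
            "degree": self.degree,
            "knots": list(self.knots),
            "boundary": list(self.boundary) if self.boundary is not None else None,
            "intercept": self.intercept,
            "right_constrained": self.right_constrained,
            "shift": self.shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        d = dict(d)
        if d.get("knots") is not None:
            d["knots"] = tuple(d["knots"])
        if d.get("boundary") is not None:
            d["boundary"] = tuple(d["boundary"])
        return cls(**d)


@dataclass
class BasisMatrix:
    """An evaluated basis: ``values[i, j] = b_j(points[i])``."""

    values: np.ndarray
    spec: BasisSpec
    input_grid: np.ndarray = field(repr=False)

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


def _check_range(x: np.ndarray, spec: BasisSpec) -> None:
    if spec.boundary is None:
        if spec.kind in _SPLINE_KINDS:
            raise ValueError(f"{spec.kind} basis requires an explicit boundary")
        return
    lo, hi = spec.boundary
    bad = (x < lo - 1e-12) | (x > hi + 1e-12)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} evaluation point(s) outside basis boundary "
            f"[{lo}, {hi}] (min={x.min()}, max={x.max()}); extrapolation is not performed"
        )


def _bspline_full(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Full (intercept-included) B-spline design matrix on the augmented knots."""
    lo, hi = spec.boundary
    k = spec.degree
    t = np.concatenate([[lo] * (k + 1), np.asarray(spec.knots, float), [hi] * (k + 1)])
    # design_matrix is exclusive of the right boundary point; evaluate the
    # exact boundary on the last span and overwrite with the exact limit
    # (only the terminal function is non-zero there, with value 1).
    at_hi = x == hi
    xe = np.where(at_hi, np.nextafter(hi, lo), np.clip(x, lo, hi))
    out = BSpline.design_matrix(xe, t, k, extrapolate=False).toarray()
    if np.any(at_hi):
        out[at_hi] = 0.0
        out[at_hi, -1] = 1.0
    return out


def _nspline_full(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Cardinal natural cubic splines interpolating unit vectors at the sites.

    The natural cubic spline space on sites (left boundary, interior knots,
    right boundary) has dimension ``#knots + 2`` and is parameterized by the
    function values at the sites; the basis columns are the natural-spline
    interpolants of the canonical unit vectors.  Column ``j`` therefore equals
    1 at site ``j`` and 0 at all other sites.
    """
    lo, hi = spec.boundary
    sites = np.concatenate([[lo], np.asarray(spec.knots, float), [hi]])
    m = sites.size
    out = np.empty((x.size, m))
    for j in range(m):
        e = np.zeros(m)
        e[j] = 1.0
        out[:, j] = CubicSpline(sites, e, bc_type="natural")(x)
    return out


def eval_basis(points: Sequence[float] | np.ndarray, spec: BasisSpec) -> BasisMatrix:
    """Evaluate a basis on a vector of points.

    Returns a :class:`BasisMatrix` of shape ``(len(points), spec.dimension)``.
    Points outside the boundary raise (no silent extrapolation).
    """
    x = np.asarray(points, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("evaluation points must be finite")
    _check_range(x, spec)

    if spec.kind == "linear":
        vals = x[:, None].copy()
    elif spec.kind == "constant":
        vals = np.ones((x.size, 1))
    elif spec.kind == "logshift":
        if np.any(x + spec.shift <= 0):
            raise ValueError(f"logshift undefined at x <= {-spec.shift}")
        vals = np.log(x + spec.shift)[:, None]
    elif spec.kind == "threshold":
        vals = np.maximum(0.0, x[:, None] - np.asarray(spec.knots))
    elif spec.kind == "step":
        cuts = np.asarray(spec.knots)
        stratum = np.searchsorted(cuts, x, side="right")  # 0..c
        full = np.zeros((x.size, cuts.size + 1))
        full[np.arange(x.size), stratum] = 1.0
        vals = full if spec.intercept else full[:, 1:]
    elif spec.kind == "bspline":
        full = _bspline_full(x, spec)
        if not spec.intercept:
            full = full[:, 1:]
        if spec.right_constrained:
            full = full[:, :-1]
        vals = full
    elif spec.kind == "nspline":
        full = _nspline_full(x, spec)
        if not spec.intercept:
            full = full[:, 1:]
        vals = full
    else:  # pragma: no cover
        raise AssertionError(spec.kind)

    assert vals.shape[1] == spec.dimension, (vals.shape, spec)
    return BasisMatrix(values=vals, spec=spec, input_grid=x)


def drop_intercept(basis: BasisMatrix) -> BasisMatrix:
    """Remove the intercept, left-constraining spline bases.

    For spline bases this removes the left-terminal function, so the fitted
    curve passes through zero at the left boundary for any coefficient vector.
    """
    spec = basis.spec
    if spec.dimension <= 1:
        raise ValueError("cannot drop the intercept of a one-column basis")
    if spec.kind in ("linear", "threshold", "logshift"):
        raise ValueError(f"{spec.kind} basis has no intercept to drop")
    if not spec.intercept:
        raise ValueError("basis was already defined without an intercept")
    new_spec = replace(spec, intercept=False)
    return BasisMatrix(values=basis.values[:, 1:], spec=new_spec, input_grid=basis.input_grid)


def apply_right_constraint(basis: BasisMatrix) -> BasisMatrix:
    """Drop the right-terminal B-spline function (null risk at the right boundary)."""
    spec = basis.spec
    if spec.kind != "bspline":
        raise ValueError("right constraint applies to B-spline bases only")
    if spec.right_constrained:
        raise ValueError("basis is already right-constrained")
    if spec.dimension <= 1:
        raise ValueError("right constraint would leave an empty basis")
    new_spec = replace(spec, right_constrained=True)
    return BasisMatrix(values=basis.values[:, :-1], spec=new_spec, input_grid=basis.input_grid)


def center_basis_row(spec: BasisSpec, x0: float) -> np.ndarray:
    """Basis row at the reference exposure ``x0``.

    Prediction code subtracts this row from exposure-basis rows so every risk
    summary is relative to ``x0`` (HR(x0) = 1).  Fitting is unaffected: the
    Cox partial likelihood has no intercept.
    """
    return eval_basis(np.array([float(x0)]), spec).values[0]
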