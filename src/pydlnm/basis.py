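"""One-dimensional basis matrices for the predictor and lag spaces.

A distributed lag non-linear model combines two one-dimensional bases: one
applied to the exposure values *x* (the "predictor space") and one applied to
the integer lag vector 0..L (the "lag space").  This module provides the
declarative :class:`BasisSpec`, the evaluator :func:`evaluate_basis`, the
dimension rule :func:`basis_dimension` and the log-scale lag knot placement
:func:`make_lag_knots`.

Conventions
-----------
Natural cubic splines follow the R ``splines::ns`` construction: a cubic
B-spline basis on the knot sequence with the second-derivative-at-boundary
constraint removed by QR projection, so that a basis with *K* internal knots
has ``K + 1`` columns without intercept (``K + 2`` with).  Under this
convention an 11-df predictor spline paired with a 5-df lag spline spends
exactly 55 parameters on the exposure-lag surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "evaluate_basis",
    "basis_dimension",
    "make_lag_knots",
]

_KINDS = {
    "linear",
    "polynomial",
    "natural_cubic_spline",
    "threshold",
    "strata",
    "constant",
    "identity",
}

# knot placement strategies for df-specified splines
_PLACEMENTS = {"even", "quantiles", "loglag"}


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of a one-dimensional basis.

    Parameters
    ----------
    kind : str
        One of ``linear``, ``polynomial``, ``natural_cubic_spline``,
        ``threshold``, ``strata``, ``constant``, ``identity``.
    degree : int, optional
        Polynomial degree (``polynomial`` only).
    df : int, optional
        Target dimension for spline bases; internal knots are placed from the
        data when :meth:`resolved` is called (``natural_cubic_spline`` only).
    knots : sequence of float, optional
        Strictly increasing knots in predictor units (spline / threshold /
        strata).
    boundary_knots : (float, float), optional
        Spline boundary; defaults to the observed input range.
    intercept : bool
        Whether the basis carries its own intercept column.
    knot_placement : str, optional
        ``even`` (equally spaced values over the range, the default for the
        predictor space), ``quantiles`` (equally spaced quantiles), or
        ``loglag`` (equal intervals on the log-lag scale, the default for the
        lag space).
    """

    kind: str
    degree: Optional[int] = None
    df: Optional[int] = None
    knots: Optional[Tuple[float, ...]] = None
    boundary_knots: Optional[Tuple[float, float]] = None
    intercept: bool = False
    knot_placement: Optional[str] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.knot_placement is not None and self.knot_placement not in _PLACEMENTS:
            raise ValueError(f"unknown knot placement {self.knot_placement!r}")
        if self.kind == "polynomial":
            if self.degree is None or self.degree < 1:
                raise ValueError("polynomial basis requires degree >= 1")
        if self.knots is not None:
            kn = tuple(float(k) for k in self.knots)
            if len(kn) and np.any(np.diff(kn) <= 0):
                raise ValueError("knots must be strictly increasing")
            object.__setattr__(self, "knots", kn)
        if self.boundary_knots is not None:
            b = (float(self.boundary_knots[0]), float(self.boundary_knots[1]))
            if b[0] >= b[1]:
                raise ValueError("boundary_knots must be an increasing pair")
            if self.knots is not None and self.kind == "natural_cubic_spline":
                if any(k < b[0] or k > b[1] for k in self.knots):
                    raise ValueError("spline knots must lie within boundary_knots")
            object.__setattr__(self, "boundary_knots", b)
        if self.kind == "natural_cubic_spline" and self.df is None and self.knots is None:
            raise ValueError("natural_cubic_spline requires df or knots")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def linear(cls) -> "BasisSpec":
        return cls("linear")

    @classmethod
    def polynomial(cls, degree: int, intercept: bool = False) -> "BasisSpec":
        return cls("polynomial", degree=degree, intercept=intercept)

    @classmethod
    def natural_spline(
        cls,
        df: Optional[int] = None,
        knots: Optional[Sequence[float]] = None,
        boundary_knots: Optional[Tuple[float, float]] = None,
        intercept: bool = False,
        knot_placement: Optional[str] = None,
    ) -> "BasisSpec":
        return cls(
            "natural_cubic_spline",
            df=df,
            knots=None if knots is None else tuple(knots),
            boundary_knots=boundary_knots,
            intercept=intercept,
            knot_placement=knot_placement,
        )

    @classmethod
    def threshold(cls, knots: Sequence[float]) -> "BasisSpec":
        return cls("threshold", knots=tuple(knots))

    @classmethod
    def strata(cls, knots: Sequence[float], intercept: bool = False) -> "BasisSpec":
        return cls("strata", knots=tuple(knots), intercept=intercept)

    @classmethod
    def constant(cls) -> "BasisSpec":
        return cls("constant")

    @classmethod
    def identity(cls) -> "BasisSpec":
        return cls("identity")

    # -- resolution ---------------------------------------------------------
    def resolved(self, values, is_lag: bool = False) -> "BasisSpec":
        """Fill in data-dependent knots and boundary knots.

        For a df-specified natural cubic spline the internal knots are placed
        according to ``knot_placement``: equally spaced values over the range
        of ``values`` (default in the predictor space), equally spaced
        quantiles, or — for the lag space — at equal intervals on the log
        scale of lags via :func:`make_lag_knots`.
        """
        if self.kind != "natural_cubic_spline":
            return self
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("cannot resolve spline knots from all-missing values")
        lo, hi = float(v.min()), float(v.max())
        boundary = self.boundary_knots if self.boundary_knots is not None else (lo, hi)
        knots = self.knots
        if knots is None:
            n_internal = self.df - 1 - (1 if self.intercept else 0)
            if n_internal < 0:
                raise ValueError("df too small for natural_cubic_spline")
            placement = self.knot_placement or ("loglag" if is_lag else "even")
            if n_internal == 0:
                knots = ()
            elif placement == "even":
                knots = tuple(np.linspace(boundary[0], boundary[1], n_internal + 2)[1:-1])
            elif placement == "quantiles":
                probs = np.arange(1, n_internal + 1) / (n_internal + 1)
                knots = tuple(np.quantile(v, probs))
            elif placement == "loglag":
                knots = tuple(make_lag_knots(int(round(hi)), n_internal))
            else:  # pragma: no cover - guarded in __post_init__
                raise ValueError(placement)
        return replace(self, knots=knots, boundary_knots=boundary)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {"kind": self.kind, "intercept": self.intercept}
        if self.degree is not None:
            d["degree"] = self.degree
        if self.df is not None:
            d["df"] = self.df
        if self.knots is not None:
            d["knots"] = list(self.knots)
        if self.boundary_knots is not None:
            d["boundary"] = list(self.boundary_knots)
        if self.knot_placement is not None:
            d["knot_placement"] = self.knot_placement
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            kind=d["kind"],
            degree=d.get("degree"),
            df=d.get("df"),
            knots=None if d.get("knots") is None else tuple(d["knots"]),
            boundary_knots=None if d.get("boundary") is None else tuple(d["boundary"]),
            intercept=bool(d.get("intercept", False)),
            knot_placement=d.get("knot_placement"),
        )


@dataclass
class BasisMatrix:
    """An evaluated basis: one row per input point, one column per variable."""

    values: np.ndarray
    spec: BasisSpec
    input_range: Tuple[float, float]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


def make_lag_knots(L: int, n_knots: int) -> np.ndarray:
    """Knots at equal intervals on the logarithmic scale of lags.

    The transform is ``log(lag)`` on lags >= 1, with lag 0 always inside the
    first interval: knot *i* is ``exp(i/(n_knots+1) * log(L))``, i.e. equally
    spaced between log(1) = 0 and log(L).  Knots come out denser at short
    lags, where most of the structure of a distributed lag curve lives.
    """
    if L < 1:
        raise ValueError("maximum lag L must be >= 1")
    if n_knots < 1 or n_knots >= L:
        raise ValueError("n_knots must satisfy 1 <= n_knots < L")
    frac = np.arange(1, n_knots + 1) / (n_knots + 1)
    return np.exp(frac * np.log(L))


def basis_dimension(spec: BasisSpec, values=None) -> int:
    """Number of columns the basis produces (v_x or v_l).

    ``identity`` depends on the inputs (one column per distinct integer
    value), so ``values`` must be supplied for that kind.
    """
    i = 1 if spec.intercept else 0
    if spec.kind == "linear":
        return 1 + i
    if spec.kind == "constant":
        return 1
    if spec.kind == "polynomial":
        return spec.degree + i
    if spec.kind == "threshold":
        if spec.knots is None:
            raise ValueError("threshold basis requires knots")
        return len(spec.knots) + i
    if spec.kind == "strata":
        if spec.knots is None:
            raise ValueError("strata basis requires knots")
        # knots cut the axis into len(knots)+1 intervals
        return len(spec.knots) + i
    if spec.kind == "natural_cubic_spline":
        if spec.knots is not None:
            return len(spec.knots) + 1 + i
        if spec.df is not None:
            return spec.df
        raise ValueError("natural_cubic_spline requires df or knots")
    if spec.kind == "identity":
        if values is None:
            raise ValueError("identity basis dimension depends on the input values")
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        return len(np.unique(v))
    raise ValueError(f"unknown basis kind {spec.kind!r}")  # pragma: no cover


def _ns_design(x: np.ndarray, knots, boundary, intercept: bool) -> np.ndarray:
    """Natural cubic spline design, splines::ns style.

    Cubic B-spline basis on the augmented knot sequence; the intercept column
    is dropped unless requested; the two second-derivative-at-boundary
    constraints are removed by projecting onto the orthogonal complement of
    the constraint rows (QR).  Outside the boundary knots the basis continues
    linearly (value + first derivative at the boundary).
    """
    lo, hi = boundary
    t = np.sort(np.concatenate([np.repeat([lo, hi], 4), np.asarray(knots, float)]))
    nb = len(t) - 4
    spl = BSpline(t, np.eye(nb), 3, extrapolate=False)

    B = np.full((x.size, nb), np.nan)
    inside = (x >= lo) & (x <= hi)
    if inside.any():
        B[inside] = spl(x[inside])
    d1 = spl.derivative(1)
    below, above = x < lo, x > hi
    if below.any():
        B[below] = spl(np.array([lo])) + (x[below] - lo)[:, None] * d1(np.array([lo]))
    if above.any():
        B[above] = spl(np.array([hi])) + (x[above] - hi)[:, None] * d1(np.array([hi]))

    const = spl.derivative(2)(np.array([lo, hi]))
    if not intercept:
        B = B[:, 1:]
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    out = B @ q[:, 2:]
    out[~np.isfinite(x)] = np.nan
    return out


def evaluate_basis(spec: BasisSpec, values, warn_range: bool = True) -> BasisMatrix:
    """Apply the basis functions to a vector of values.

    Missing (NaN) inputs propagate to all-NaN rows; downstream fitting drops
    incomplete rows.  Knots outside the observed range raise a warning, not
    an error (``warn_range=False`` silences this, e.g. when re-evaluating an
    already-resolved basis on a prediction grid).
    """
    x = np.asarray(values, dtype=float).ravel()
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        raise ValueError("all input values are missing")
    rng = (float(finite.min()), float(finite.max()))
    spec = spec.resolved(finite) if spec.kind == "natural_cubic_spline" else spec

    if (
        warn_range
        and spec.knots is not None
        and spec.kind in ("threshold", "strata", "natural_cubic_spline")
    ):
        if any(k < rng[0] or k > rng[1] for k in spec.knots):
            warnings.warn(
                f"{spec.kind} knots outside the data range {rng}", UserWarning, stacklevel=2
            )

    nanrow = np.where(np.isfinite(x), 0.0, np.nan)[:, None]

    if spec.kind == "linear":
        cols = [x]
    elif spec.kind == "constant":
        return BasisMatrix(np.ones((x.size, 1)) + nanrow, spec, rng)
    elif spec.kind == "polynomial":
        cols = [x**p for p in range(1, spec.degree + 1)]
    elif spec.kind == "threshold":
        if spec.knots is None:
            raise ValueError("threshold basis requires knots")
        cols = [np.maximum(x - k, 0.0) for k in spec.knots]
    elif spec.kind == "strata":
        if spec.knots is None:
            raise ValueError("strata basis requires knots")
        edges = [-np.inf, *spec.knots, np.inf]
        ind = [
            ((x >= edges[i]) & (x < edges[i + 1])).astype(float)
            for i in range(len(edges) - 1)
        ]
        cols = ind if spec.intercept else ind[1:]
        m = np.column_stack(cols) + nanrow
        return BasisMatrix(m, spec, rng)
    elif spec.kind == "natural_cubic_spline":
        m = _ns_design(x, spec.knots, spec.boundary_knots, spec.intercept)
        return BasisMatrix(m, spec, rng)
    elif spec.kind == "identity":
        if not np.allclose(finite, np.round(finite)):
            raise ValueError("identity basis requires integer inputs (the lag vector)")
        levels = np.unique(np.round(finite)).astype(int)
        m = np.column_stack([(np.round(x) == lv).astype(float) for lv in levels])
        return BasisMatrix(m + nanrow, spec, rng)
    else:  # pragma: no cover
        raise ValueError(spec.kind)

    if spec.intercept and spec.kind in ("linear", "polynomial", "threshold"):
        cols = [np.ones_like(x), *cols]
    m = np.column_stack(cols) + nanrow
    expected = basis_dimension(spec, values=x)
    assert m.shape[1] == expected, (m.shape, expected)
    return BasisMatrix(m, spec, rng)
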