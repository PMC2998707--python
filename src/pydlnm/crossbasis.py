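"""Lagged-exposure structure and the cross-basis design matrix.

The lag matrix ``Q`` stacks the exposure history of each day: entry (t, l)
is the exposure l days before day t, undefined (NaN) for the first L days.
The cross-basis matrix ``W`` combines a predictor-space basis Z (applied to
the exposure values) with a lag-space basis C (applied to the lag vector
0..L):

    W[t, (j, k)] = sum_{l=0}^{L}  Z[t - l, j] * C[l, k]

i.e. each predictor-basis column is lagged and the lag-basis coefficients
weight the contributions along the lag dimension.  The construction is
symmetric: lagging the transformed exposures or transforming the lagged
exposures gives the same W.

Columns are ordered predictor-basis-major: column index = j * v_l + k, with
names ``cb_v{j+1}_l{k+1}``; the same ordering must be (and is) used when
building prediction contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .basis import BasisSpec, evaluate_basis

__all__ = ["LagMatrix", "CrossBasis", "build_lag_matrix", "build_crossbasis"]


@dataclass
class LagMatrix:
    """n x (L+1) matrix of lagged exposures; column l holds x shifted by l."""

    values: np.ndarray
    L: int

    @property
    def lag_vector(self) -> np.ndarray:
        return np.arange(self.L + 1)


def _check_time_index(x) -> np.ndarray:
    if isinstance(x, pd.Series):
        idx = x.index
        if idx.has_duplicates:
            raise ValueError("duplicated time index in exposure series")
        if not idx.is_monotonic_increasing:
            raise ValueError("exposure series must be ordered in time")
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float).ravel()


def build_lag_matrix(x, L: int) -> LagMatrix:
    """Build the exposure-history matrix Q for maximum lag L.

    Column 0 is the series itself; entries reaching before the start of the
    series are missing, so the first L rows are incomplete.
    """
    xv = _check_time_index(x)
    n = xv.size
    if L < 0:
        raise ValueError("maximum lag L must be >= 0")
    if L >= n:
        raise ValueError(f"maximum lag L={L} leaves no complete row for n={n}")
    Q = np.full((n, L + 1), np.nan)
    for lag in range(L + 1):
        Q[lag:, lag] = xv[: n - lag]
    return LagMatrix(Q, L)


@dataclass
class CrossBasis:
    """Cross-basis design matrix W plus the recipe to rebuild it.

    Attributes
    ----------
    W : ndarray, shape (n, v_x * v_l)
        The cross-basis design; rows 0..L-1 are NaN (incomplete history).
    var_spec, lag_spec : BasisSpec
        The resolved basis specs (knots and boundaries filled in), so the
        transforms can be reconstructed exactly at prediction time.
    L : int
        Maximum lag.
    exposure_range : (float, float)
        Observed range of the exposure series.
    column_order : list of (j, k)
        Mapping from column index to (predictor-basis column j, lag-basis
        column k); index = j * v_l + k.
    """

    W: np.ndarray
    var_spec: BasisSpec
    lag_spec: BasisSpec
    L: int
    exposure_range: Tuple[float, float]
    column_order: List[Tuple[int, int]]

    @property
    def v_x(self) -> int:
        return 1 + max(j for j, _ in self.column_order)

    @property
    def v_l(self) -> int:
        return 1 + max(k for _, k in self.column_order)

    @property
    def colnames(self) -> List[str]:
        return [f"cb_v{j + 1}_l{k + 1}" for j, k in self.column_order]

    def lag_basis_matrix(self) -> np.ndarray:
        """The (L+1) x v_l matrix C, evaluated on the lag vector."""
        return evaluate_basis(self.lag_spec, np.arange(self.L + 1), warn_range=False).values

    def var_basis_matrix(self, values) -> np.ndarray:
        """The predictor basis evaluated at arbitrary values (prediction)."""
        return evaluate_basis(self.var_spec, values, warn_range=False).values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, columns=self.colnames)

    # -- serialization ------------------------------------------------------
    def recipe(self) -> dict:
        return {
            "var_spec": self.var_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "max_lag": self.L,
            "exposure_range": list(self.exposure_range),
            "column_order": "var-basis-major: index = j * v_l + k",
        }

    @classmethod
    def from_recipe(cls, recipe: dict, x) -> "CrossBasis":
        return build_crossbasis(
            x,
            BasisSpec.from_dict(recipe["var_spec"]),
            BasisSpec.from_dict(recipe["lag_spec"]),
            recipe["max_lag"],
        )

    @classmethod
    def for_prediction(cls, recipe: dict) -> "CrossBasis":
        """Rebuild the transforms (no design rows) from a serialized recipe.

        Prediction needs only the resolved basis specs, the maximum lag and
        the exposure range, so a fit exported to the interchange format can
        be predicted from without re-reading the original series.
        """
        from .basis import basis_dimension

        var_spec = BasisSpec.from_dict(recipe["var_spec"])
        lag_spec = BasisSpec.from_dict(recipe["lag_spec"])
        L = int(recipe["max_lag"])
        v_x = basis_dimension(var_spec)
        v_l = basis_dimension(lag_spec, values=np.arange(L + 1))
        order = [(j, k) for j in range(v_x) for k in range(v_l)]
        rng = tuple(recipe["exposure_range"])
        return cls(np.empty((0, v_x * v_l)), var_spec, lag_spec, L, rng, order)


def build_crossbasis(x, var_spec: BasisSpec, lag_spec: BasisSpec, L: int) -> CrossBasis:
    """Build the n x (v_x * v_l) cross-basis matrix from an exposure series.

    Missingness propagates: any missing lagged exposure makes the whole W row
    missing, so for a complete series exactly the first L rows are NaN.
    """
    xv = _check_time_index(x)
    if not np.isfinite(xv).any():
        raise ValueError("exposure series is all-missing")
    if L < 0:
        raise ValueError("maximum lag L must be >= 0")
    if L >= xv.size:
        raise ValueError(f"maximum lag L={L} leaves no complete row for n={xv.size}")

    finite = xv[np.isfinite(xv)]
    var_spec = var_spec.resolved(finite)
    lag_vector = np.arange(L + 1)
    lag_spec = lag_spec.resolved(lag_vector, is_lag=True)

    Z = evaluate_basis(var_spec, xv).values  # n x v_x
    C = evaluate_basis(lag_spec, lag_vector).values  # (L+1) x v_l
    if C.shape[0] != L + 1:
        raise ValueError("lag basis evaluated on 0..L must have L+1 rows")

    n, v_x = Z.shape
    v_l = C.shape[1]
    W = np.empty((n, v_x * v_l))
    for j in range(v_x):
        Qj = build_lag_matrix(Z[:, j], L).values  # n x (L+1), NaN-propagating
        W[:, j * v_l : (j + 1) * v_l] = Qj @ C
    order = [(j, k) for j in range(v_x) for k in range(v_l)]
    rng = (float(finite.min()), float(finite.max()))
    return CrossBasis(W, var_spec, lag_spec, L, rng, order)
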