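"""Prediction of lag-specific and overall effects with uncertainty.

Effects are linear contrasts of the fitted cross-basis coefficients.  For a
prediction exposure x_p and lag l the contrast vector is built from the
predictor basis difference (z_p - z_ref) and row l of the lag basis C,
ordered exactly as the cross-basis columns; the effect is a' eta_hat and its
variance a' V a.  Overall (lag-summed) effects use the summed contrast
a_tot = sum_l a(x_p, l), whose variance picks up all the covariances between
lag contributions — on a correlated fit this differs from naively adding
variances lag by lag.

All effects are reported relative to a reference exposure (the centering
value); on the log link, exponentiating gives relative risks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .crossbasis import CrossBasis
from .model import FittedCrossBasis

__all__ = ["PredictionGrid", "predict_grid", "to_risk_scale", "slice_grid"]


@dataclass
class PredictionGrid:
    """Effects and standard errors over (exposure, lag), plus lag-summed totals.

    ``E`` and ``E_sd`` are m x (L+1) matrices on the linear-predictor scale;
    ``e_tot`` / ``e_tot_sd`` are the overall (lag-summed) effects per
    exposure value.  The row at ``exposure == reference`` is identically 0.
    """

    exposures: np.ndarray
    lags: np.ndarray
    E: np.ndarray
    E_sd: np.ndarray
    e_tot: np.ndarray
    e_tot_sd: np.ndarray
    reference: Optional[float]
    link: str = "log"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (exposure, lag) plus 'overall' rows."""
        rows = []
        for i, xp in enumerate(self.exposures):
            for j, lag in enumerate(self.lags):
                rows.append((xp, str(int(lag)), self.E[i, j], self.E_sd[i, j]))
            rows.append((xp, "overall", self.e_tot[i], self.e_tot_sd[i]))
        return pd.DataFrame(rows, columns=["exposure", "lag", "effect", "sd"])


def predict_grid(
    fit: FittedCrossBasis,
    cb: CrossBasis,
    exposures=None,
    reference: Optional[float] = None,
    centered: bool = True,
) -> PredictionGrid:
    """Compute the effect grid E, its standard errors and the overall effects.

    Parameters
    ----------
    exposures : array-like, optional
        Prediction exposure values; defaults to 50 equally spaced values over
        the observed exposure range (the reference is appended if absent).
    reference : float
        The exposure all effects are contrasted against.  Required when
        ``centered`` (the default); RRs are only interpretable as contrasts.
    centered : bool
        If False, report uncentered predictions z_p' eta (meaningful only for
        bases through the origin, e.g. linear or threshold).
    """
    lo, hi = cb.exposure_range
    if exposures is None:
        exposures = np.linspace(lo, hi, 50)
        if centered and reference is not None and not np.any(np.isclose(exposures, reference)):
            exposures = np.sort(np.append(exposures, reference))
    exposures = np.asarray(exposures, dtype=float).ravel()
    if centered and reference is None:
        raise ValueError("centered prediction requires a reference exposure")
    out_of_range = (exposures < lo) | (exposures > hi)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} prediction exposure(s) outside the observed "
            f"range [{lo:.4g}, {hi:.4g}]; splines extrapolate linearly",
            UserWarning,
            stacklevel=2,
        )

    v_l = cb.v_l
    expected_cols = cb.v_x * v_l
    if fit.eta.size != expected_cols:
        raise ValueError(
            f"fit has {fit.eta.size} coefficients but cross-basis has {expected_cols} columns"
        )
    if list(fit.names) and list(fit.names) != cb.colnames:
        raise ValueError("fit/crossbasis column-order mismatch")

    V = fit.vcov
    eigmin = float(np.linalg.eigvalsh((V + V.T) / 2.0).min())
    if eigmin < -1e-8 * max(1.0, float(np.abs(V).max())):
        raise ValueError(
            f"vcov is not positive semidefinite (min eigenvalue {eigmin:.3e}); "
            "the fit may be rank-deficient or corrupted"
        )

    # predictor-basis contrasts: the transformed exposure is repeated across
    # lags (effects at each lag for a given exposure, not a temporal sequence)
    Zp = cb.var_basis_matrix(exposures)  # m x v_x
    if centered:
        Zref = cb.var_basis_matrix(np.array([reference]))  # 1 x v_x
        D = Zp - Zref
    else:
        D = Zp
    C = cb.lag_basis_matrix()  # (L+1) x v_l
    m, v_x = D.shape
    L1 = C.shape[0]

    H = fit.eta.reshape(v_x, v_l)  # column order j * v_l + k
    E = D @ H @ C.T  # m x (L+1)

    # contrast tensor A[p, l, :] = outer(D[p], C[l]).ravel()
    A = np.einsum("pj,lk->pljk", D, C).reshape(m, L1, v_x * v_l)
    E_sd = np.sqrt(np.maximum(np.einsum("plc,cd,pld->pl", A, V, A), 0.0))
    A_tot = A.sum(axis=1)  # m x (v_x * v_l)
    e_tot = A_tot @ fit.eta
    e_tot_sd = np.sqrt(np.maximum(np.einsum("pc,cd,pd->p", A_tot, V, A_tot), 0.0))

    return PredictionGrid(
        exposures=exposures,
        lags=np.arange(L1),
        E=E,
        E_sd=E_sd,
        e_tot=e_tot,
        e_tot_sd=e_tot_sd,
        reference=reference if centered else None,
        link=fit.link,
    )


def to_risk_scale(grid: PredictionGrid, level: float = 0.95) -> pd.DataFrame:
    """Exponentiate a log-link grid into relative risks with Wald CIs.

    Returns one row per (exposure, lag) and per (exposure, 'overall'), with
    columns rr, rr_low, rr_high; the interval is exp(effect +/- z * sd) with
    z the standard-normal quantile for the requested coverage.
    """
    if grid.link != "log":
        raise ValueError(
            "risk-scale output requires a log link; report identity-scale effects instead"
        )
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    df = grid.to_frame()
    df["rr"] = np.exp(df["effect"])
    df["rr_low"] = np.exp(df["effect"] - z * df["sd"])
    df["rr_high"] = np.exp(df["effect"] + z * df["sd"])
    return df


def slice_grid(
    grid: PredictionGrid,
    lag: Optional[int] = None,
    exposure: Optional[float] = None,
) -> pd.DataFrame:
    """Extract an effect curve by lag (effects across exposures at a fixed
    lag) or by exposure (the distributed lag curve at a fixed exposure).

    The requested value must be on the grid; no interpolation is done.
    """
    if (lag is None) == (exposure is None):
        raise ValueError("specify exactly one of lag or exposure")
    if lag is not None:
        idx = np.where(grid.lags == lag)[0]
        if idx.size == 0:
            raise ValueError(f"lag {lag} is not on the grid")
        j = int(idx[0])
        return pd.DataFrame(
            {"exposure": grid.exposures, "effect": grid.E[:, j], "sd": grid.E_sd[:, j]}
        )
    idx = np.where(np.isclose(grid.exposures, exposure))[0]
    if idx.size == 0:
        raise ValueError(f"exposure {exposure} is not on the grid")
    i = int(idx[0])
    return pd.DataFrame({"lag": grid.lags, "effect": grid.E[i], "sd": grid.E_sd[i]})
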