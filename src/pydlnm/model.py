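"""Fitting interface: quasi-Poisson GLM bridge, QAIC/QBIC, Model/Results.

Estimating a distributed lag non-linear model is just a generalized linear
model fit once the cross-basis columns are in the design matrix, so this
module delegates estimation to :mod:`statsmodels` and concentrates on the
bridge: pulling the cross-basis coefficient block and its covariance out of
a fit (:func:`extract_fit`), the overdispersion-adjusted information
criteria (:func:`qaic`, :func:`qbic`), and a convenient Model/Results pair
(:class:`DLNM` / :class:`DLNMResults`) that wires the pieces together.

The criteria are the quasi-likelihood variants

    QAIC = -2*L + 2 * phi * k          QBIC = -2*L + log(n) * phi * k

with L the Poisson log-likelihood evaluated at the fitted mean, phi the
Pearson-based dispersion estimate, k the number of mean-model parameters
(cross-basis plus confounders) and n the number of observations used.  With
phi = 1 they reduce to ordinary AIC/BIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .basis import BasisSpec
from .crossbasis import CrossBasis, build_crossbasis

__all__ = [
    "FittedCrossBasis",
    "extract_fit",
    "qaic",
    "qbic",
    "DLNM",
    "DLNMResults",
    "write_fit_interchange",
    "read_fit_interchange",
]


@dataclass
class FittedCrossBasis:
    """Cross-basis coefficients and covariance pulled out of a GLM fit.

    ``eta`` and ``vcov`` are ordered per ``CrossBasis.column_order``
    (predictor-basis-major); ``n_params`` counts *all* mean-model parameters,
    not just the cross-basis block, so whole models are compared by the
    information criteria.
    """

    eta: np.ndarray
    vcov: np.ndarray
    dispersion: float
    loglik: float
    n_obs: int
    n_params: int
    link: str = "log"
    names: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float).ravel()
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.vcov.shape != (self.eta.size, self.eta.size):
            raise ValueError("vcov dimension does not match coefficient vector")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise ValueError("vcov must be symmetric")
        if np.any(np.diag(self.vcov) < -1e-12):
            raise ValueError("vcov has negative diagonal entries")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_params < self.eta.size:
            raise ValueError("n_params must count at least the cross-basis block")


def extract_fit(results, crossbasis: CrossBasis) -> FittedCrossBasis:
    """Extract the cross-basis block from a fitted GLM.

    ``results`` may be a statsmodels ``GLMResults`` whose design used the
    cross-basis column names, or any object with ``params`` (named Series),
    ``cov_params()`` (named DataFrame), ``scale``, ``llf`` and ``nobs``.
    Coefficients are re-ordered by name, so a permuted coefficient table
    yields an identical result.
    """
    params = pd.Series(results.params)
    cov = pd.DataFrame(results.cov_params())
    names = crossbasis.colnames
    if params.index.has_duplicates:
        raise ValueError("coefficient names are not unique")
    missing = [c for c in names if c not in params.index]
    if missing:
        raise ValueError(f"cross-basis columns missing from the fit: {missing}")
    eta = params.loc[names].to_numpy()
    vcov = cov.loc[names, names].to_numpy()
    # quasi-likelihood convention: report the Poisson log-likelihood at the
    # fitted mean (statsmodels' llf under scale='X2' is divided by phi)
    if hasattr(results, "model") and hasattr(results, "mu"):
        loglik = float(results.model.family.loglike(results.model.endog, results.mu, scale=1.0))
    else:
        loglik = float(results.llf)
    return FittedCrossBasis(
        eta=eta,
        vcov=vcov,
        dispersion=float(results.scale),
        loglik=loglik,
        n_obs=int(results.nobs),
        n_params=int(len(params)),
        link="log",
        names=names,
    )


def qaic(fit: FittedCrossBasis) -> float:
    """Quasi-AIC: -2*loglik + 2 * dispersion * n_params."""
    if fit.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    return -2.0 * fit.loglik + 2.0 * fit.dispersion * fit.n_params


def qbic(fit: FittedCrossBasis) -> float:
    """Quasi-BIC: -2*loglik + log(n_obs) * dispersion * n_params."""
    if fit.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    return -2.0 * fit.loglik + np.log(fit.n_obs) * fit.dispersion * fit.n_params


# ---------------------------------------------------------------------------
# interchange files: named coefficients (CSV), covariance (CSV), scalars (JSON)
# ---------------------------------------------------------------------------

def write_fit_interchange(fit: FittedCrossBasis, directory) -> None:
    """Write a fit to the documented interchange format.

    ``coefficients.csv`` (name, estimate), ``vcov.csv`` (named square
    matrix), ``scalars.json`` (dispersion, loglik, n_obs, n_params, link).
    Fits from any environment can be imported this way.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = list(fit.names) or [f"eta{i}" for i in range(fit.eta.size)]
    pd.Series(fit.eta, index=names, name="estimate").rename_axis("name").to_csv(
        directory / "coefficients.csv"
    )
    pd.DataFrame(fit.vcov, index=names, columns=names).to_csv(directory / "vcov.csv")
    scalars = {
        "dispersion": fit.dispersion,
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "n_params": fit.n_params,
        "link": fit.link,
    }
    (directory / "scalars.json").write_text(json.dumps(scalars, indent=2))


def read_fit_interchange(directory) -> FittedCrossBasis:
    directory = Path(directory)
    coefs = pd.read_csv(directory / "coefficients.csv", index_col=0)["estimate"]
    vcov = pd.read_csv(directory / "vcov.csv", index_col=0)
    scalars = json.loads((directory / "scalars.json").read_text())
    return FittedCrossBasis(
        eta=coefs.to_numpy(),
        vcov=vcov.loc[coefs.index, coefs.index].to_numpy(),
        dispersion=scalars["dispersion"],
        loglik=scalars["loglik"],
        n_obs=scalars["n_obs"],
        n_params=scalars["n_params"],
        link=scalars.get("link", "log"),
        names=list(coefs.index),
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DLNM:
    """Distributed lag non-linear model for daily count time series.

    Parameters
    ----------
    endog : array-like
        Daily event counts.
    exposure : array-like
        Daily exposure series (same length, regular daily spacing assumed).
    var_spec, lag_spec : BasisSpec
        Bases for the predictor space and the lag space.
    max_lag : int
        Maximum lag L; the first L days are dropped from the fit (incomplete
        exposure history).
    confounders : DataFrame, optional
        Additional design columns (seasonality splines, day-of-week
        indicators, co-exposures) entered linearly alongside the cross-basis.
    family : {"quasipoisson", "poisson"}
        ``quasipoisson`` (default) estimates the dispersion from the Pearson
        statistic and scales the covariance accordingly.

    Examples
    --------
    >>> model = DLNM(counts, temp, BasisSpec.natural_spline(df=5),
    ...              BasisSpec.natural_spline(df=5), max_lag=30)
    >>> res = model.fit()
    >>> grid = res.predict_grid(reference=21.0)
    """

    def __init__(
        self,
        endog,
        exposure,
        var_spec: BasisSpec,
        lag_spec: BasisSpec,
        max_lag: int,
        confounders: Optional[pd.DataFrame] = None,
        family: str = "quasipoisson",
    ):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exposure = np.asarray(exposure, dtype=float).ravel()
        if self.endog.size != self.exposure.size:
            raise ValueError("outcome and exposure series must have equal length")
        if family not in ("quasipoisson", "poisson"):
            raise ValueError("family must be 'quasipoisson' or 'poisson'")
        self.family = family
        self.crossbasis = build_crossbasis(self.exposure, var_spec, lag_spec, max_lag)
        self.max_lag = max_lag

        design = self.crossbasis.to_frame()
        if confounders is not None:
            confounders = pd.DataFrame(confounders).reset_index(drop=True)
            if confounders.shape[0] != self.endog.size:
                raise ValueError("confounder rows must match the series length")
            clash = set(confounders.columns) & set(design.columns)
            if clash:
                raise ValueError(f"confounder names collide with cross-basis: {clash}")
            design = pd.concat([design, confounders], axis=1)
        design.insert(0, "const", 1.0)
        self._design = design

        mask = design.notna().all(axis=1) & np.isfinite(self.endog)
        self._mask = mask.to_numpy()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        exposure: str,
        var_spec: BasisSpec,
        lag_spec: BasisSpec,
        max_lag: int,
        confounder_formula: Optional[str] = None,
        family: str = "quasipoisson",
    ) -> "DLNM":
        """Build a model from a tidy daily table.

        ``confounder_formula`` is a patsy formula evaluated against ``data``
        (e.g. ``"cr(time, df=7) + C(dow)"``); the resulting columns enter the
        design linearly.
        """
        conf = None
        if confounder_formula:
            # keep patsy's intercept during coding (so factors are treatment
            # coded), then drop it: the model supplies its own constant
            conf = patsy.dmatrix(
                confounder_formula, data, return_type="dataframe"
            ).reset_index(drop=True)
            conf = conf.drop(columns=[c for c in conf.columns if c == "Intercept"])
        return cls(
            data[outcome],
            data[exposure],
            var_spec,
            lag_spec,
            max_lag,
            confounders=conf,
            family=family,
        )

    @property
    def n_used(self) -> int:
        return int(self._mask.sum())

    def fit(self) -> "DLNMResults":
        y = self.endog[self._mask]
        X = self._design.loc[self._mask]
        glm = sm.GLM(y, X, family=sm.families.Poisson())
        scale = "X2" if self.family == "quasipoisson" else 1.0
        res = glm.fit(scale=scale)
        extracted = extract_fit(res, self.crossbasis)
        return DLNMResults(self, res, extracted)


class DLNMResults:
    """Results of a fitted DLNM; prediction and criteria hang off this."""

    def __init__(self, model: DLNM, glm_results, extracted: FittedCrossBasis):
        self.model = model
        self.glm_results = glm_results
        self.fitted_crossbasis = extracted

    # -- statsmodels-flavoured accessors -----------------------------------
    @property
    def params(self) -> pd.Series:
        return self.glm_results.params

    @property
    def eta(self) -> np.ndarray:
        return self.fitted_crossbasis.eta

    @property
    def vcov(self) -> np.ndarray:
        return self.fitted_crossbasis.vcov

    @property
    def dispersion(self) -> float:
        return self.fitted_crossbasis.dispersion

    @property
    def llf(self) -> float:
        return self.fitted_crossbasis.loglik

    @property
    def qaic(self) -> float:
        return qaic(self.fitted_crossbasis)

    @property
    def qbic(self) -> float:
        return qbic(self.fitted_crossbasis)

    def predict_grid(self, exposures=None, reference=None, centered: bool = True):
        from .predict import predict_grid

        return predict_grid(
            self.fitted_crossbasis,
            self.model.crossbasis,
            exposures=exposures,
            reference=reference,
            centered=centered,
        )

    def summary(self) -> str:
        cb = self.model.crossbasis
        f = self.fitted_crossbasis
        lines = [
            "Distributed lag non-linear model (quasi-Poisson GLM)",
            "=" * 56,
            f"Observations used:        {f.n_obs}  (of {self.model.endog.size}, "
            f"first {cb.L} lag-incomplete days dropped)",
            f"Cross-basis dimension:    {cb.v_x} x {cb.v_l} = {len(f.eta)} columns",
            f"Predictor basis:          {cb.var_spec.kind}"
            + (f", df={cb.var_spec.df}" if cb.var_spec.df else ""),
            f"Lag basis:                {cb.lag_spec.kind}"
            + (f", df={cb.lag_spec.df}" if cb.lag_spec.df else "")
            + f", max lag {cb.L}",
            f"Total mean parameters:    {f.n_params}",
            f"Dispersion (Pearson):     {f.dispersion:.4f}",
            f"Log-likelihood:           {f.loglik:.2f}",
            f"QAIC:                     {self.qaic:.2f}",
            f"QBIC:                     {self.qbic:.2f}",
        ]
        return "\n".join(lines)
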