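"""Synthetic overdispersed count series with a known exposure-lag surface.

The generator emulates the data a temperature-mortality time series study
works with: a temperature-like exposure (seasonal cycle plus AR(1) noise),
a smooth seasonal baseline for the log event rate, and a known bi-dimensional
surface f(x, l) giving the log-rate contribution of exposure x at lag l.
Because the truth is known, the full pipeline (basis -> cross-basis -> GLM
fit -> prediction) can be validated end to end without external data.

Surfaces are stored as contrasts: f(reference, l) = 0 for all lags, so the
fitted centered effects estimate f directly.  Overdispersion is generated by
a gamma-Poisson (negative binomial) mixture parameterized to V(Y) = phi * mu
— quasi-Poisson defines no generative law, and this is the standard stand-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "ExposureProcess",
    "Baseline",
    "SimConfig",
    "SURFACES",
    "make_surface",
    "simulate_exposure",
    "simulate_counts",
    "simulate_dataset",
    "true_contrast",
    "write_dataset",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ExposureProcess:
    """Temperature-like daily process: seasonal cosine plus AR(1) noise.

    ``sd`` is the stationary standard deviation of the noise component; the
    innovation variance is scaled by (1 - ar_coef^2) so changing the AR
    coefficient does not change the marginal spread.
    """

    mean: float = 12.0
    sd: float = 3.5
    seasonal_amp: float = 10.0
    ar_coef: float = 0.8

    def __post_init__(self):
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")


@dataclass(frozen=True)
class Baseline:
    """Log-scale baseline rate: intercept + seasonal cosine + linear trend."""

    intercept: float = np.log(50.0)
    seasonal_amp: float = 0.1
    trend: float = 0.0


def _ushape(x, ref, scale, strength):
    return strength * ((np.asarray(x, float) - ref) / scale) ** 2


def make_surface(name: str, reference: float = 20.0) -> Callable:
    """Named surface presets f(x, l), all zero at the reference exposure.

    ``null``              no exposure effect.
    ``linear_decay``      linear in x, exponentially decaying over lags.
    ``ushape_decay``      U-shaped in x (minimum at the reference),
                          exponentially decaying over lags.
    ``ushape_delayed_cold`` U-shaped with an immediate, fast-decaying heat arm
                          and a cold arm whose effect peaks a few days after
                          exposure — the qualitative temperature-mortality
                          pattern reported in this literature.
    """
    if name == "null":
        return lambda x, lag: np.zeros(np.broadcast(np.asarray(x), np.asarray(lag)).shape)
    if name == "linear_decay":
        return lambda x, lag: 0.004 * (np.asarray(x, float) - reference) * np.exp(
            -np.asarray(lag, float) / 3.0
        )
    if name == "ushape_decay":
        return lambda x, lag: _ushape(x, reference, 10.0, 0.08) * np.exp(
            -np.asarray(lag, float) / 3.0
        )
    if name == "ushape_delayed_cold":
        # lag kernels normalized to (approximately) unit sum over lags, so
        # the arm strengths below are overall log-RRs at the scale anchors:
        # ~1.25 overall RR at reference+12, ~1.30 at reference-28
        z_hot = 1.0 / (1.0 - np.exp(-0.5))  # sum of e^(-l/2)
        z_cold = (np.e / 3.0) * np.exp(-1 / 3.0) / (1.0 - np.exp(-1 / 3.0)) ** 2

        def f(x, lag):
            x = np.asarray(x, float)
            lag = np.asarray(lag, float)
            hot = np.where(x > reference, _ushape(x, reference, 12.0, 0.22), 0.0)
            cold = np.where(x < reference, _ushape(x, reference, 28.0, 0.26), 0.0)
            # heat: immediate and fast-decaying; cold: peaks around lag 3
            k_hot = np.exp(-lag / 2.0) / z_hot
            k_cold = (lag / 3.0) * np.exp(1.0 - lag / 3.0) / z_cold
            return hot * k_hot + cold * k_cold

        return f
    raise ValueError(f"unknown surface preset {name!r}")


SURFACES = ("null", "linear_decay", "ushape_decay", "ushape_delayed_cold")


@dataclass
class SimConfig:
    """Everything the generator needs; all randomness flows from ``seed``."""

    n_days: int = 5114
    surface: Union[str, Callable] = "ushape_decay"
    reference: float = 20.0
    max_lag: int = 30
    dispersion: float = 1.5
    exposure_process: ExposureProcess = field(default_factory=ExposureProcess)
    baseline: Baseline = field(default_factory=Baseline)
    seed: int = 0

    def __post_init__(self):
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1")
        if self.n_days <= self.max_lag:
            raise ValueError("n_days must exceed max_lag")

    def surface_fn(self) -> Callable:
        if callable(self.surface):
            return self.surface
        return make_surface(self.surface, self.reference)


def simulate_exposure(config: SimConfig) -> np.ndarray:
    """Daily exposure x_t = mean + seasonal cosine + stationary AR(1) noise."""
    p = config.exposure_process
    rng = np.random.default_rng([config.seed, 101])
    t = np.arange(config.n_days)
    seasonal = p.seasonal_amp * np.cos(2 * np.pi * t / DAYS_PER_YEAR)
    rho = p.ar_coef
    innov_sd = p.sd * np.sqrt(1.0 - rho**2)
    noise = np.empty(config.n_days)
    noise[0] = rng.normal(0.0, p.sd)  # stationary start
    e = rng.normal(0.0, innov_sd, size=config.n_days)
    for i in range(1, config.n_days):
        noise[i] = rho * noise[i - 1] + e[i]
    return p.mean + seasonal + noise


def _log_mu(config: SimConfig, exposure: np.ndarray) -> np.ndarray:
    n = exposure.size
    t = np.arange(n)
    b = config.baseline
    log_mu = b.intercept + b.seasonal_amp * np.cos(2 * np.pi * t / DAYS_PER_YEAR) + b.trend * t
    f = config.surface_fn()
    L = config.max_lag
    for lag in range(L + 1):
        contrib = f(exposure[: n - lag], lag)
        log_mu[lag:] += contrib
    return log_mu


def simulate_counts(config: SimConfig, exposure: np.ndarray) -> np.ndarray:
    """Draw daily counts with log mu_t = baseline(t) + sum_l f(x_{t-l}, l).

    The first ``max_lag`` days have incomplete exposure history (the sum runs
    over the available lags only); they are emitted but should be treated as
    burn-in, as :func:`simulate_dataset` flags them.

    phi = 1 draws Poisson counts; phi > 1 draws a gamma-Poisson mixture with
    V(Y) = phi * mu exactly.
    """
    exposure = np.asarray(exposure, dtype=float)
    if exposure.size != config.n_days:
        raise ValueError("exposure length must equal n_days")
    log_mu = _log_mu(config, exposure)
    if np.any(log_mu > 20):
        raise ValueError(
            "simulated log-rate exceeds 20 (count overflow); rescale the surface "
            "or baseline"
        )
    mu = np.exp(log_mu)
    rng = np.random.default_rng([config.seed, 202])
    phi = config.dispersion
    if phi == 1.0:
        return rng.poisson(mu).astype(np.int64)
    lam = rng.gamma(shape=mu / (phi - 1.0), scale=phi - 1.0)
    return rng.poisson(lam).astype(np.int64)


def simulate_dataset(config: SimConfig, start: str = "2000-01-01") -> pd.DataFrame:
    """Simulate the standard input table: date, count, exposure, burn_in."""
    exposure = simulate_exposure(config)
    counts = simulate_counts(config, exposure)
    dates = pd.date_range(start, periods=config.n_days, freq="D")
    burn_in = np.zeros(config.n_days, dtype=bool)
    burn_in[: config.max_lag] = True
    return pd.DataFrame(
        {"date": dates, "count": counts, "exposure": exposure, "burn_in": burn_in}
    )


def true_contrast(
    config: SimConfig, x_p: float, reference: Optional[float] = None
) -> Tuple[np.ndarray, float]:
    """Ground-truth lag curve f(x_p, l) - f(ref, l) and its lag-summed total."""
    ref = config.reference if reference is None else reference
    f = config.surface_fn()
    lags = np.arange(config.max_lag + 1)
    curve = np.asarray(f(np.full(lags.shape, float(x_p)), lags), dtype=float) - np.asarray(
        f(np.full(lags.shape, float(ref)), lags), dtype=float
    )
    return curve, float(curve.sum())


def write_dataset(config: SimConfig, directory, n_grid: int = 25) -> None:
    """Emit the input CSV plus a JSON of the true surface on a grid (oracle)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = simulate_dataset(config)
    df.assign(date=df["date"].dt.strftime("%Y-%m-%d")).to_csv(
        directory / "simulated.csv", index=False
    )
    f = config.surface_fn()
    xs = np.linspace(df["exposure"].min(), df["exposure"].max(), n_grid)
    lags = np.arange(config.max_lag + 1)
    X, Lg = np.meshgrid(xs, lags, indexing="ij")
    truth = {
        "reference": config.reference,
        "exposures": xs.tolist(),
        "lags": lags.tolist(),
        "surface": np.asarray(f(X, Lg), dtype=float).tolist(),
        "dispersion": config.dispersion,
        "seed": config.seed,
    }
    (directory / "truth.json").write_text(json.dumps(truth))
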