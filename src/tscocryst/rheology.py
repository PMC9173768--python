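"""Carreau shear-thinning viscosity and Arrhenius temperature scaling.

The granulated mixture behaves as a pseudoplastic (shear-thinning)
fluid.  The Carreau model bridges the low-shear Newtonian plateau mu0
and a high-shear power law:

    (mu - mu_inf) / (mu0 - mu_inf) = [1 + (lam * gdot)^alpha]^((n-1)/alpha)

with alpha conventionally 2.  Its asymptotes — mu = mu0 at low shear
and mu = mu0 (lam gdot)^(n-1) at high shear — intersect at
gdot = 1/lam.  The temperature dependence of the plateau is captured by
an Arrhenius law mu = A exp(E_R / T) and, around a reference
temperature T0, by its refined relative form
mu/mu0 = exp(E_R (1/T - 1/T0)).

Fitting shares a single (lam, n) across all temperatures with one mu0
per temperature, done in log-viscosity so that the decades of shear are
weighted evenly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, InsufficientData, MissingReference

__all__ = [
    "CarreauParams",
    "ArrheniusParams",
    "CarreauFit",
    "ArrheniusFit",
    "carreau_viscosity",
    "asymptote_intersection",
    "fit_carreau",
    "fit_arrhenius",
    "refined_arrhenius",
]


@dataclass(frozen=True)
class CarreauParams:
    """mu0, mu_inf (cP), time constant lam (inverse shear unit),
    power index n, sharpness alpha (default 2)."""

    mu0: float
    mu_inf: float = 0.0
    lam: float = 1.0
    n: float = 0.5
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.mu_inf < 0 or self.mu0 <= self.mu_inf:
            raise DomainError("require mu0 > mu_inf >= 0")
        if self.lam <= 0:
            raise DomainError("lam must be positive")
        if self.alpha <= 0:
            raise DomainError("alpha must be positive")


@dataclass(frozen=True)
class ArrheniusParams:
    """mu = A * exp(E_over_R / T); A in cP, E_over_R in K.

    T0 is the reference temperature of the refined relative form."""

    A: float
    E_over_R: float
    T0: float | None = None

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise DomainError("pre-exponential A must be positive")

    def mu0(self, T: float) -> float:
        if T <= 0:
            raise DomainError("T must be positive")
        return self.A * np.exp(self.E_over_R / T)


def carreau_viscosity(gamma_dot: float | np.ndarray, p: CarreauParams) -> float | np.ndarray:
    """Carreau viscosity at shear rate(s) gamma_dot >= 0."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise DomainError("shear rate must be >= 0")
    mu = p.mu_inf + (p.mu0 - p.mu_inf) * (1.0 + (p.lam * g) ** p.alpha) ** (
        (p.n - 1.0) / p.alpha
    )
    return float(mu) if np.isscalar(gamma_dot) else mu


def asymptote_intersection(p: CarreauParams) -> float:
    """Shear rate where the Newtonian plateau meets the power law: 1/lam."""
    return 1.0 / p.lam


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarreauFit:
    params: CarreauParams           # at the reference (lowest) temperature
    mu0_by_T: dict[float, float]
    r_squared: float                # on the fitted (log) scale
    converged: bool


@dataclass(frozen=True)
class ArrheniusFit:
    params: ArrheniusParams
    r_squared: float


def _as_table(data: pd.DataFrame) -> pd.DataFrame:
    required = {"shear_s-1", "viscosity_cP"}
    if not required.issubset(data.columns):
        raise InsufficientData(f"viscosity table needs columns {sorted(required)}")
    table = data.copy()
    if "T_K" not in table.columns:
        table["T_K"] = np.nan
    return table


def fit_carreau(
    data: pd.DataFrame,
    fix_alpha: float = 2.0,
    mu_inf: float = 0.0,
) -> CarreauFit:
    """Fit (lam, n) shared across temperatures, one mu0 per temperature.

    Nonlinear least squares on ln(mu) with alpha fixed; mu_inf defaults
    to 0 (not identifiable unless the data reach the high-shear
    plateau).  Initialization is a deterministic multi-start over
    candidate lam values spanning the reciprocal shear-rate range of
    the data; the best final cost wins, so the result depends only on
    the data.
    """
    table = _as_table(data)
    g = table["shear_s-1"].to_numpy(float)
    mu = table["viscosity_cP"].to_numpy(float)
    if np.any(g <= 0) or np.any(mu <= 0):
        raise DomainError("shear rates and viscosities must be positive")
    if len(table) < 5:
        raise InsufficientData("need at least 5 data points")
    if np.log10(g.max() / g.min()) < 2:
        raise InsufficientData("data must span at least 2 decades of shear")

    temps = sorted(set(table["T_K"].fillna(0.0)))
    t_index = {T: k for k, T in enumerate(temps)}
    rows_T = table["T_K"].fillna(0.0).map(t_index).to_numpy(int)
    log_mu = np.log(mu)

    log_g = np.log(g)

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_lam, n = theta[0], theta[1]
        log_mu0 = theta[2:]
        # log(1 + (lam g)^alpha) computed as logaddexp for overflow safety
        z = fix_alpha * (log_lam + log_g)
        log_shape = ((n - 1.0) / fix_alpha) * np.logaddexp(0.0, z)
        if mu_inf == 0.0:
            return log_mu0[rows_T] + log_shape - log_mu
        model_mu = mu_inf + (np.exp(log_mu0[rows_T]) - mu_inf) * np.exp(log_shape)
        return np.log(model_mu) - log_mu

    # per-temperature mu0 init: largest viscosity observed at that T
    mu0_init = np.array(
        [np.log(mu[rows_T == k].max()) for k in range(len(temps))]
    )
    lam_candidates = np.unique(
        np.concatenate([1.0 / g, [np.sqrt(1.0 / (g.max() * g.min()))]])
    )
    best = None
    for lam0 in lam_candidates:
        x0 = np.concatenate([[np.log(lam0), -0.3], mu0_init])
        sol = optimize.least_squares(
            residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
            max_nfev=20000,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    log_lam, n = best.x[0], best.x[1]
    mu0_by_T = {
        float(T): float(np.exp(best.x[2 + k])) for T, k in t_index.items()
    }
    ref_T = temps[0]
    params = CarreauParams(
        mu0=mu0_by_T[float(ref_T)],
        mu_inf=mu_inf,
        lam=float(np.exp(log_lam)),
        n=float(n),
        alpha=fix_alpha,
    )
    res = residuals(best.x)
    ss_res = float(res @ res)
    ss_tot = float(((log_mu - log_mu.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CarreauFit(
        params=params, mu0_by_T=mu0_by_T, r_squared=r2, converged=bool(best.success)
    )


def fit_arrhenius(data: pd.DataFrame | Sequence[tuple[float, float]]) -> ArrheniusFit:
    """Linear regression of ln(mu) on 1/T: A = exp(intercept), E/R = slope."""
    if isinstance(data, pd.DataFrame):
        T = data["T_K"].to_numpy(float)
        mu = data["viscosity_cP"].to_numpy(float)
    else:
        arr = np.asarray(list(data), float)
        T, mu = arr[:, 0], arr[:, 1]
    if np.any(T <= 0) or np.any(mu <= 0):
        raise DomainError("temperatures and viscosities must be positive")
    if np.unique(T).size < 2:
        raise InsufficientData("need at least 2 distinct temperatures")
    fit = stats.linregress(1.0 / T, np.log(mu))
    r2 = float(fit.rvalue**2)
    return ArrheniusFit(
        params=ArrheniusParams(A=float(np.exp(fit.intercept)), E_over_R=float(fit.slope)),
        r_squared=r2,
    )


def refined_arrhenius(T: float, p: ArrheniusParams, mu0: float) -> float:
    """Relative Arrhenius form: mu = mu0 * exp(E_R * (1/T - 1/T0))."""
    if p.T0 is None:
        raise MissingReference("refined Arrhenius form needs a reference T0")
    if T <= 0:
        raise DomainError("T must be positive")
    return float(mu0 * np.exp(p.E_over_R * (1.0 / T - 1.0 / p.T0)))
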