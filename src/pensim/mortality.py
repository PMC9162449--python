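"""Age-sex mortality: Lee-Carter fitting, time-index forecasting, old-age
closure, and conversion from central rates to death probabilities.

The Lee-Carter model is the log-bilinear decomposition

    ln m_{x,t} = alpha_x + beta_x * k_t + eps_{x,t}

with the usual identifiability normalization sum(beta) = 1, sum(k) = 0.
``alpha`` is the time-averaged log mortality per age, ``beta`` the per-age
sensitivity to the common time index ``k``, which is forecast as a random
walk with drift whose drift itself carries estimation noise (a
doubly-stochastic reading of the index forecast).

Statistical yearbooks truncate old-age mortality, so fitted surfaces are
closed out to the ultimate age with the Coale-Kisker method: the age-to-age
increment of log rates declines linearly from its value at a pivot age to
whatever value forces a chosen central rate at the ultimate age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySurface", "LeeCarterParams", "fit_lee_carter", "forecast_k",
    "extend_old_age", "central_to_q",
]


@dataclass
class MortalitySurface:
    """Rectangular grid of central death rates m_{x,t} for one sex."""

    years: np.ndarray          # ordered calendar years
    ages: np.ndarray           # ordered integer ages
    rates: np.ndarray          # shape (n_ages, n_years), all > 0
    sex: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (len(self.ages), len(self.years)):
            raise ValueError("rates must have shape (n_ages, n_years)")
        if np.any(self.rates <= 0) or not np.all(np.isfinite(self.rates)):
            raise ValueError("central death rates must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        """Long format (year, age, sex, central_rate)."""
        yy, aa = np.meshgrid(self.years, self.ages)
        return pd.DataFrame({
            "year": yy.ravel(), "age": aa.ravel(),
            "sex": self.sex, "central_rate": self.rates.ravel(),
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sex: str) -> "MortalitySurface":
        sub = frame[frame["sex"] == sex]
        pivot = sub.pivot(index="age", columns="year", values="central_rate")
        if pivot.isna().any().any():
            raise ValueError(f"mortality surface for sex={sex!r} is not "
                             "rectangular (missing age x year cells)")
        return cls(years=pivot.columns.to_numpy(),
                   ages=pivot.index.to_numpy(),
                   rates=pivot.to_numpy(), sex=sex)


@dataclass
class LeeCarterParams:
    """Fitted Lee-Carter parameters plus the drift model for k."""

    ages: np.ndarray
    years: np.ndarray
    alpha: np.ndarray          # per-age level of log mortality
    beta: np.ndarray           # per-age sensitivity, sums to 1
    k: np.ndarray              # per-year index, sums to 0
    drift: float               # mean yearly change of k
    innovation_sd: float       # sd of k shocks around the drift
    drift_se: float            # standard error of the drift estimate
    residual_sd: float         # sd of eps_{x,t} after the rank-1 fit

    def reconstruct_log_m(self, k=None) -> np.ndarray:
        """alpha + beta * k on the (age, year-or-path) grid."""
        kk = self.k if k is None else np.asarray(k, dtype=float)
        return self.alpha[:, None] + self.beta[:, None] * kk[None, :]


def fit_lee_carter(surface: MortalitySurface,
                   weights: str | None = None) -> LeeCarterParams:
    """Fit the Lee-Carter model by a rank-1 least-squares decomposition.

    ``weights=None`` is ordinary least squares (SVD of the centred log
    surface). ``weights="inverse_variance"`` reweights ages by the inverse
    residual variance of a first OLS pass and refits by alternating least
    squares, a common weighted variant.
    """
    if len(surface.years) < 2 or len(surface.ages) < 2:
        raise ValueError("Lee-Carter fit needs at least 2 ages and 2 years")
    log_m = np.log(surface.rates)
    alpha = log_m.mean(axis=1)
    centred = log_m - alpha[:, None]

    beta, k = _rank1(centred)
    if weights == "inverse_variance":
        resid = centred - beta[:, None] * k[None, :]
        var = resid.var(axis=1)
        w = 1.0 / np.maximum(var, 1e-12)
        beta, k = _rank1_weighted(centred, w, beta, k)
    elif weights is not None:
        raise ValueError(f"unknown weights option {weights!r}")

    # identifiability: sum(beta) = 1, sum(k) = 0
    scale = beta.sum()
    if abs(scale) < 1e-12:
        raise ValueError("degenerate beta (sums to zero)")
    beta = beta / scale
    k = k * scale
    shift = k.mean()
    alpha = alpha + beta * shift
    k = k - shift

    resid = log_m - (alpha[:, None] + beta[:, None] * k[None, :])
    residual_sd = float(resid.std(ddof=0))

    dk = np.diff(k)
    drift = float(dk.mean()) if len(dk) else 0.0
    if len(dk) > 1:
        innovation_sd = float(dk.std(ddof=1))
        drift_se = innovation_sd / np.sqrt(len(dk))
    else:
        innovation_sd, drift_se = 0.0, 0.0
    return LeeCarterParams(
        ages=surface.ages.copy(), years=surface.years.copy(),
        alpha=alpha, beta=beta, k=k, drift=drift,
        innovation_sd=innovation_sd, drift_se=drift_se,
        residual_sd=residual_sd)


def _rank1(centred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    beta = u[:, 0]
    k = s[0] * vt[0]
    # orient so that beta is predominantly positive
    if beta.sum() < 0:
        beta, k = -beta, -k
    return beta, k


def _rank1_weighted(centred, w, beta, k, n_iter: int = 60):
    """Alternating weighted least squares for the rank-1 approximation."""
    for _ in range(n_iter):
        k = (w[:, None] * beta[:, None] * centred).sum(axis=0) / \
            (w * beta ** 2).sum()
        beta = (centred * k[None, :]).sum(axis=1) / (k ** 2).sum()
    if beta.sum() < 0:
        beta, k = -beta, -k
    return beta, k


def forecast_k(params: LeeCarterParams, horizon: int, n_paths: int,
               seed=None, drift_uncertainty: bool = True,
               deterministic_steps: int = 0) -> np.ndarray:
    """Forecast the time index as a drifted random walk, shape (n_paths, horizon).

    Paths start from the last fitted k. Each step adds the drift plus a
    Gaussian innovation; with ``drift_uncertainty`` the drift is resampled
    once per path from its sampling distribution N(drift, drift_se^2),
    making the walk doubly stochastic. With ``innovation_sd == 0`` the path
    is exactly linear. The first ``deterministic_steps`` steps advance by
    the point drift with no noise (used to bridge data years to the
    forecast start).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k_last = params.k[-1]
    sd = params.innovation_sd
    drift_se = params.drift_se if (drift_uncertainty and sd > 0) else 0.0
    drifts = params.drift + drift_se * rng.standard_normal(n_paths)
    shocks = sd * rng.standard_normal((n_paths, horizon))
    if deterministic_steps > 0:
        shocks[:, :deterministic_steps] = 0.0
    steps = drifts[:, None] + shocks
    if deterministic_steps > 0:
        steps[:, :deterministic_steps] = params.drift
    return k_last + np.cumsum(steps, axis=1)


def extend_old_age(ages: np.ndarray, rates: np.ndarray, pivot_age: int = 84,
                   closing_rate: float = 0.8, omega: int = 100
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Coale-Kisker closure of central death rates up to the ultimate age.

    The log-rate increment d_x = ln m_x - ln m_{x-1} is taken at the pivot
    age and interpolated linearly in age down (or up) to the increment that
    forces ``m_omega == closing_rate``; rates beyond the pivot are rebuilt
    by the resulting recursion. Ages at or below the pivot pass through
    unchanged. ``rates`` may be 1-D (age,) or 2-D (..., age) with age last.
    """
    ages = np.asarray(ages, dtype=int)
    rates = np.asarray(rates, dtype=float)
    if pivot_age >= omega:
        raise ValueError("pivot_age must be below the ultimate age")
    if pivot_age not in ages or (pivot_age - 1) not in ages:
        raise ValueError("rates must be available up to the pivot age")
    squeeze = rates.ndim == 1
    if squeeze:
        rates = rates[None, :]
    ip = int(np.searchsorted(ages, pivot_age))
    log_m = np.log(rates)
    d_pivot = log_m[..., ip] - log_m[..., ip - 1]

    n = omega - pivot_age
    # sum of linearly interpolated increments over pivot+1..omega must equal
    # ln(closing) - ln(m_pivot); solve for the closing increment d_omega.
    total = np.log(closing_rate) - log_m[..., ip]
    d_omega = (total - n * d_pivot) * 2.0 / (n + 1) + d_pivot

    frac = np.arange(1, n + 1) / n                          # (n,)
    increments = d_pivot[..., None] + frac * (d_omega - d_pivot)[..., None]
    ext_log = log_m[..., ip, None] + np.cumsum(increments, axis=-1)

    out_ages = np.arange(ages[0], omega + 1)
    out = np.empty(rates.shape[:-1] + (len(out_ages),))
    out[..., :ip + 1] = rates[..., :ip + 1]
    out[..., ip + 1:] = np.exp(ext_log)
    if squeeze:
        out = out[0]
    return out_ages, out


def central_to_q(m, ages=None, omega: int = 100):
    """Convert central death rates to death probabilities q = 1 - exp(-m).

    Under a constant hazard within the year of age. The ultimate age is
    absorbing: q(omega) is forced to 1 when ``ages`` is supplied.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("central death rates must be non-negative")
    q = 1.0 - np.exp(-m)
    if ages is not None:
        ages = np.asarray(ages)
        q = np.where(ages == omega, 1.0, q) if q.ndim == ages.ndim else \
            np.where(np.broadcast_to(ages, q.shape) == omega, 1.0, q)
    return q if q.shape else float(q)
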