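"""Fitting and simulation of the stochastic economic parameters.

Unemployment, urbanization, and wage growth follow first-order
autoregressions on their first differences (fitted by least squares on the
lagged differences); the return on investment follows a discretized
mean-reverting (Vasicek) recursion fitted by lag-1 least squares on levels;
the bookkeeping rate is iid lognormal (fitted by maximum likelihood, i.e.
the mean and sd of the logs); the enterprise and individual contribution
rates are iid normal draws, redrawn each year. The pension growth rate is
a fixed multiple of the wage growth rate.

Simulation applies the study's clipping rules after every step:
unemployment floored at 0, urbanization capped at 80 %, wage growth kept
inside [0, 9.20 %].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (DiffARSpec, LogNormalSpec, NormalSpec,
                     RandomizationSpec, VasicekSpec)

__all__ = [
    "fit_difference_ar", "fit_vasicek", "fit_lognormal",
    "InitialConditions", "ParameterPaths", "simulate_paths",
]


def fit_difference_ar(series, with_intercept: bool = True) -> DiffARSpec:
    """Regress first differences on their own lag by least squares.

    Returns (intercept, coefficient, innovation sd); the innovation sd is
    the residual standard deviation (dof-corrected for fitted parameters).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 5:
        raise ValueError("difference-AR fit needs a series of length >= 5")
    diffs = np.diff(series)
    if np.allclose(diffs, diffs[0]):
        raise ValueError("constant series: no variation to fit")
    y, x = diffs[1:], diffs[:-1]
    design = sm.add_constant(x) if with_intercept else x[:, None]
    res = sm.OLS(y, design).fit()
    if with_intercept:
        intercept, coef = float(res.params[0]), float(res.params[1])
    else:
        intercept, coef = 0.0, float(res.params[0])
    dof = max(len(y) - design.shape[1], 1)
    sd = float(np.sqrt(res.ssr / dof))
    return DiffARSpec(intercept, coef, sd)


def fit_vasicek(series) -> VasicekSpec:
    """Lag-1 least squares on levels: x_t = a + b x_{t-1} + sd * N(0,1)."""
    series = np.asarray(series, dtype=float)
    if len(series) < 30:
        raise ValueError("Vasicek fit needs a series of length >= 30")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    if np.allclose(series, series[0]):
        raise ValueError("constant series: no variation to fit")
    y, x = series[1:], series[:-1]
    res = sm.OLS(y, sm.add_constant(x)).fit()
    dof = max(len(y) - 2, 1)
    sd = float(np.sqrt(res.ssr / dof))
    return VasicekSpec(float(res.params[0]), float(res.params[1]), sd)


def fit_lognormal(series) -> LogNormalSpec:
    """Maximum-likelihood lognormal fit: mean and sd of the log values."""
    series = np.asarray(series, dtype=float)
    if np.any(series <= 0):
        raise ValueError("lognormal fit requires strictly positive values")
    logs = np.log(series)
    return LogNormalSpec(float(logs.mean()), float(logs.std(ddof=0)))


@dataclass
class InitialConditions:
    """State of each recursion at the last observed year.

    Unemployment/urbanization are carried in percentage points (the units
    their difference equations were fitted in); wage growth and the ROI in
    fractions.
    """

    u_pct: float
    du_pct: float
    ub_pct: float
    dub_pct: float
    g: float
    dg: float
    roi: float

    def validate(self) -> None:
        for name in ("u_pct", "du_pct", "ub_pct", "dub_pct", "g", "dg", "roi"):
            val = getattr(self, name)
            if val is None or not np.isfinite(val):
                raise ValueError(f"missing or non-finite initial condition: {name}")


@dataclass
class ParameterPaths:
    """Realizations of the eight scalar parameter paths (fractions per year).

    Arrays have shape (n_paths, horizon); the mortality path is carried
    separately as the Lee-Carter k-index ensemble (see the engine module),
    completing the nine randomized parameters.
    """

    years: np.ndarray
    u: np.ndarray
    ub: np.ndarray
    g: np.ndarray
    rho: np.ndarray
    roi: np.ndarray
    j: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def n_paths(self) -> int:
        return self.u.shape[0]

    def path(self, i: int) -> dict:
        """Single path as a dict of 1-D arrays."""
        return {name: getattr(self, name)[i]
                for name in ("u", "ub", "g", "rho", "roi", "j", "b", "c")}

    def to_frame(self) -> pd.DataFrame:
        """Long format (path_id, year, parameter, value)."""
        rows = []
        for name in ("u", "ub", "g", "rho", "roi", "j", "b", "c"):
            arr = getattr(self, name)
            for i in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "path_id": i, "year": self.years,
                    "parameter": name, "value": arr[i]}))
        return pd.concat(rows, ignore_index=True)


def simulate_paths(spec: RandomizationSpec, initial: InitialConditions,
                   horizon: int, n_paths: int, seed=None,
                   rho_multiplier: float = 0.8,
                   deterministic: bool = False,
                   deterministic_steps: int = 0,
                   start_year: int = 2022) -> ParameterPaths:
    """Advance every parameter recursion year by year for an ensemble.

    Each difference recursion evolves on its own (latent) level; the value
    emitted for each year is clipped after each step (u >= 0, ub <= cap,
    g inside its band). ``deterministic``
    runs every recursion at the mean of its innovations and every iid draw
    at its distribution mean (the fixed-parameter scenario);
    ``deterministic_steps`` silences the noise for the first few years only
    (bridging data years to the forecast start). Deterministic given seed.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    initial.validate()
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    shape = (n_paths, horizon)
    if deterministic:
        noise = {key: np.zeros(shape) for key in ("u", "ub", "g", "roi")}
        b = np.full(shape, spec.enterprise_rate.mean)
        c = np.full(shape, spec.individual_rate.mean)
        j = np.full(shape, spec.bookkeeping.mean)
    else:
        noise = {key: rng.standard_normal(shape)
                 for key in ("u", "ub", "g", "roi")}
        b = spec.enterprise_rate.mean + \
            spec.enterprise_rate.sd * rng.standard_normal(shape)
        c = spec.individual_rate.mean + \
            spec.individual_rate.sd * rng.standard_normal(shape)
        j = np.exp(spec.bookkeeping.log_mean +
                   spec.bookkeeping.log_sd * rng.standard_normal(shape))
        if deterministic_steps > 0:
            ds = deterministic_steps
            for key in noise:
                noise[key][:, :ds] = 0.0
            b[:, :ds] = spec.enterprise_rate.mean
            c[:, :ds] = spec.individual_rate.mean
            j[:, :ds] = spec.bookkeeping.mean

    u = np.empty(shape)
    ub = np.empty(shape)
    g = np.empty(shape)
    roi = np.empty(shape)

    # the difference recursions evolve on latent (unclipped) levels; the
    # emitted value is clipped after each step
    u_lat = np.full(n_paths, initial.u_pct)
    du_prev = np.full(n_paths, initial.du_pct)
    ub_lat = np.full(n_paths, initial.ub_pct)
    dub_prev = np.full(n_paths, initial.dub_pct)
    g_lat = np.full(n_paths, initial.g)
    dg_prev = np.full(n_paths, initial.dg)
    roi_prev = np.full(n_paths, initial.roi)

    su, sub, sg, sv = (spec.unemployment, spec.urbanization,
                       spec.wage_growth, spec.roi)
    ub_cap_pct = spec.urbanization_cap * 100.0
    for t in range(horizon):
        du = su.intercept + su.coef * du_prev + su.sd * noise["u"][:, t]
        u_lat = u_lat + du
        du_prev = du

        dub = sub.intercept + sub.coef * dub_prev + sub.sd * noise["ub"][:, t]
        ub_lat = ub_lat + dub
        dub_prev = dub

        dg = sg.intercept + sg.coef * dg_prev + sg.sd * noise["g"][:, t]
        g_lat = g_lat + dg
        dg_prev = dg

        roi_prev = sv.intercept + sv.persistence * roi_prev + \
            sv.sd * noise["roi"][:, t]

        u[:, t] = np.clip(u_lat, 0.0, 100.0)
        ub[:, t] = np.clip(ub_lat, 0.0, ub_cap_pct)
        g[:, t] = np.clip(g_lat, 0.0, spec.wage_growth_cap)
        roi[:, t] = roi_prev

    return ParameterPaths(
        years=np.arange(start_year, start_year + horizon),
        u=u / 100.0, ub=ub / 100.0, g=g, rho=rho_multiplier * g,
        roi=roi, j=j, b=b, c=c)
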