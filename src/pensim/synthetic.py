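"""Self-contained pseudo-yearbook bundle generator with known ground truth.

Real runs of this model consume statistical-yearbook series (an age-sex
population pyramid, a mortality surface, urban fertility schedules,
unemployment/urbanization/wage histories, deposit and interbank repo rates)
that are not redistributable. This module fabricates a bundle with the same
statistical structure from configurable "true" parameters, so every fitting
stage of the pipeline can be tested by parameter recovery:

* the mortality surface is exp(alpha + beta * k + noise) with a declining
  log-bilinear time index;
* unemployment, urbanization, and wage growth histories follow first-order
  autoregressions in differences;
* the short-rate history follows a mean-reverting recursion at
  daily-observation persistence;
* the bookkeeping-rate history is iid lognormal;
* the initial pyramid is a smooth parametric hump with old-age decay.

Default truths mirror the study environment (printed recursion coefficients,
initial fund stock 4,440.17 bn yuan, 2019 average wage 63,182 yuan, initial
ROI 6.89 %).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DiffARSpec, LogNormalSpec, VasicekSpec

__all__ = ["SynthConfig", "PseudoYearbookBundle", "generate_bundle",
           "write_bundle", "read_bundle"]

_TABLES = ("population_initial", "mortality_hist", "fertility_schedule",
           "tfr_path", "srb_path", "unemployment_hist", "urbanization_hist",
           "wage_hist", "deposit_rate_hist", "repo_rate_hist",
           "initial_conditions")


def _default_alpha(sex: str, ages: np.ndarray) -> np.ndarray:
    """Siler-type baseline log mortality: infant decline + plateau + Gompertz."""
    a1, b1 = (0.005, 1.0) if sex == "male" else (0.004, 1.05)
    a2 = 1.5e-4 if sex == "male" else 1.0e-4
    a3, b3 = (3.0e-5, 0.100) if sex == "male" else (2.2e-5, 0.102)
    m = a1 * np.exp(-b1 * ages) + a2 + a3 * np.exp(b3 * ages)
    return np.log(m)


def _default_beta(ages: np.ndarray) -> np.ndarray:
    raw = 0.5 * np.exp(-ages / 15.0) + \
        0.25 * np.exp(-((ages - 70.0) / 25.0) ** 2) + 0.05
    return raw / raw.sum()


def _default_pyramid(ages: np.ndarray) -> np.ndarray:
    """Piecewise-linear hump with exponential old-age decay (unit scale).

    Emulates a low-fertility East-Asian age structure: a narrow base,
    working-age bulges around 30 and 50, and a modest (under one fifth)
    share aged 60 and above.
    """
    shape = np.interp(ages, [0, 15, 30, 50, 60, 72, 85],
                      [0.62, 0.55, 1.02, 1.0, 0.62, 0.30, 0.10])
    old = ages > 85
    shape[old] = 0.10 * 0.72 ** (ages[old] - 85)
    return shape


@dataclass
class SynthConfig:
    """Ground-truth configuration of the pseudo-yearbook bundle."""

    seed: int = 0
    n_hist_years_mortality: int = 26      # 1994-2019
    n_hist_years_unemployment: int = 42   # 1978-2019
    n_hist_years_urbanization: int = 40   # 1980-2019
    n_hist_years_wage: int = 22           # growth observations, 1998-2019
    n_deposit_obs: int = 25               # 1997-2021
    n_repo_obs: int = 1650                # daily short-rate observations
    base_year: int = 2019                 # pyramid + last mortality year
    fit_age_max: int = 89                 # yearbooks truncate old-age rates
    # Lee-Carter truth
    lc_drift: float = -1.8
    lc_innovation_sd: float = 0.4
    lc_resid_sd: float = 0.02
    # difference-AR truths (u/ub in percentage points, g in fractions)
    true_ar_unemployment: DiffARSpec = field(
        default_factory=lambda: DiffARSpec(0.0, 0.5851, 0.2616))
    true_ar_urbanization: DiffARSpec = field(
        default_factory=lambda: DiffARSpec(1.0476, 0.7042, 0.2815))
    true_ar_wage_growth: DiffARSpec = field(
        default_factory=lambda: DiffARSpec(-0.0010, -0.3095, 0.0258))
    true_vasicek: VasicekSpec = field(
        default_factory=lambda: VasicekSpec(0.0015002, 0.95275, 0.0020282))
    true_lognormal: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(-3.173, 0.364))
    # history starting levels
    u0_pct: float = 5.3
    du0_pct: float = 0.2
    ub0_pct: float = 19.4
    dub0_pct: float = 0.5
    g0: float = 0.12
    dg0: float = 0.0
    repo0: float = 0.025
    # demography
    fertility_peak_shape: tuple = (4.0, 6.0)   # beta-density shape over 15-49
    tfr_level: float = 1.45
    srb_start: float = 1.11
    srb_end: float = 1.07
    total_population: float = 1.398e9
    male_share: float = 0.511
    # initial conditions
    initial_fund: float = 4_440.17e9
    initial_wage: float = 63_182.0
    initial_roi: float = 0.0689

    def validate(self) -> None:
        for name in ("n_hist_years_mortality", "n_hist_years_unemployment",
                     "n_hist_years_urbanization", "n_hist_years_wage",
                     "n_deposit_obs", "n_repo_obs"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be a count >= 3")
        if not (0.0 < self.true_vasicek.persistence < 1.0):
            raise ValueError("true_vasicek: persistence must lie in (0, 1)")
        for name in ("lc_innovation_sd", "lc_resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_population <= 0:
            raise ValueError("total_population must be positive")
        if self.tfr_level < 0:
            raise ValueError("tfr_level must be non-negative")


@dataclass
class PseudoYearbookBundle:
    """All tables of a pseudo-yearbook bundle plus the generating truth."""

    population_initial: pd.DataFrame
    mortality_hist: pd.DataFrame
    fertility_schedule: pd.DataFrame
    tfr_path: pd.DataFrame
    srb_path: pd.DataFrame
    unemployment_hist: pd.DataFrame
    urbanization_hist: pd.DataFrame
    wage_hist: pd.DataFrame
    deposit_rate_hist: pd.DataFrame
    repo_rate_hist: pd.DataFrame
    initial_conditions: pd.DataFrame

    ground_truth: dict = field(default_factory=dict)

    def initial_value(self, key: str) -> float:
        frame = self.initial_conditions
        row = frame.loc[frame["key"] == key, "value"]
        if len(row) != 1:
            raise KeyError(f"initial condition {key!r} missing from bundle")
        return float(row.iloc[0])


def _simulate_diff_ar(spec: DiffARSpec, x0: float, dx0: float, n: int,
                      rng, floor: float | None = None) -> np.ndarray:
    out = np.empty(n)
    out[0] = x0
    dx = dx0
    for i in range(1, n):
        dx = spec.intercept + spec.coef * dx + spec.sd * rng.standard_normal()
        nxt = out[i - 1] + dx
        if floor is not None and nxt < floor:
            nxt = floor
        dx = nxt - out[i - 1]
        out[i] = nxt
    return out


def generate_bundle(config: SynthConfig) -> PseudoYearbookBundle:
    """Generate the full pseudo-yearbook bundle, deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base = config.base_year

    # --- mortality surface -------------------------------------------------
    ages = np.arange(0, config.fit_age_max + 1)
    n_years = config.n_hist_years_mortality
    years = np.arange(base - n_years + 1, base + 1)
    beta = _default_beta(ages)
    steps = config.lc_drift + config.lc_innovation_sd * \
        rng.standard_normal(n_years - 1)
    k = np.concatenate([[0.0], np.cumsum(steps)])
    k = k - k.mean()
    truth_alpha, frames = {}, []
    for sex in ("male", "female"):
        alpha = _default_alpha(sex, ages)
        truth_alpha[sex] = alpha
        noise = config.lc_resid_sd * rng.standard_normal((len(ages), n_years))
        log_m = alpha[:, None] + beta[:, None] * k[None, :] + noise
        yy, aa = np.meshgrid(years, ages)
        frames.append(pd.DataFrame({
            "year": yy.ravel(), "age": aa.ravel(), "sex": sex,
            "central_rate": np.exp(log_m).ravel()}))
    mortality_hist = pd.concat(frames, ignore_index=True)

    # --- fertility, pyramid ------------------------------------------------
    fa = np.arange(15, 50)
    x = (fa - 15 + 0.5) / 35.0
    a, b = config.fertility_peak_shape
    shape = x ** (a - 1) * (1 - x) ** (b - 1)
    schedule = shape / shape.sum()
    fertility_schedule = pd.DataFrame({"age": fa, "coefficient": schedule})

    path_years = np.arange(base + 1, base + 102)
    tfr_path = pd.DataFrame({"year": path_years,
                             "tfr": np.full(len(path_years), config.tfr_level)})
    srb = np.where(path_years <= 2050,
                   config.srb_start + (config.srb_end - config.srb_start) *
                   (path_years - path_years[0]) / (2050 - path_years[0]),
                   config.srb_end)
    srb_path = pd.DataFrame({"year": path_years, "srb": srb})

    all_ages = np.arange(0, 101)
    pyr_shape = _default_pyramid(all_ages)
    scale = config.total_population / (2 * pyr_shape.sum())
    rows = []
    for sex, share in (("male", config.male_share),
                       ("female", 1.0 - config.male_share)):
        rows.append(pd.DataFrame({
            "age": all_ages, "sex": sex,
            "count": pyr_shape * scale * 2 * share}))
    population_initial = pd.concat(rows, ignore_index=True)

    # --- economic histories -------------------------------------------------
    nu = config.n_hist_years_unemployment
    u_years = np.arange(base - nu + 1, base + 1)
    u = _simulate_diff_ar(config.true_ar_unemployment, config.u0_pct,
                          config.du0_pct, nu, rng, floor=0.0)
    unemployment_hist = pd.DataFrame({"year": u_years, "rate_pct": u})

    nub = config.n_hist_years_urbanization
    ub_years = np.arange(base - nub + 1, base + 1)
    ub = _simulate_diff_ar(config.true_ar_urbanization, config.ub0_pct,
                           config.dub0_pct, nub, rng)
    urbanization_hist = pd.DataFrame({"year": ub_years, "rate_pct": ub})

    ng = config.n_hist_years_wage
    g = _simulate_diff_ar(config.true_ar_wage_growth, config.g0,
                          config.dg0, ng + 1, rng)[1:]   # growth 1998..2019
    g_years = np.arange(base - ng + 1, base + 1)
    wages = np.empty(ng + 1)                             # levels 1997..2019
    wages[-1] = config.initial_wage
    for i in range(ng - 1, -1, -1):
        wages[i] = wages[i + 1] / (1.0 + g[i])
    wage_hist = pd.DataFrame({"year": np.arange(g_years[0] - 1, base + 1),
                              "avg_wage": wages})

    dep_years = np.arange(1997, 1997 + config.n_deposit_obs)
    deposit = np.exp(config.true_lognormal.log_mean +
                     config.true_lognormal.log_sd *
                     rng.standard_normal(config.n_deposit_obs))
    deposit_rate_hist = pd.DataFrame({"year": dep_years, "rate": deposit})

    vs = config.true_vasicek
    repo = np.empty(config.n_repo_obs)
    repo[0] = config.repo0
    shocks = rng.standard_normal(config.n_repo_obs - 1)
    for i in range(1, config.n_repo_obs):
        repo[i] = vs.intercept + vs.persistence * repo[i - 1] + \
            vs.sd * shocks[i - 1]
    repo_rate_hist = pd.DataFrame({"obs": np.arange(config.n_repo_obs),
                                   "rate": repo})

    initial_conditions = pd.DataFrame({
        "key": ["initial_fund", "initial_wage", "initial_roi", "base_year"],
        "value": [config.initial_fund, config.initial_wage,
                  config.initial_roi, float(base)]})

    truth = {
        "lee_carter": {
            "ages": ages.tolist(), "beta": beta.tolist(),
            "k": k.tolist(), "drift": config.lc_drift,
            "innovation_sd": config.lc_innovation_sd,
            "resid_sd": config.lc_resid_sd,
            "alpha": {sex: truth_alpha[sex].tolist()
                      for sex in ("male", "female")}},
        "ar": {name: dataclasses.asdict(getattr(config, f"true_ar_{name}"))
               for name in ("unemployment", "urbanization", "wage_growth")},
        "vasicek": dataclasses.asdict(config.true_vasicek),
        "lognormal": dataclasses.asdict(config.true_lognormal),
        "seed": config.seed,
    }

    return PseudoYearbookBundle(
        population_initial=population_initial, mortality_hist=mortality_hist,
        fertility_schedule=fertility_schedule, tfr_path=tfr_path,
        srb_path=srb_path, unemployment_hist=unemployment_hist,
        urbanization_hist=urbanization_hist, wage_hist=wage_hist,
        deposit_rate_hist=deposit_rate_hist, repo_rate_hist=repo_rate_hist,
        initial_conditions=initial_conditions, ground_truth=truth)


def write_bundle(bundle: PseudoYearbookBundle, directory) -> None:
    """Write every table as CSV plus ground_truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(bundle, name).to_csv(directory / f"{name}.csv", index=False,
                                     float_format="%.17g")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)


def read_bundle(directory) -> PseudoYearbookBundle:
    directory = Path(directory)
    tables = {}
    for name in _TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"bundle is missing table {name!r} "
                                    f"({path})")
        tables[name] = pd.read_csv(path)
    truth_path = directory / "ground_truth.json"
    truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return PseudoYearbookBundle(ground_truth=truth, **tables)
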