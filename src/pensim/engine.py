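"""Orchestration: fit every dynamic parameter from a pseudo-yearbook bundle,
run the fixed-parameter baseline and the Monte Carlo ensemble, and summarize
per-year 95 % bands and the final-reserve distribution.

The forecast horizon is 2022-2094. The fund stock is dated end-2020, so the
pipeline internally bridges 2020-2021 with the deterministic (mean) parameter
recursions: the published table starts in 2022 with the end-2021 balance as
its opening stock. Each Monte Carlo path draws an independent realization of
the nine randomized parameters (the Lee-Carter k-index plus the eight scalar
paths) from a per-path substream spawned off the master seed, so results do
not depend on scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import actuarial, indicators, mortality, population, stochastic
from .config import PolicyParams, RandomizationSpec
from .population import SEXES, FertilityInputs, PopulationState
from .series import YearSeries
from .synthetic import PseudoYearbookBundle

__all__ = ["FittedInputs", "fit_from_bundle", "Demography",
           "project_demography", "run_single_path", "run_fixed_scenario",
           "SimulationResult", "run_monte_carlo",
           "final_reserve_distribution"]

#: earliest year wage/pension-growth series must reach: the oldest retiree
#: alive at the bridge year retired omega - r years earlier (female workers:
#: 2021 - 50 = 1971), and her final wage is dated the year before.
HIST_START = 1965


# ---------------------------------------------------------------------------
# Fitting stage

@dataclass
class FittedInputs:
    """Everything estimated from (or carried by) a pseudo-yearbook bundle."""

    lc: dict                      # sex -> LeeCarterParams
    fert: FertilityInputs
    spec: RandomizationSpec       # recursions fitted, b/c distributions assumed
    init: stochastic.InitialConditions
    pyramid: PopulationState      # base-year population
    base_year: int
    wage_hist: YearSeries         # average-wage levels
    deposit_hist: YearSeries     # bookkeeping-rate history
    initial_fund: float
    initial_wage: float
    initial_roi: float


def fit_from_bundle(bundle: PseudoYearbookBundle, policy: PolicyParams,
                    randomization: RandomizationSpec | None = None
                    ) -> FittedInputs:
    """Fit Lee-Carter and the parameter recursions from the bundle tables.

    The enterprise/individual contribution-rate distributions and the
    clipping bounds are assumptions, taken from ``randomization`` (defaults
    if omitted); everything else is estimated from the bundle histories.
    """
    base = randomization or RandomizationSpec()

    lc = {}
    for sex in SEXES:
        surface = mortality.MortalitySurface.from_frame(
            bundle.mortality_hist, sex)
        lc[sex] = mortality.fit_lee_carter(surface)

    sched = bundle.fertility_schedule.sort_values("age")["coefficient"]
    sched = sched.to_numpy() / sched.sum()
    tfr = _series_from(bundle.tfr_path, "tfr")
    srb = _series_from(bundle.srb_path, "srb")
    fert = FertilityInputs(schedule=sched, tfr=tfr, srb=srb)

    u_hist = bundle.unemployment_hist.sort_values("year")["rate_pct"].to_numpy()
    ub_hist = bundle.urbanization_hist.sort_values("year")["rate_pct"].to_numpy()
    wage_frame = bundle.wage_hist.sort_values("year")
    wage_hist = YearSeries(int(wage_frame["year"].iloc[0]),
                           wage_frame["avg_wage"].to_numpy())
    g_hist = np.diff(wage_hist.values) / wage_hist.values[:-1]

    spec = RandomizationSpec(
        unemployment=stochastic.fit_difference_ar(u_hist, with_intercept=False),
        urbanization=stochastic.fit_difference_ar(ub_hist),
        wage_growth=stochastic.fit_difference_ar(g_hist),
        roi=stochastic.fit_vasicek(
            bundle.repo_rate_hist.sort_values("obs")["rate"].to_numpy()),
        bookkeeping=stochastic.fit_lognormal(
            bundle.deposit_rate_hist["rate"].to_numpy()),
        enterprise_rate=base.enterprise_rate,
        individual_rate=base.individual_rate,
        wage_growth_cap=base.wage_growth_cap,
        urbanization_cap=base.urbanization_cap)

    initial_roi = bundle.initial_value("initial_roi")
    init = stochastic.InitialConditions(
        u_pct=float(u_hist[-1]), du_pct=float(u_hist[-1] - u_hist[-2]),
        ub_pct=float(ub_hist[-1]), dub_pct=float(ub_hist[-1] - ub_hist[-2]),
        g=float(g_hist[-1]), dg=float(g_hist[-1] - g_hist[-2]),
        roi=initial_roi)

    base_year = int(bundle.initial_value("base_year"))
    pyr = bundle.population_initial
    counts = np.zeros((2, policy.omega + 1))
    for i, sex in enumerate(SEXES):
        sub = pyr[pyr["sex"] == sex].sort_values("age")
        counts[i, sub["age"].to_numpy()] = sub["count"].to_numpy()
    pyramid = PopulationState(year=base_year, counts=counts)

    dep = bundle.deposit_rate_hist.sort_values("year")
    deposit_hist = YearSeries(int(dep["year"].iloc[0]),
                              dep["rate"].to_numpy())

    return FittedInputs(
        lc=lc, fert=fert, spec=spec, init=init, pyramid=pyramid,
        base_year=base_year, wage_hist=wage_hist, deposit_hist=deposit_hist,
        initial_fund=bundle.initial_value("initial_fund"),
        initial_wage=bundle.initial_value("initial_wage"),
        initial_roi=initial_roi)


def _series_from(frame: pd.DataFrame, col: str) -> YearSeries:
    frame = frame.sort_values("year")
    years = frame["year"].to_numpy(dtype=int)
    if len(years) > 1 and np.any(np.diff(years) != 1):
        raise ValueError(f"{col} path has gaps in its year column")
    return YearSeries(years[0], frame[col].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Demographic stage (population + insured ledgers for one parameter path)

@dataclass
class Demography:
    years: np.ndarray                     # base_year+1 .. end_year
    states: list                          # PopulationState per year
    ledgers: list                         # InsuredLedger per year
    q: np.ndarray                         # (horizon, 2, omega+1)


def build_q(fitted: FittedInputs, k_by_sex: dict, policy: PolicyParams,
            m_scale: float = 1.0) -> np.ndarray:
    """Death probabilities (horizon, 2, omega+1) from k-index paths."""
    horizon = len(next(iter(k_by_sex.values())))
    q = np.empty((horizon, 2, policy.omega + 1))
    for i, sex in enumerate(SEXES):
        lc = fitted.lc[sex]
        log_m = lc.reconstruct_log_m(k_by_sex[sex])       # (ages, horizon)
        ages, m_ext = mortality.extend_old_age(
            lc.ages, np.exp(log_m).T, pivot_age=policy.ck_pivot_age,
            closing_rate=policy.ck_closing_rate, omega=policy.omega)
        q[:, i, :] = mortality.central_to_q(m_scale * m_ext, ages,
                                            omega=policy.omega)
    return q


def project_demography(fitted: FittedInputs, policy: PolicyParams,
                       k_by_sex: dict, u_path: np.ndarray,
                       ub_path: np.ndarray, m_scale: float = 1.0
                       ) -> Demography:
    """Project population and insured ledgers for base_year+1 .. end_year."""
    q = build_q(fitted, k_by_sex, policy, m_scale=m_scale)
    horizon = q.shape[0]
    states = population.project_population(fitted.pyramid, fitted.fert, q,
                                           horizon)
    ledgers = []
    for h, state in enumerate(states):
        ledgers.append(population.insured_counts(
            state, float(u_path[h]), float(ub_path[h]),
            policy.coverage_rate(state.year), q[h], policy))
    years = np.array([s.year for s in states])
    return Demography(years=years, states=states, ledgers=ledgers, q=q)


# ---------------------------------------------------------------------------
# One full path: wages, pension tables, flows, indicators

def run_single_path(fitted: FittedInputs, policy: PolicyParams,
                    path: dict, demog: Demography,
                    scale: dict | None = None) -> dict:
    """Run the actuarial pipeline for one parameter path.

    ``path`` maps parameter name -> 1-D array over the projection years
    (base_year+1 .. end_year) for g, rho, roi, j, b, c. ``scale`` optionally
    multiplies a named path (used by the elasticity scan). Returns the
    indicator table (start_year..end_year) plus diagnostics.
    """
    scale = scale or {}
    years = demog.years
    start, end = policy.start_year, policy.end_year
    bridge = start - 1                     # flows start the year before

    def scaled(name):
        arr = np.asarray(path[name], dtype=float)
        return arr * scale.get(name, 1.0)

    g_path = scaled("g")
    rho_path = scaled("rho")
    roi_path = scaled("roi")
    j_path = scaled("j")
    b_path = scaled("b")
    c_path = scaled("c")

    y0 = int(years[0])
    wage_hist = fitted.wage_hist

    # average wage 1965..end: backfill history geometrically, extend by g
    g_hist = np.diff(wage_hist.values) / wage_hist.values[:-1]
    g_mean = float(g_hist.mean())
    sbar = np.empty(end - HIST_START + 1)
    sy = YearSeries(HIST_START, sbar)
    for year in range(wage_hist.start_year, wage_hist.end_year + 1):
        sy[year] = wage_hist[year]
    for year in range(wage_hist.start_year - 1, HIST_START - 1, -1):
        sy[year] = sy[year + 1] / (1.0 + g_mean)
    for year in range(wage_hist.end_year + 1, end + 1):
        sy[year] = sy[year - 1] * (1.0 + g_path[year - y0])

    # pension growth: multiplier * g, historical g backfilled with its mean
    mult = policy.pension_growth_multiplier
    rho = YearSeries(HIST_START, np.empty(end - HIST_START + 1))
    for year in range(HIST_START, y0):
        if year - 1 >= wage_hist.start_year and year <= wage_hist.end_year:
            rho[year] = mult * (wage_hist[year] / wage_hist[year - 1] - 1.0)
        else:
            rho[year] = mult * g_mean
    for year in range(y0, end + 1):
        rho[year] = rho_path[year - y0]

    # bookkeeping rate: deposit history then the simulated path
    dep = fitted.deposit_hist
    j = YearSeries(dep.start_year, np.empty(end - dep.start_year + 1))
    for year in range(dep.start_year, end + 1):
        if year <= dep.end_year:
            j[year] = dep[year]
        else:
            j[year] = j_path[year - y0]

    # contribution-rate and contributory-ratio series for account history
    c_full = YearSeries(HIST_START, np.empty(end - HIST_START + 1))
    for year in range(HIST_START, end + 1):
        c_full[year] = (fitted.spec.individual_rate.mean if year < y0
                        else c_path[year - y0])
    d_full = YearSeries(HIST_START,
                        np.full(end - HIST_START + 1,
                                policy.contrib_wage_ratio))

    # salary-structure entry ratio: uniform in history, ledger-weighted after
    e = policy.entry_age
    max_r = max(cls.retire_age for cls in policy.classes)
    work_ages = np.arange(e, max_r)
    s = policy.seniority_growth
    uniform_ratio = len(work_ages) / ((1.0 + s) ** (work_ages - e)).sum()
    entry_ratio = YearSeries(HIST_START,
                             np.full(end - HIST_START + 1, uniform_ratio))
    for h, led in enumerate(demog.ledgers):
        counts = led.in_service.sum(axis=0)[e:max_r]
        denom = (counts * (1.0 + s) ** (work_ages - e)).sum()
        if denom > 0:
            entry_ratio[int(demog.years[h])] = counts.sum() / denom

    ws = actuarial.WageSystem(sy, entry_ratio, s, e)
    indexer = actuarial.IndexationTable(rho, mode=policy.indexation)

    tables = {}
    for cls in policy.classes:
        first_ret = bridge - (policy.omega - cls.retire_age)
        tables[cls.name] = actuarial.build_pension_table(
            ws, cls, policy, c_full, d_full, j, first_ret, end)

    flows = []
    for year in range(bridge, end + 1):
        led = demog.ledgers[year - y0]
        flows.append(actuarial.yearly_fund_flow(
            led, ws, policy, float(b_path[year - y0]),
            float(c_path[year - y0]), c_full, d_full, j, tables, indexer))

    roi_for_acc = np.empty(len(flows))
    roi_for_acc[0] = fitted.initial_roi
    for i, year in enumerate(range(start, end + 1)):
        roi_for_acc[i + 1] = roi_path[year - y0]
    table = indicators.indicator_table(flows, fitted.initial_fund,
                                       roi_for_acc)
    full_table = table
    table = table[table["year"] >= start].reset_index(drop=True)

    mask = demog.years >= start
    insured_total = np.array([led.total_insured()
                              for led in demog.ledgers])[mask]
    return {"table": table, "bridge_table": full_table,
            "insured_total": insured_total,
            "years": demog.years[mask]}


# ---------------------------------------------------------------------------
# Scenarios

_PARAM_TO_PATH = {"unemployment": "u", "urbanization": "ub",
                  "wage_growth": "g", "pension_growth": "rho", "roi": "roi",
                  "bookkeeping": "j", "enterprise_rate": "b",
                  "individual_rate": "c"}


def _deterministic_k(fitted: FittedInputs, horizon: int) -> dict:
    return {sex: fitted.lc[sex].k[-1] +
            fitted.lc[sex].drift * np.arange(1, horizon + 1)
            for sex in SEXES}


def _draw_paths(fitted: FittedInputs, policy: PolicyParams, horizon: int,
                rng=None, deterministic: bool = False,
                only: str | None = None, det_steps: int = 2) -> dict:
    """One path of the nine parameters over base_year+1 .. end_year.

    ``only`` keeps every parameter at its deterministic mean except the named
    one (used for the influence index). The first ``det_steps`` years are
    always deterministic (the 2020-2021 bridge).
    """
    start = fitted.base_year + 1
    spec, init = fitted.spec, fitted.init
    det = stochastic.simulate_paths(spec, init, horizon, 1,
                                    deterministic=True, start_year=start,
                                    rho_multiplier=policy.pension_growth_multiplier)
    if deterministic:
        sto = det
    else:
        sto = stochastic.simulate_paths(spec, init, horizon, 1, rng,
                                        deterministic_steps=det_steps,
                                        start_year=start,
                                        rho_multiplier=policy.pension_growth_multiplier)
    if policy.fixed_j == "median":
        det.j[:] = spec.bookkeeping.median

    k_det = _deterministic_k(fitted, horizon)
    if deterministic or only is not None and only != "mortality":
        k = k_det
    else:
        k = {sex: mortality.forecast_k(fitted.lc[sex], horizon, 1, rng,
                                       deterministic_steps=det_steps)[0]
             for sex in SEXES}

    names = ("u", "ub", "g", "rho", "roi", "j", "b", "c")
    if deterministic or only == "mortality":
        chosen = {n: det for n in names}
    elif only is None:
        chosen = {n: sto for n in names}
    else:
        chosen = {n: det for n in names}
        chosen[_PARAM_TO_PATH[only]] = sto
        if only == "wage_growth":
            # wages fluctuate; pensions keep indexing at the mean growth
            chosen["rho"] = det
        elif only == "pension_growth":
            chosen["g"] = det
    path = {n: getattr(chosen[n], n)[0] for n in names}
    path["k"] = k
    return path


def run_fixed_scenario(bundle_or_fitted, policy: PolicyParams | None = None,
                       randomization: RandomizationSpec | None = None) -> dict:
    """Fixed-parameter baseline: every recursion at its mean innovation and
    every distributional draw at its mean."""
    policy = policy or PolicyParams()
    fitted = _ensure_fitted(bundle_or_fitted, policy, randomization)
    horizon = policy.end_year - fitted.base_year
    path = _draw_paths(fitted, policy, horizon, deterministic=True)
    demog = project_demography(fitted, policy, path["k"], path["u"],
                               path["ub"])
    out = run_single_path(fitted, policy, path, demog)
    out["path"] = path
    out["demography"] = demog
    out["fitted"] = fitted
    return out


def _ensure_fitted(bundle_or_fitted, policy, randomization=None):
    if isinstance(bundle_or_fitted, FittedInputs):
        return bundle_or_fitted
    return fit_from_bundle(bundle_or_fitted, policy, randomization)


@dataclass
class SimulationResult:
    """Monte Carlo ensemble of indicator tables and parameter paths."""

    years: np.ndarray
    n_paths: int
    seed: int
    indicator_paths: dict            # name -> (n_paths, n_years)
    final_balance: np.ndarray        # accumulated balance at the end, trn yuan
    param_paths: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-year median/mean and 2.5/97.5 % empirical quantiles.

        Indicator 6 is undefined (NaN) while the accumulated balance is
        non-negative; those cells stay missing in the summary.
        """
        import warnings
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for name, arr in self.indicator_paths.items():
                rows.append(pd.DataFrame({
                    "indicator": name, "year": self.years,
                    "mean": np.nanmean(arr, axis=0),
                    "median": np.nanmedian(arr, axis=0),
                    "lower": np.nanquantile(arr, 0.025, axis=0),
                    "upper": np.nanquantile(arr, 0.975, axis=0)}))
        return pd.concat(rows, ignore_index=True)


def run_monte_carlo(bundle_or_fitted, policy: PolicyParams | None = None,
                    n_paths: int = 5000, seed: int = 0,
                    randomization: RandomizationSpec | None = None,
                    only: str | None = None, store_paths: bool = True,
                    progress: bool = False) -> SimulationResult:
    """Monte Carlo ensemble: each path draws an independent parameter
    realization from a substream spawned off the master seed.

    ``only`` restricts fluctuation to a single named parameter (all others
    held at their deterministic means), the procedure behind the influence
    index. Demography is recomputed per path only when the fluctuating
    parameters touch it.
    """
    if n_paths < 2:
        raise ValueError("a Monte Carlo ensemble needs n_paths >= 2")
    policy = policy or PolicyParams()
    fitted = _ensure_fitted(bundle_or_fitted, policy, randomization)
    horizon = policy.end_year - fitted.base_year

    demog_static = None
    if only is not None and only not in ("mortality", "unemployment",
                                         "urbanization"):
        det = _draw_paths(fitted, policy, horizon, deterministic=True)
        demog_static = project_demography(fitted, policy, det["k"],
                                          det["u"], det["ub"])

    streams = np.random.SeedSequence(seed).spawn(n_paths)
    ind_names = ("ind1", "ind2", "ind3", "ind4", "ind5", "ind6")
    collected = None
    finals = np.empty(n_paths)
    params = {}
    years = None
    for p in range(n_paths):
        rng = np.random.default_rng(streams[p])
        path = _draw_paths(fitted, policy, horizon, rng, only=only)
        demog = demog_static or project_demography(
            fitted, policy, path["k"], path["u"], path["ub"])
        out = run_single_path(fitted, policy, path, demog)
        table = out["table"]
        if collected is None:
            years = table["year"].to_numpy()
            collected = {n: np.empty((n_paths, len(years)))
                         for n in ind_names}
            if store_paths:
                offset = horizon - len(years)
                params = {n: np.empty((n_paths, len(years)))
                          for n in ("u", "ub", "g", "rho", "roi", "j",
                                    "b", "c", "insured_total")}
        for n in ind_names:
            collected[n][p] = table[n].to_numpy()
        finals[p] = table["ind4"].to_numpy()[-1]
        if store_paths:
            for n in ("u", "ub", "g", "rho", "roi", "j", "b", "c"):
                params[n][p] = path[n][offset:]
            params["insured_total"][p] = out["insured_total"]
        if progress and (p + 1) % 1000 == 0:
            print(f"... {p + 1}/{n_paths} paths")
    return SimulationResult(years=years, n_paths=n_paths, seed=seed,
                            indicator_paths=collected, final_balance=finals,
                            param_paths=params)


def final_reserve_distribution(result: SimulationResult) -> dict:
    """Sorted final balances with decile cut values and membership masks.

    The bottom/top decile groups have exactly floor(n/10) members each
    ("worse" / "better" final fund-reserve statuses).
    """
    finals = result.final_balance
    order = np.argsort(finals, kind="stable")
    n = len(finals)
    k = n // 10
    bottom = np.zeros(n, dtype=bool)
    top = np.zeros(n, dtype=bool)
    bottom[order[:k]] = True
    top[order[-k:]] = True
    return {"sorted": finals[order],
            "cut_low": float(np.quantile(finals, 0.10)),
            "cut_high": float(np.quantile(finals, 0.90)),
            "bottom_mask": bottom, "top_mask": top}
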