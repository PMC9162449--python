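"""Yearly pension contributions and expenditures of the insured population.

The model keeps cohort-level (not individual) accounts. Wages follow a
seniority structure S_{t,x} = (1+s)^{x-e} S_{t,e}, pinned down by requiring
that the insured-weighted mean equals the published average wage. Employer
contributions (rate b_t) feed the social pooling account, employee
contributions (rate c_t) the notional individual account, both levied on the
previous year's contributory wage d_t * S_{t-1,x-1}.

Benefits by reform cohort:

* old people (retired before the 1997 reform) draw a replacement-rate pension
  off their final pre-retirement wage, paid by pooling;
* middle and new retirees draw the basic pension (half the economy average
  wage at retirement, scaled by one plus their average contribution wage
  index, times 1 % per contribution year), middle people additionally a
  transition pension at coefficient eps per pre-reform year, and an
  individual-account annuity of 12/m_r of the balance accumulated at the
  bookkeeping rate;
* the account annuity is paid by the individual account while the retiree is
  within the stipulated m_r months and by pooling afterwards; it is fixed in
  nominal terms, while basic/transition/old pensions are indexed by the
  pension growth rate.

Deaths trigger refunds of the accumulated individual-account balance
(in-service) or the remaining stipulated months of the annuity (retirees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CohortClass, PolicyParams
from .population import InsuredLedger, cohort_age_ranges
from .series import YearSeries

__all__ = [
    "SalaryProfile", "build_salary_profile", "WageSystem",
    "indexation_factor", "IndexationTable", "contributions",
    "old_people_pension", "old_people_expenditure", "basic_pension",
    "transition_pension", "account_balance_at_retirement",
    "individual_account_pension", "split_account_payer",
    "in_service_account_balance", "retired_refund_factor", "death_refunds",
    "PensionTable", "build_pension_table", "FundFlow", "yearly_fund_flow",
]


# ---------------------------------------------------------------------------
# Salary structure

@dataclass
class SalaryProfile:
    """Seniority wage structure for one year: S_{t,x} = (1+s)^{x-e} S_{t,e}."""

    year: int
    avg_wage: float
    entry_age: int
    seniority_growth: float
    entry_wage: float

    def wage(self, age) -> float | np.ndarray:
        return self.entry_wage * \
            (1.0 + self.seniority_growth) ** (np.asarray(age) - self.entry_age)


def build_salary_profile(avg_wage: float, ages, counts, s: float,
                         entry_age: int, year: int = 0) -> SalaryProfile:
    """Solve the entry wage so the insured-weighted mean wage equals avg_wage.

    S_{t,e} = avg_wage * sum(L) / sum(L * (1+s)^{x-e}).
    """
    ages = np.asarray(ages, dtype=int)
    counts = np.asarray(counts, dtype=float)
    if avg_wage <= 0:
        raise ValueError("average wage must be positive")
    total = counts.sum()
    if total <= 0:
        raise ValueError("no insureds: salary structure undetermined")
    weighted = (counts * (1.0 + s) ** (ages - entry_age)).sum()
    return SalaryProfile(year=year, avg_wage=avg_wage, entry_age=entry_age,
                         seniority_growth=s,
                         entry_wage=avg_wage * total / weighted)


class WageSystem:
    """Average-wage and salary-structure series spanning history + forecast.

    ``entry_ratio[y]`` is S_{y,e} / Sbar_y, so the wage of an x-year-old in
    year y is Sbar_y * entry_ratio_y * (1+s)^{x-e}.
    """

    def __init__(self, avg_wage: YearSeries, entry_ratio: YearSeries,
                 seniority_growth: float, entry_age: int) -> None:
        self.avg = avg_wage
        self.entry_ratio = entry_ratio
        self.s = seniority_growth
        self.e = entry_age

    def wage(self, year: int, age) -> float | np.ndarray:
        return self.avg[year] * self.entry_ratio[year] * \
            (1.0 + self.s) ** (np.asarray(age) - self.e)

    def ratio(self, year: int, age) -> float | np.ndarray:
        """Individual wage relative to the average wage of the same year."""
        return self.entry_ratio[year] * \
            (1.0 + self.s) ** (np.asarray(age) - self.e)


# ---------------------------------------------------------------------------
# Pension indexation

def indexation_factor(rho: YearSeries, ret_year: int, t: int,
                      mode: str = "as-printed") -> float:
    """Pension indexation from the retirement year to year t.

    prod_{h=ret}^{t} (1 + rho_h) divided by (1 + rho_t) ("as-printed") or by
    (1 + rho_ret) ("retirement-year"); with constant rho both telescope to
    (1 + rho)^(t - ret).
    """
    if t < ret_year:
        raise ValueError("t must not precede the retirement year")
    prod = float(np.prod(1.0 + rho.window(ret_year, t)))
    denom = 1.0 + (rho[t] if mode == "as-printed" else rho[ret_year])
    return prod / denom


class IndexationTable:
    """Vectorized indexation factors via a running product of (1 + rho)."""

    def __init__(self, rho: YearSeries, mode: str = "as-printed") -> None:
        self.rho = rho
        self.mode = mode
        self._cp = rho.cumprod1p()

    def factor(self, ret_years, t: int) -> np.ndarray:
        ret_years = np.atleast_1d(np.asarray(ret_years, dtype=int))
        pos = ret_years - 1 - self._cp.start_year
        if np.any(pos < 0):
            raise ValueError("rho series starts too late for these cohorts")
        cp_prev = np.where(pos >= 0, self._cp.values[np.maximum(pos, 0)], 1.0)
        num = self._cp[t] / cp_prev
        if self.mode == "as-printed":
            return num / (1.0 + self.rho[t])
        return num / (1.0 + self.rho.values[ret_years - self.rho.start_year])


# ---------------------------------------------------------------------------
# Contributions (pooling: rate b; individual account: rate c)

def contributions(counts, wages_prev, d: float, b: float, c: float
                  ) -> tuple[float, float]:
    """Pooling and individual-account contribution revenue for one year.

    ``counts`` are in-service insureds by age, ``wages_prev`` the matching
    previous-year wages at the previous age (S_{t-1,x-1}).
    """
    if min(b, c, d) < 0:
        raise ValueError("rates must be non-negative")
    counts = np.asarray(counts, dtype=float)
    wages_prev = np.asarray(wages_prev, dtype=float)
    base = float((counts * d * wages_prev).sum())
    return b * base, c * base


# ---------------------------------------------------------------------------
# Per-capita pensions at (and after) retirement

def old_people_pension(ws: WageSystem, replacement: float, ret_year: int,
                       r: int) -> float:
    """Pre-indexation pension of a pre-reform retiree: R^ * S_{ret-1, r-1}."""
    return replacement * float(ws.wage(ret_year - 1, r - 1))


def old_people_expenditure(retired_by_age: np.ndarray, ws: WageSystem,
                           replacement: float, rho: YearSeries, t: int,
                           r: int, z: int = 1997, omega: int = 100,
                           mode: str = "as-printed") -> float:
    """Total pooling expenditure on pre-reform retirees in year t."""
    if t < z:
        raise ValueError("t must not precede the reform year")
    lo = r + t - z
    if lo > omega:
        return 0.0
    total = 0.0
    for x in range(lo, omega + 1):
        ret = t - (x - r)
        if retired_by_age[x] <= 0:
            continue
        percap = old_people_pension(ws, replacement, ret, r) * \
            indexation_factor(rho, ret, t, mode)
        total += retired_by_age[x] * percap
    return total


def basic_pension(ws: WageSystem, d: YearSeries, ret_year: int,
                  cls: CohortClass, policy: PolicyParams,
                  rho: YearSeries | None = None, t: int | None = None) -> float:
    """Basic pension per retiree of a post-reform cohort.

    (Sbar_{ret-1} / 2) * [1 + mean contribution wage index] * 1 % per
    contribution year, with contribution years min(ret - z, r - e); indexed
    to year t when a pension-growth series is supplied.
    """
    r, e, z = cls.retire_age, policy.entry_age, policy.reform_year
    n_c = min(ret_year - z, r - e)
    if n_c <= 0:
        raise ValueError("non-positive contribution years")
    ks = np.arange(1, n_c + 1)
    idx = np.array([d[ret_year - k] * ws.ratio(ret_year - k - 1, r - k - 1)
                    for k in ks])
    base = 0.5 * ws.avg[ret_year - 1] * (1.0 + idx.mean()) * n_c / 100.0
    if rho is not None:
        if t is None:
            raise ValueError("t required for indexation")
        base *= indexation_factor(rho, ret_year, t, policy.indexation)
    return base


def transition_pension(ws: WageSystem, d: YearSeries, ret_year: int,
                       cls: CohortClass, policy: PolicyParams,
                       rho: YearSeries | None = None,
                       t: int | None = None) -> float:
    """Transition pension compensating middle people's pre-reform years.

    Sbar_{ret-1} * (mean post-reform contribution index) * pre-reform years *
    eps; zero for new people (no pre-reform years).
    """
    r, e, z = cls.retire_age, policy.entry_age, policy.reform_year
    post = ret_year - z
    if post <= 0:
        raise ValueError("middle people retire after the reform year")
    pre = max(r - e - post, 0)
    if pre == 0:
        return 0.0
    ks = np.arange(1, post + 1)
    idx = np.array([d[ret_year - k] * ws.ratio(ret_year - k - 1, r - k - 1)
                    for k in ks])
    base = ws.avg[ret_year - 1] * idx.mean() * pre * policy.transition_coef
    if rho is not None:
        if t is None:
            raise ValueError("t required for indexation")
        base *= indexation_factor(rho, ret_year, t, policy.indexation)
    return base


def account_balance_at_retirement(ws: WageSystem, c: YearSeries,
                                  d: YearSeries, j: YearSeries,
                                  ret_year: int, cls: CohortClass,
                                  policy: PolicyParams) -> float:
    """Individual-account balance at retirement: credited contributions
    compounded at the bookkeeping rate through the year before retirement."""
    r, e, z = cls.retire_age, policy.entry_age, policy.reform_year
    join = ret_year - (r - e)
    k_lo = max(z, join)
    if k_lo > ret_year - 1:
        return 0.0
    total = 0.0
    for k in range(k_lo, ret_year):
        age_k = e + (k - join)
        contrib = c[k] * d[k] * float(ws.wage(k - 1, age_k - 1))
        growth = float(np.prod(1.0 + j.window(k, ret_year - 1)))
        total += contrib * growth
    return total


def individual_account_pension(balance: float, m_r: int) -> float:
    """Annual account annuity: 12 * balance / m_r, fixed in nominal terms."""
    if m_r <= 0:
        raise ValueError("payout months must be positive")
    if balance < 0:
        raise ValueError("account balance must be non-negative")
    return 12.0 * balance / m_r


def split_account_payer(age: int, r: int, m_r: int) -> str:
    """Who pays the account annuity at this age: the individual account
    while age - r < m_r / 12 (strict), the pooling account afterwards."""
    return "individual" if (age - r) < m_r / 12.0 else "pooling"


# ---------------------------------------------------------------------------
# Death refunds

def in_service_account_balance(ws: WageSystem, c: YearSeries, d: YearSeries,
                               j: YearSeries, t: int, age: int,
                               policy: PolicyParams) -> float:
    """Accumulated account balance of an in-service insured aged ``age`` in
    year t: contributions since max(reform, entry), compounded at the
    bookkeeping rate through t-1 (no interest in the death year)."""
    e, z = policy.entry_age, policy.reform_year
    k_max = min(t - z, age - e)
    total = 0.0
    for k in range(0, k_max + 1):
        contrib = c[t - k] * d[t - k] * float(ws.wage(t - k - 1, age - k - 1))
        growth = float(np.prod(1.0 + j.window(t - k, t - 1))) if k >= 1 else 1.0
        total += contrib * growth
    return total


def retired_refund_factor(age: int, r: int, m_r: int) -> float:
    """Remaining annuity-years factor refunded when a retiree dies within
    the stipulated months: max(0, m_r/12 - (age - r) - 1)."""
    return max(0.0, m_r / 12.0 - (age - r) - 1.0)


def death_refunds(ledger: InsuredLedger, ws: WageSystem, c: YearSeries,
                  d: YearSeries, j: YearSeries, annuities: dict,
                  policy: PolicyParams) -> float:
    """Total individual-account refunds triggered by deaths in year t.

    ``annuities`` maps class name -> YearSeries of account annuities by
    retirement year. In-service decedents refund their accumulated balance;
    retired decedents within the stipulated months refund the remaining
    annuity-years factor times their annuity.
    """
    t, z = ledger.year, policy.reform_year
    total = 0.0
    balances = _in_service_balance_row(ws, c, d, j, t, policy)
    for i, cls in enumerate(ledger.classes):
        r = cls.retire_age
        for x in range(policy.entry_age, r):
            dx = ledger.deaths_in_service[i, x]
            if dx > 0:
                total += dx * balances[x - policy.entry_age]
        hi = min(r + t - z - 1, r + m_floor(cls.payout_months) - 1)
        ann = annuities[cls.name]
        for x in range(r, hi + 1):
            dx = ledger.deaths_retired[i, x]
            if dx <= 0:
                continue
            ret = t - (x - r)
            total += dx * retired_refund_factor(x, r, cls.payout_months) * \
                ann[ret]
    return total


def m_floor(m_r: int) -> int:
    return int(m_r // 12)


def _in_service_balance_row(ws: WageSystem, c: YearSeries, d: YearSeries,
                            j: YearSeries, t: int, policy: PolicyParams
                            ) -> np.ndarray:
    """Account balances of in-service insureds by age (entry_age..max r - 1).

    The balance factorizes as (1+s)^{x-e} times a prefix sum over
    contribution lags, so one pass serves every age.
    """
    e, z, s = policy.entry_age, policy.reform_year, ws.s
    max_age = max(cls.retire_age for cls in policy.classes) - 1
    ages = np.arange(e, max_age + 1)
    k_cap = min(t - z, int(ages.max()) - e)
    ks = np.arange(0, k_cap + 1)
    g_pad = np.concatenate([[1.0], np.cumprod(1.0 + j.values)])
    j0 = j.start_year
    g_last = g_pad[max(t - 1 - j0 + 1, 0)]
    growth = np.where(ks >= 1,
                      g_last / g_pad[np.maximum(t - ks - 1 - j0 + 1, 0)],
                      1.0)
    sv, s0 = ws.avg.values, ws.avg.start_year
    wv, w0 = ws.entry_ratio.values, ws.entry_ratio.start_year
    a = (c.values[t - ks - c.start_year] * d.values[t - ks - d.start_year] *
         sv[t - ks - 1 - s0] * wv[t - ks - 1 - w0] *
         (1.0 + s) ** (-ks - 1.0)) * growth
    prefix = np.cumsum(a)
    k_of_age = np.minimum(t - z, ages - e)
    k_of_age = np.clip(k_of_age, 0, k_cap)
    return (1.0 + s) ** (ages - e) * prefix[k_of_age]


# ---------------------------------------------------------------------------
# Pension tables per retirement cohort and the yearly fund flow

@dataclass
class PensionTable:
    """Per-capita pension amounts by retirement year for one class.

    ``pool_base`` is the pre-indexation pooling pension (old-people pension,
    or basic + transition for post-reform cohorts); ``annuity`` the fixed
    individual-account annuity (zero for pre-reform cohorts).
    """

    cls: CohortClass
    pool_base: YearSeries
    annuity: YearSeries


def build_pension_table(ws: WageSystem, cls: CohortClass,
                        policy: PolicyParams, c: YearSeries, d: YearSeries,
                        j: YearSeries, first_ret: int,
                        last_ret: int) -> PensionTable:
    """Tabulate per-capita pensions for every retirement year in range.

    Vectorized over the contribution years of each cohort; semantically
    identical to the per-cohort operations above (basic + transition
    pensions, account annuity, old-people replacement pension).
    """
    z, e, s = policy.reform_year, policy.entry_age, ws.s
    r, m_r = cls.retire_age, cls.payout_months
    sv, s0 = ws.avg.values, ws.avg.start_year
    wv, w0 = ws.entry_ratio.values, ws.entry_ratio.start_year
    dv, d0 = d.values, d.start_year
    cv, c0 = c.values, c.start_year
    # padded running product of (1 + j): g_pad[i] = prod over the first i-1
    g_pad = np.concatenate([[1.0], np.cumprod(1.0 + j.values)])
    j0 = j.start_year

    def gprod(year):          # prod_{h<=year} (1 + j_h), 1 before the series
        return g_pad[max(int(year) - j0 + 1, 0)]

    ret_years = np.arange(first_ret, last_ret + 1)
    pool = np.zeros(len(ret_years))
    ann = np.zeros(len(ret_years))
    for i, ret in enumerate(ret_years):
        if ret <= z:
            pool[i] = policy.old_replacement * sv[ret - 1 - s0] * \
                wv[ret - 1 - w0] * (1.0 + s) ** (r - 1 - e)
            continue
        post = ret - z
        n_c = min(post, r - e)
        ks = np.arange(1, n_c + 1)
        # contribution wage index d_{ret-k} * S_{ret-k-1, r-k-1} / Sbar
        idx = dv[ret - ks - d0] * wv[ret - ks - 1 - w0] * \
            (1.0 + s) ** (r - ks - 1 - e)
        sbar_ret = sv[ret - 1 - s0]
        base = 0.5 * sbar_ret * (1.0 + idx.mean()) * n_c / 100.0
        if post < r - e:   # middle person: transition pension on top
            base += sbar_ret * idx.mean() * (r - e - post) * \
                policy.transition_coef
        pool[i] = base

        join = ret - (r - e)
        k_lo = max(z, join)
        kk = np.arange(k_lo, ret)
        if len(kk):
            ages = e + kk - join
            contrib = cv[kk - c0] * dv[kk - d0] * sv[kk - 1 - s0] * \
                wv[kk - 1 - w0] * (1.0 + s) ** (ages - 1 - e)
            growth = gprod(ret - 1) / \
                g_pad[np.maximum(kk - 1 - j0 + 1, 0)]
            ann[i] = 12.0 * float((contrib * growth).sum()) / m_r
    return PensionTable(cls=cls, pool_base=YearSeries(first_ret, pool),
                        annuity=YearSeries(first_ret, ann))


@dataclass
class FundFlow:
    """Decomposed contributions and expenditures for one year (yuan)."""

    year: int
    pool_contrib: float = 0.0
    ind_contrib: float = 0.0
    pool_pension: float = 0.0        # old + basic + transition, indexed
    pool_account: float = 0.0        # account annuities beyond m_r months
    ind_account: float = 0.0         # account annuities within m_r months
    ind_refund: float = 0.0          # death refunds from individual accounts

    @property
    def contributions(self) -> float:
        return self.pool_contrib + self.ind_contrib

    @property
    def expenditures(self) -> float:
        return (self.pool_pension + self.pool_account +
                self.ind_account + self.ind_refund)

    @property
    def balance(self) -> float:
        return self.contributions - self.expenditures


def yearly_fund_flow(ledger: InsuredLedger, ws: WageSystem,
                     policy: PolicyParams, b_t: float, c_t: float,
                     c_hist: YearSeries, d: YearSeries, j: YearSeries,
                     tables: dict, indexer: IndexationTable) -> FundFlow:
    """Assemble the year's contribution and expenditure components.

    ``tables`` maps class name -> PensionTable covering every retirement
    year alive in this ledger. Contributions and expenditures are booked at
    the beginning of the year.
    """
    t = ledger.year
    e, z, omega = policy.entry_age, policy.reform_year, policy.omega
    flow = FundFlow(year=t)

    for i, cls in enumerate(ledger.classes):
        r = cls.retire_age
        ages = np.arange(e, r)
        counts = ledger.in_service[i, e:r]
        wages_prev = ws.avg[t - 1] * ws.entry_ratio[t - 1] * \
            (1.0 + ws.s) ** (ages - 1 - e)
        pool_rev, ind_rev = contributions(counts, wages_prev, d[t], b_t, c_t)
        flow.pool_contrib += pool_rev
        flow.ind_contrib += ind_rev

        table = tables[cls.name]
        ranges = cohort_age_ranges(t, r, e, z, omega)
        months_limit = cls.payout_months / 12.0
        for group in ("old", "middle", "new"):
            rng = ranges[group]
            if rng is None:
                continue
            xs = np.arange(rng[0], rng[1] + 1)
            counts_x = ledger.retired[i, xs]
            live = counts_x > 0
            if not live.any():
                continue
            xs, counts_x = xs[live], counts_x[live]
            rets = t - (xs - r)
            pool_base = table.pool_base.values[rets - table.pool_base.start_year]
            flow.pool_pension += float(
                (counts_x * pool_base * indexer.factor(rets, t)).sum())
            if group != "old":
                ann = table.annuity.values[rets - table.annuity.start_year]
                within = (xs - r) < months_limit
                flow.ind_account += float((counts_x * ann)[within].sum())
                flow.pool_account += float((counts_x * ann)[~within].sum())

    annuities = {name: tbl.annuity for name, tbl in tables.items()}
    flow.ind_refund = death_refunds(ledger, ws, c_hist, d, j, annuities,
                                    policy)
    return flow
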