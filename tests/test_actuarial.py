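"""Salary structure, pension formulas, account mechanics, fund flows."""

import numpy as np
import pytest

from pensim import actuarial
from pensim.actuarial import (IndexationTable, WageSystem,
                              account_balance_at_retirement, basic_pension,
                              build_pension_table, build_salary_profile,
                              contributions, in_service_account_balance,
                              indexation_factor, individual_account_pension,
                              old_people_expenditure, retired_refund_factor,
                              split_account_payer, transition_pension,
                              yearly_fund_flow)
from pensim.config import PolicyParams
from pensim.population import InsuredLedger
from pensim.series import YearSeries


def _const(start, end, value):
    return YearSeries(start, np.full(end - start + 1, value))


def _ws(sbar=100.0, ratio=1.0, s=0.0, start=1960, end=2120, e=20):
    return WageSystem(_const(start, end, sbar), _const(start, end, ratio),
                      s, e)


class TestSalaryProfile:
    def test_zero_seniority_growth_flattens_wages(self):
        prof = build_salary_profile(100.0, np.arange(20, 60), np.ones(40),
                                    s=0.0, entry_age=20)
        assert np.allclose(prof.wage(np.arange(20, 60)), 100.0)

    def test_two_age_solution(self):
        prof = build_salary_profile(105.0, np.array([20, 21]),
                                    np.array([1.0, 1.0]), s=0.10,
                                    entry_age=20)
        assert prof.wage(20) == pytest.approx(100.0)
        assert prof.wage(21) == pytest.approx(110.0)

    def test_weighted_mean_invariant_default_growth(self):
        ages = np.arange(20, 60)
        counts = np.ones(40)
        prof = build_salary_profile(63182.0, ages, counts, s=0.01363,
                                    entry_age=20)
        mean = (prof.wage(ages) * counts).sum() / counts.sum()
        assert mean == pytest.approx(63182.0, abs=1e-10 * 63182.0)

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValueError, match="insured"):
            build_salary_profile(100.0, np.array([30]), np.array([0.0]),
                                 0.01, 20)


class TestContributions:
    def test_single_insured_printed_rates(self):
        pool, ind = contributions([1.0], [100.0], d=0.6089, b=0.16, c=0.08)
        assert pool == pytest.approx(9.7424)
        assert ind == pytest.approx(4.8712)

    def test_zero_rate_and_empty_ledger(self):
        assert contributions([1.0], [100.0], 0.6089, 0.0, 0.08)[0] == 0.0
        assert contributions([], [], 0.6089, 0.16, 0.08) == (0.0, 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            contributions([1.0], [100.0], 0.6089, -0.1, 0.08)


class TestIndexation:
    def test_constant_rate_telescopes(self):
        rho = _const(2000, 2040, 0.10)
        assert indexation_factor(rho, 2010, 2012) == pytest.approx(1.21)
        assert indexation_factor(rho, 2010, 2010) == pytest.approx(1.0)

    def test_table_matches_scalar(self):
        rng = np.random.default_rng(2)
        rho = YearSeries(2000, rng.uniform(0, 0.1, 50))
        for mode in ("as-printed", "retirement-year"):
            table = IndexationTable(rho, mode=mode)
            for ret, t in [(2005, 2030), (2010, 2010), (2020, 2045)]:
                assert table.factor([ret], t)[0] == pytest.approx(
                    indexation_factor(rho, ret, t, mode), rel=1e-12)


class TestPensions:
    def test_old_people_replacement(self, policy):
        ws = _ws()
        retired = np.zeros(101)
        retired[61] = 1.0   # retired one year ago at r=60
        rho = _const(1960, 2100, 0.0)
        # pick t so that age 61 falls inside the pre-reform range
        t = 1998
        total = old_people_expenditure(retired, ws, 0.7163, rho, t, r=60)
        assert total == pytest.approx(71.63)

    def test_no_old_people_left(self, policy):
        ws = _ws()
        retired = np.ones(101)
        rho = _const(1960, 2120, 0.0)
        t = 1997 + 100 - 60 + 1
        assert old_people_expenditure(retired, ws, 0.7163, rho, t, r=60) == 0.0

    def test_full_career_basic_pension_collapses(self, policy):
        ws = _ws()   # wage identically the average, d == 1
        d = _const(1960, 2120, 1.0)
        cls = policy.classes[0]
        ret = 1997 + 40   # full 40-year contribution career
        assert basic_pension(ws, d, ret, cls, policy) == \
            pytest.approx(0.5 * 100 * 2.0 * 0.40)

    def test_double_wage_basic_pension(self, policy):
        ws = _ws(ratio=2.0)
        d = _const(1960, 2120, 1.0)
        cls = policy.classes[0]
        ret = 1997 + 40
        n = 40
        assert basic_pension(ws, d, ret, cls, policy) == \
            pytest.approx(1.5 * 100 * n / 100.0)

    def test_middle_person_contribution_years(self, policy):
        ws = _ws()
        d = _const(1960, 2120, 1.0)
        cls = policy.classes[0]
        # retiring 2007: min(2007-1997, 40) = 10 contribution years
        assert basic_pension(ws, d, 2007, cls, policy) == \
            pytest.approx(0.5 * 100 * 2.0 * 0.10)

    def test_transition_pension_printed_product(self, policy):
        ws = _ws()
        d = _const(1960, 2120, 1.0)
        cls = policy.classes[0]
        ret = 2007   # pre-reform years 40 - 10 = 30
        assert transition_pension(ws, d, ret, cls, policy) == \
            pytest.approx(100 * 1.0 * 30 * 0.012)

    def test_new_person_has_no_transition_pension(self, policy):
        ws = _ws()
        d = _const(1960, 2120, 1.0)
        assert transition_pension(ws, d, 1997 + 41, policy.classes[0],
                                  policy) == 0.0

    def test_account_annuity_printed_divisor(self):
        assert individual_account_pension(139_000.0, 139) == \
            pytest.approx(12_000.0)
        assert individual_account_pension(0.0, 195) == 0.0
        with pytest.raises(ValueError):
            individual_account_pension(100.0, 0)

    def test_female_worker_payout_months(self, policy):
        assert {c.name: c.payout_months for c in policy.classes} == \
            {"male": 139, "female_worker": 195, "female_cadre": 170}

    @pytest.mark.parametrize("age_minus_r, expected", [
        (5, "individual"), (11, "individual"), (12, "pooling"),
    ])
    def test_account_payer_split(self, age_minus_r, expected):
        assert split_account_payer(60 + age_minus_r, 60, 139) == expected


class TestRefunds:
    def test_retired_refund_factor(self):
        assert retired_refund_factor(61, 60, 139) == \
            pytest.approx(139 / 12 - 2)
        assert retired_refund_factor(75, 60, 139) == 0.0

    def test_in_service_death_refund_no_interest_in_death_year(self, policy):
        ws = _ws()
        c = _const(1960, 2120, 0.08)
        d = _const(1960, 2120, 1.0)
        j = _const(1996, 2120, 0.50)   # large rate to expose any interest
        # death in the reform year: exactly one (current-year) contribution
        bal = in_service_account_balance(ws, c, d, j, t=1997, age=30,
                                         policy=policy)
        assert bal == pytest.approx(0.08 * 100.0)

    def test_balance_compounds_prior_years(self, policy):
        ws = _ws()
        c = _const(1960, 2120, 0.08)
        d = _const(1960, 2120, 1.0)
        j = _const(1996, 2120, 0.03)
        bal = in_service_account_balance(ws, c, d, j, t=1999, age=30,
                                         policy=policy)
        expected = 8.0 * (1.03 ** 2 + 1.03 + 1)
        assert bal == pytest.approx(expected, rel=1e-12)


class TestVectorizedConsistency:
    """The fast per-cohort tables must reproduce the scalar operations."""

    def _generic_inputs(self, policy):
        rng = np.random.default_rng(11)
        years = np.arange(1960, 2121)
        sbar = YearSeries(1960, 100.0 * np.cumprod(
            1 + rng.uniform(0.0, 0.08, len(years))))
        ratio = YearSeries(1960, rng.uniform(0.7, 1.0, len(years)))
        ws = WageSystem(sbar, ratio, policy.seniority_growth,
                        policy.entry_age)
        c = YearSeries(1960, rng.uniform(0.07, 0.09, len(years)))
        d = _const(1960, 2120, policy.contrib_wage_ratio)
        j = YearSeries(1996, rng.uniform(0.01, 0.06, 2120 - 1996 + 1))
        return ws, c, d, j

    def test_pension_table_matches_scalar_ops(self, policy):
        ws, c, d, j = self._generic_inputs(policy)
        for cls in policy.classes:
            table = build_pension_table(ws, cls, policy, c, d, j,
                                        first_ret=1985, last_ret=2080)
            for ret in (1985, 1997, 2005, 2036, 2037, 2060):
                if ret <= policy.reform_year:
                    expected = actuarial.old_people_pension(
                        ws, policy.old_replacement, ret, cls.retire_age)
                    assert table.annuity[ret] == 0.0
                else:
                    expected = basic_pension(ws, d, ret, cls, policy)
                    if ret - policy.reform_year < \
                            cls.retire_age - policy.entry_age:
                        expected += transition_pension(ws, d, ret, cls,
                                                       policy)
                    bal = account_balance_at_retirement(ws, c, d, j, ret,
                                                        cls, policy)
                    assert table.annuity[ret] == pytest.approx(
                        individual_account_pension(bal, cls.payout_months),
                        rel=1e-9)
                assert table.pool_base[ret] == pytest.approx(expected,
                                                             rel=1e-9)

    def test_balance_row_matches_scalar(self, policy):
        ws, c, d, j = self._generic_inputs(policy)
        row = actuarial._in_service_balance_row(ws, c, d, j, 2030, policy)
        for age in (20, 25, 40, 59):
            assert row[age - policy.entry_age] == pytest.approx(
                in_service_account_balance(ws, c, d, j, 2030, age, policy),
                rel=1e-9)


def _toy_ledger(policy, scale=1.0):
    n_cls = len(policy.classes)
    in_service = np.zeros((n_cls, 101))
    retired = np.zeros((n_cls, 101))
    deaths_is = np.zeros((n_cls, 101))
    deaths_ret = np.zeros((n_cls, 101))
    in_service[0, 30] = 2.0 * scale
    retired[0, 61] = 3.0 * scale
    deaths_is[0, 30] = 0.1 * scale
    deaths_ret[0, 61] = 0.2 * scale
    return InsuredLedger(year=2022, classes=policy.classes,
                         in_service=in_service, retired=retired,
                         deaths_in_service=deaths_is,
                         deaths_retired=deaths_ret)


def _toy_system(policy):
    ws = _ws()
    c = _const(1960, 2120, 0.08)
    d = _const(1960, 2120, 0.6089)
    j = _const(1996, 2120, 0.03)
    rho = _const(1965, 2120, 0.02)
    indexer = IndexationTable(rho, mode=policy.indexation)
    tables = {cls.name: build_pension_table(
        ws, cls, policy, c, d, j,
        2021 - (policy.omega - cls.retire_age), 2100)
        for cls in policy.classes}
    return ws, c, d, j, tables, indexer


class TestYearlyFundFlow:
    def test_toy_economy_matches_hand_computation(self, policy):
        """One worker cohort and one retiree cohort, constant wages: every
        flow component agrees with a spreadsheet-style recomputation."""
        ws, c, d, j, tables, indexer = _toy_system(policy)
        flow = yearly_fund_flow(_toy_ledger(policy), ws, policy, 0.16, 0.08,
                                c, d, j, tables, indexer)

        base = 2.0 * 0.6089 * 100.0
        assert flow.pool_contrib == pytest.approx(0.16 * base, rel=1e-9)
        assert flow.ind_contrib == pytest.approx(0.08 * base, rel=1e-9)

        # retiree: retired 2021 at 60 -> middle person with 24 post-reform
        # contribution years and 16 pre-reform years
        b_pension = 0.5 * 100 * (1 + 0.6089) * 0.24
        t_pension = 100 * 0.6089 * 16 * 0.012
        index = 1.02 ** 1   # the printed product telescopes to (1+rho)^(t-ret)
        assert flow.pool_pension == pytest.approx(
            3.0 * (b_pension + t_pension) * index, rel=1e-9)

        # contribution of year k compounds over h = k .. ret-1, so the 1997
        # contribution earns 24 years of interest and the 2020 one earns 1
        balance = 0.08 * 0.6089 * 100 * sum(1.03 ** i for i in range(1, 25))
        annuity = 12 * balance / 139
        assert flow.ind_account == pytest.approx(3.0 * annuity, rel=1e-9)
        assert flow.pool_account == 0.0

        worker_balance = 0.08 * 0.6089 * 100 * \
            sum(1.03 ** k for k in range(11))
        refund = 0.1 * worker_balance + 0.2 * (139 / 12 - 2) * annuity
        assert flow.ind_refund == pytest.approx(refund, rel=1e-9)

        assert flow.expenditures == pytest.approx(
            flow.pool_pension + flow.ind_account + flow.ind_refund, rel=1e-12)
        assert flow.balance == pytest.approx(
            flow.contributions - flow.expenditures, rel=1e-12)

    def test_flows_homogeneous_in_counts(self, policy):
        ws, c, d, j, tables, indexer = _toy_system(policy)
        one = yearly_fund_flow(_toy_ledger(policy), ws, policy, 0.16, 0.08,
                               c, d, j, tables, indexer)
        two = yearly_fund_flow(_toy_ledger(policy, scale=2.0), ws, policy,
                               0.16, 0.08, c, d, j, tables, indexer)
        for name in ("pool_contrib", "ind_contrib", "pool_pension",
                     "pool_account", "ind_account", "ind_refund"):
            assert getattr(two, name) == pytest.approx(
                2 * getattr(one, name), rel=1e-12)

    def test_no_retirees_means_no_expenditures(self, policy):
        ws, c, d, j, tables, indexer = _toy_system(policy)
        ledger = _toy_ledger(policy)
        ledger.retired[:] = 0.0
        ledger.deaths_retired[:] = 0.0
        ledger.deaths_in_service[:] = 0.0
        flow = yearly_fund_flow(ledger, ws, policy, 0.16, 0.08, c, d, j,
                                tables, indexer)
        assert flow.expenditures == 0.0
        assert flow.balance == flow.contributions

    def test_account_conserved_within_one_installment(self, policy):
        """A full-career cohort followed to exhaustion of its stipulated
        months: individual-account inflows equal the annuity payments made
        by the account, up to the annual-installment granularity."""
        ws, c, d, j, tables, indexer = _toy_system(policy)
        cls = policy.classes[0]
        ret = 2037   # joined exactly at the reform year: 40 credited years
        bal = account_balance_at_retirement(ws, c, d, j, ret, cls, policy)
        annuity = individual_account_pension(bal, cls.payout_months)
        inflow = bal   # compounded to retirement by construction
        years_paid = sum(
            1 for age in range(cls.retire_age, policy.omega + 1)
            if split_account_payer(age, cls.retire_age,
                                   cls.payout_months) == "individual")
        assert abs(years_paid * annuity - inflow) <= annuity
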