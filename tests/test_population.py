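"""Cohort-component projection, insured counts, cohort classes, aging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pensim.config import PolicyParams
from pensim.population import (SEXES, FertilityInputs, PopulationState,
                               aging_indicators, classify_cohort,
                               cohort_age_ranges, insured_counts,
                               project_population)
from pensim.series import YearSeries


def _fert(tfr=0.0, srb=1.05, year0=2000, n=200):
    schedule = np.full(35, 1 / 35)
    return FertilityInputs(schedule=schedule,
                           tfr=YearSeries(year0, np.full(n, tfr)),
                           srb=YearSeries(year0, np.full(n, srb)))


def _state(counts=None, year=2000):
    if counts is None:
        counts = np.ones((2, 101)) * 100.0
    return PopulationState(year=year, counts=counts)


class TestProjection:
    def test_pure_aging_conserves_mass(self):
        horizon = 5
        initial = _state()
        q = np.zeros((horizon, 2, 101))
        states = project_population(initial, _fert(tfr=0.0), q, horizon)
        for h, state in enumerate(states):
            # each year one terminal cohort exits at the ultimate age
            expected = initial.total - (h + 1) * 2 * 100.0
            assert state.total == pytest.approx(expected)
            # the pyramid shifts up one age per year
            assert np.allclose(state.counts[:, h + 1:],
                               initial.counts[:, :100 - h])

    def test_survivorship_identity_exact(self):
        rng = np.random.default_rng(4)
        horizon = 3
        q = rng.uniform(0, 0.3, (horizon, 2, 101))
        initial = _state(rng.uniform(10, 100, (2, 101)))
        states = project_population(initial, _fert(tfr=0.0), q, horizon)
        prev = initial.counts
        for h, state in enumerate(states):
            assert np.array_equal(state.counts[:, 1:],
                                  prev[:, :-1] * (1 - q[h, :, 1:]))
            prev = state.counts

    def test_equal_sex_ratio_splits_births_evenly(self):
        states = project_population(_state(), _fert(tfr=1.8, srb=1.0),
                                    np.zeros((1, 2, 101)), 1)
        male, female = states[0].counts[:, 0]
        assert male == pytest.approx(female)
        assert male > 0

    def test_stationary_population_under_unit_reproduction(self):
        """With fertility scaled so the female Leslie matrix has dominant
        eigenvalue 1, the total population is constant within 0.5 % over
        50 years after convergence."""
        q_age = np.clip(0.002 + 0.0001 * np.arange(101) ** 1.5 / 50, 0, 1)
        q_age[-1] = 1.0
        schedule = np.full(35, 1 / 35)
        srb = 1.05
        f_share = 1 / (1 + srb)

        # Euler-Lotka at unit growth: the net reproduction rate is linear in
        # the fertility scale, so tfr = 1/NRR(tfr=1) gives eigenvalue 1
        survival = np.cumprod(1 - q_age[1:])          # to age x, x = 1..100
        nrr = sum(schedule[x - 15] * (1 - q_age[x]) * f_share *
                  (survival[x - 2] if x >= 2 else 1.0)
                  for x in range(15, 50))
        tfr = 1.0 / nrr

        leslie = np.zeros((101, 101))
        for x in range(1, 101):
            leslie[x, x - 1] = 1 - q_age[x]
        for x in range(15, 50):
            leslie[0, x - 1] = tfr * schedule[x - 15] * (1 - q_age[x]) * f_share
        eigvals, eigvecs = np.linalg.eig(leslie)
        dom = np.argmax(np.abs(eigvals))
        assert np.abs(eigvals[dom]) == pytest.approx(1.0, abs=1e-8)
        stable = np.abs(np.real(eigvecs[:, dom]))
        stable = stable / stable.sum() * 1e6

        horizon = 50
        q = np.broadcast_to(q_age, (horizon, 2, 101)).copy()
        fert = _fert(tfr=tfr, srb=srb, year0=2000, n=horizon + 1)
        initial = _state(np.vstack([srb * stable, stable]))
        states = project_population(initial, fert, q, horizon)
        totals = np.array([s.total for s in states])
        assert np.max(np.abs(totals / initial.total - 1)) < 0.005

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            project_population(_state(), _fert(), np.zeros((1, 2, 101)), 0)
        with pytest.raises(ValueError):
            project_population(_state(), _fert(), np.zeros((1, 2, 50)), 1)


class TestInsuredCounts:
    def test_direct_product(self, policy):
        counts = np.zeros((2, 101))
        counts[0, 30] = 1000.0
        led = insured_counts(_state(counts), 0.05, 0.6, 0.9,
                             np.zeros((2, 101)), policy)
        assert led.in_service[0, 30] == pytest.approx(
            1000 * 0.95 * 0.6 * 0.9 * 0.9370)

    def test_full_unemployment_means_no_workers(self, policy):
        led = insured_counts(_state(), 1.0, 0.6, 0.9, np.zeros((2, 101)),
                             policy)
        assert led.in_service.sum() == 0.0
        assert led.retired.sum() > 0.0

    def test_retirees_scaled_by_retiree_share(self, policy):
        counts = np.zeros((2, 101))
        counts[0, 70] = 1000.0
        led = insured_counts(_state(counts), 0.05, 0.6, 0.9,
                             np.zeros((2, 101)), policy)
        assert led.retired[0, 70] == pytest.approx(1000 * 0.6 * 0.9 * 0.9440)

    def test_female_classes_split_four_to_one(self, policy):
        counts = np.zeros((2, 101))
        counts[1, 30] = 1000.0
        led = insured_counts(_state(counts), 0.0, 1.0, 1.0,
                             np.zeros((2, 101)), policy)
        worker = led.in_service[1, 30]
        cadre = led.in_service[2, 30]
        assert worker == pytest.approx(4 * cadre)

    def test_deaths_follow_death_probability(self, policy):
        q = np.full((2, 101), 0.1)
        led = insured_counts(_state(), 0.05, 0.6, 0.9, q, policy)
        assert np.allclose(led.deaths_in_service, 0.1 * led.in_service)
        assert np.allclose(led.deaths_retired, 0.1 * led.retired)

    def test_rate_outside_unit_interval_rejected(self, policy):
        with pytest.raises(ValueError, match="urbanization"):
            insured_counts(_state(), 0.05, 1.2, 0.9, np.zeros((2, 101)),
                           policy)

    def test_coverage_schedule(self, policy):
        assert policy.coverage_rate(2020) == pytest.approx(0.90)
        assert policy.coverage_rate(2010) == pytest.approx(0.85)
        assert policy.coverage_rate(2040) == pytest.approx(0.95)


class TestCohorts:
    @pytest.mark.parametrize("join, retire, expected", [
        (1980, 1996, "old"),
        (1990, 2010, "middle"),
        (1990, 1997, "middle"),     # boundary: retired in the reform year
        (2000, 2040, "new"),
        (1997, 2037, "new"),
    ])
    def test_classification(self, join, retire, expected):
        assert classify_cohort(join, retire) == expected

    def test_join_after_retire_rejected(self):
        with pytest.raises(ValueError):
            classify_cohort(2010, 2000)

    def test_printed_interval_example(self):
        ranges = cohort_age_ranges(2000, r=60, e=20)
        assert ranges["middle"] == (60, 62)
        assert ranges["old"] == (63, 100)
        assert ranges["new"] is None

    def test_all_new_after_transition_completes(self):
        ranges = cohort_age_ranges(2078, r=60, e=20)
        assert ranges["old"] is None
        assert ranges["middle"] is None
        assert ranges["new"] == (60, 100)

    def test_first_post_reform_retirees(self):
        ranges = cohort_age_ranges(1998, r=60, e=20)
        assert ranges["middle"] == (60, 60)

    def test_pre_reform_year_rejected(self):
        with pytest.raises(ValueError):
            cohort_age_ranges(1996, r=60, e=20)

    @given(t=st.integers(1997, 2120), r=st.sampled_from([50, 55, 60]))
    @settings(max_examples=200, deadline=None)
    def test_ranges_partition_retiree_ages(self, t, r):
        """old/middle/new intervals are disjoint, ordered, and jointly cover
        every retiree age [r, omega]."""
        ranges = cohort_age_ranges(t, r=r, e=20)
        covered = []
        for group in ("new", "middle", "old"):
            rng = ranges[group]
            if rng is not None:
                assert r <= rng[0] <= rng[1] <= 100
                covered.extend(range(rng[0], rng[1] + 1))
        assert sorted(covered) == list(range(r, 101))


class TestAging:
    def _ledger(self, policy, elderly, young):
        counts = np.zeros((2, 101))
        counts[0, 40] = young
        counts[0, 70] = elderly
        return insured_counts(_state(counts), 0.0, 1.0, 1.0,
                              np.zeros((2, 101)), policy)

    def test_share_from_counts(self, policy):
        led = self._ledger(policy, elderly=300 / 0.944, young=700 / 0.937)
        table = aging_indicators([led])
        total = table[table["sex"] == "total"].iloc[0]
        assert total["elderly_share"] == pytest.approx(0.30)

    def test_degenerate_shares(self, policy):
        all_old = aging_indicators([self._ledger(policy, 10.0, 0.0)])
        none_old = aging_indicators([self._ledger(policy, 0.0, 10.0)])
        assert all_old[all_old["sex"] == "total"].iloc[0]["elderly_share"] == 1.0
        assert none_old[none_old["sex"] == "total"].iloc[0]["elderly_share"] == 0.0

    def test_empty_ledger_series_rejected(self):
        with pytest.raises(ValueError):
            aging_indicators([])

    def test_elderly_share_rises_through_mid_century(self, fixed_run):
        table = aging_indicators(fixed_run["demography"].ledgers)
        total = table[table["sex"] == "total"].set_index("year")
        assert total.loc[2040, "elderly_share"] > total.loc[2022, "elderly_share"]
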