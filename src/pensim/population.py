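"""Cohort-component population projection and derivation of insured counts.

The national population advances one age per year with survival
P_{t,x} = P_{t-1,x-1} (1 - q_{t,x}); births come from the current-year
female population aged 15-49 through age-specific fertility rates
FR_{t,x} = TFR_t * hbar_x, split male/female by the sex ratio at birth.
No international migration.

Insured counts are carved out of the projected population through the labor
participation rate (1 - unemployment), urbanization rate, coverage rate, and
the enterprise share of urban insureds; retirees analogously with the
retiree share (retirees are outside the labor force, so no participation
factor). Female insureds split 4:1 into workers (retiring at 50) and cadres
(retiring at 55). Retirees are classified old / middle / new relative to the
1997 reform year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PolicyParams
from .series import YearSeries

__all__ = [
    "SEXES", "PopulationState", "FertilityInputs", "project_population",
    "InsuredLedger", "insured_counts", "classify_cohort",
    "cohort_age_ranges", "aging_indicators",
]

SEXES = ("male", "female")
FERTILE_AGES = np.arange(15, 50)


@dataclass
class PopulationState:
    """Age-sex population counts for one calendar year (ages 0..omega)."""

    year: int
    counts: np.ndarray        # shape (2, omega + 1), rows follow SEXES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("counts must have shape (2, n_ages)")
        if np.any(self.counts < 0):
            raise ValueError("population counts must be non-negative")

    @property
    def omega(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.counts.shape[1])
        frames = [pd.DataFrame({"year": self.year, "age": ages, "sex": sex,
                                "count": self.counts[i]})
                  for i, sex in enumerate(SEXES)]
        return pd.concat(frames, ignore_index=True)


@dataclass
class FertilityInputs:
    """Standardized fertility schedule over ages 15-49 plus TFR/SRB paths."""

    schedule: np.ndarray      # length 35, sums to 1
    tfr: YearSeries           # total fertility rate per calendar year
    srb: YearSeries           # sex ratio at birth (males per female)

    def __post_init__(self) -> None:
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.schedule.shape != (len(FERTILE_AGES),):
            raise ValueError("schedule must cover ages 15..49")
        if np.any(self.schedule < 0):
            raise ValueError("fertility schedule must be non-negative")
        if abs(self.schedule.sum() - 1.0) > 1e-8:
            raise ValueError("standardized fertility schedule must sum to 1")
        if np.any(self.srb.values <= 0):
            raise ValueError("sex ratio at birth must be positive")


def project_population(initial: PopulationState, fert: FertilityInputs,
                       q: np.ndarray, horizon: int) -> list[PopulationState]:
    """Project the population ``horizon`` years past the initial state.

    ``q`` holds death probabilities with shape (horizon, 2, n_ages), where
    q[h] applies to the transition into year ``initial.year + 1 + h``.
    Returns the projected states (excluding the initial one).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    q = np.asarray(q, dtype=float)
    n_ages = initial.counts.shape[1]
    if q.shape != (horizon, 2, n_ages):
        raise ValueError(f"q must have shape ({horizon}, 2, {n_ages})")

    states = []
    prev = initial.counts
    fem = SEXES.index("female")
    for h in range(horizon):
        year = initial.year + 1 + h
        cur = np.zeros_like(prev)
        cur[:, 1:] = prev[:, :-1] * (1.0 - q[h, :, 1:])
        fr = fert.tfr[year] * fert.schedule
        births = float((cur[fem, FERTILE_AGES] * fr).sum())
        srb = fert.srb[year]
        cur[SEXES.index("male"), 0] = births * srb / (1.0 + srb)
        cur[fem, 0] = births * 1.0 / (1.0 + srb)
        states.append(PopulationState(year=year, counts=cur))
        prev = cur
    return states


@dataclass
class InsuredLedger:
    """Insured counts for one year by retirement class, age, and status.

    Arrays are (n_classes, n_ages). Deaths are the death probability applied
    to the insured stock of the same year.
    """

    year: int
    classes: tuple
    in_service: np.ndarray
    retired: np.ndarray
    deaths_in_service: np.ndarray
    deaths_retired: np.ndarray

    def total_insured(self) -> float:
        return float(self.in_service.sum() + self.retired.sum())

    def by_sex(self, sex: str) -> np.ndarray:
        """Insured count per age summed over this sex's classes."""
        idx = [i for i, c in enumerate(self.classes) if c.sex == sex]
        return self.in_service[idx].sum(axis=0) + self.retired[idx].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.in_service.shape[1])
        rows = []
        for i, cls in enumerate(self.classes):
            for status, arr in (("in_service", self.in_service),
                                ("retired", self.retired)):
                mask = arr[i] > 0
                if mask.any():
                    rows.append(pd.DataFrame({
                        "year": self.year, "age": ages[mask], "sex": cls.sex,
                        "class": cls.name, "status": status,
                        "count": arr[i][mask]}))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["year", "age", "sex", "class", "status", "count"])


def insured_counts(pop: PopulationState, unemployment: float,
                   urbanization: float, coverage: float,
                   q_row: np.ndarray, policy: PolicyParams) -> InsuredLedger:
    """Derive in-service and retired insured counts from a population state.

    In-service, ages [e, r-1]:  P * (1-u) * ub * coverage * enterprise_share;
    retired, ages >= r:         P * ub * coverage * retiree_share
    (each scaled by the class share within its sex). Deaths are
    q_{t,x} * insured count.
    """
    for name, rate in (("unemployment", unemployment),
                       ("urbanization", urbanization),
                       ("coverage", coverage)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} rate {rate} outside [0, 1]")
    classes = policy.classes
    n_ages = pop.counts.shape[1]
    ages = np.arange(n_ages)
    in_service = np.zeros((len(classes), n_ages))
    retired = np.zeros_like(in_service)
    labor = 1.0 - unemployment
    for i, cls in enumerate(classes):
        p = pop.counts[SEXES.index(cls.sex)] * cls.share
        work = (ages >= policy.entry_age) & (ages < cls.retire_age)
        in_service[i, work] = (p[work] * labor * urbanization * coverage *
                               policy.enterprise_share)
        ret = ages >= cls.retire_age
        retired[i, ret] = (p[ret] * urbanization * coverage *
                           policy.retiree_share)
    q_row = np.asarray(q_row, dtype=float)
    deaths_is = in_service * q_row[[SEXES.index(c.sex) for c in classes], :]
    deaths_ret = retired * q_row[[SEXES.index(c.sex) for c in classes], :]
    return InsuredLedger(year=pop.year, classes=classes,
                         in_service=in_service, retired=retired,
                         deaths_in_service=deaths_is,
                         deaths_retired=deaths_ret)


def classify_cohort(join_year: int, retire_year: int,
                    reform_year: int = 1997) -> str:
    """Classify an insured as old / middle / new relative to the reform.

    Retired before the reform -> old; joined before and retired at or after
    the reform -> middle; joined at or after the reform -> new.
    """
    if join_year > retire_year:
        raise ValueError("join_year must not exceed retire_year")
    if retire_year < reform_year:
        return "old"
    if join_year < reform_year:
        return "middle"
    return "new"


def cohort_age_ranges(t: int, r: int, e: int, z: int = 1997,
                      omega: int = 100) -> dict:
    """Closed age intervals of old/middle/new retirees in year t (or None).

    old:    [r + t - z, omega]
    middle: [max(r, r + t - z - 1 - l_m), r + t - z - 1],  l_m = r - e - 1
    new:    [r, t - z + e - 1]
    all intersected with the retiree span [r, omega]. For
    t >= z - e + omega + 1 every retiree is "new".
    """
    if t < z:
        raise ValueError("the model starts after the reform year")
    l_m = r - e - 1

    def clamp(lo, hi):
        lo, hi = max(lo, r), min(hi, omega)
        return (lo, hi) if lo <= hi else None

    old = clamp(r + t - z, omega)
    middle = clamp(max(r, r + t - z - 1 - l_m), r + t - z - 1)
    new = clamp(r, t - z + e - 1)
    return {"old": old, "middle": middle, "new": new}


def aging_indicators(ledgers: list[InsuredLedger],
                     elderly_age: int = 60) -> pd.DataFrame:
    """Per-year elderly insured count and elderly share, per sex and total."""
    if not ledgers:
        raise ValueError("empty ledger series")
    rows = []
    for led in ledgers:
        totals, elders = {}, {}
        for sex in SEXES:
            by_age = led.by_sex(sex)
            totals[sex] = by_age.sum()
            elders[sex] = by_age[elderly_age:].sum()
        for sex in SEXES:
            rows.append({
                "year": led.year, "sex": sex,
                "elderly_count": elders[sex],
                "total_insured": totals[sex],
                "elderly_share": (elders[sex] / totals[sex]
                                  if totals[sex] > 0 else 0.0)})
        tot = sum(totals.values())
        eld = sum(elders.values())
        rows.append({"year": led.year, "sex": "total",
                     "elderly_count": eld, "total_insured": tot,
                     "elderly_share": eld / tot if tot > 0 else 0.0})
    return pd.DataFrame(rows)
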