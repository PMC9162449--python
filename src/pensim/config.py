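"""Policy parameters, parameter-randomization settings, and run configuration.

All scalar constants of the pension model live here so they are auditable in
one place: statutory entry/retirement ages, the 1997 reform year, annuity
divisors, contribution-wage ratio, replacement and transition coefficients,
initial fund stock, and the distributions used to randomize the nine main
parameters (unemployment, urbanization, wage growth, pension growth, ROI,
bookkeeping rate, enterprise and individual contribution rates, mortality).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "CohortClass", "PolicyParams", "DiffARSpec", "VasicekSpec",
    "LogNormalSpec", "NormalSpec", "RandomizationSpec", "RunConfig",
    "load_config", "save_config", "PARAMETER_NAMES",
]

#: The nine randomized parameters (mortality enters through its k-index path).
PARAMETER_NAMES = (
    "mortality", "unemployment", "urbanization", "wage_growth",
    "pension_growth", "roi", "bookkeeping", "enterprise_rate",
    "individual_rate",
)


@dataclass(frozen=True)
class CohortClass:
    """One retirement class: male workers, female workers, or female cadres."""

    name: str
    sex: str                 # "male" | "female"
    retire_age: int          # statutory retirement age r
    payout_months: int       # stipulated individual-account payout months m_r
    share: float             # share of this class within its sex's insureds


@dataclass
class PolicyParams:
    """Statutory and actuarial constants of the basic pension insurance model.

    Defaults follow the scheme for enterprise employees: entry at age 20,
    retirement at 60/50/55 (male / female worker / female cadre) with annuity
    divisors of 139/195/170 months, ultimate age 100, 1997 reform year,
    seniority wage growth 1.363 %/yr, transition coefficient 1.2 %, the
    contributory-to-statistical wage ratio 60.89 %, and a 71.63 % replacement
    rate for pre-reform retirees. Monetary amounts are in yuan.
    """

    entry_age: int = 20
    omega: int = 100
    reform_year: int = 1997
    seniority_growth: float = 0.01363
    transition_coef: float = 0.012
    contrib_wage_ratio: float = 0.6089
    old_replacement: float = 0.7163
    enterprise_share: float = 0.9370
    retiree_share: float = 0.9440
    pension_growth_multiplier: float = 0.8
    female_worker_share: float = 0.8   # female workers : cadres = 4 : 1
    initial_fund: float = 4_440.17e9   # accumulated fund at end-2020, yuan
    initial_wage: float = 63_182.0     # weighted average urban wage, 2019
    initial_roi: float = 0.0689        # entrusted-investment average ROI
    start_year: int = 2022
    end_year: int = 2094
    coverage_from: tuple = (2015, 0.85)
    coverage_to: tuple = (2025, 0.95)
    indexation: str = "as-printed"     # or "retirement-year"
    fixed_j: str = "mean"              # fixed-scenario bookkeeping rate: mean|median
    ck_pivot_age: int = 84
    ck_closing_rate: float = 0.8       # central death rate forced at omega

    def __post_init__(self) -> None:
        self.validate()

    @property
    def classes(self) -> tuple:
        fw = self.female_worker_share
        return (
            CohortClass("male", "male", 60, 139, 1.0),
            CohortClass("female_worker", "female", 50, 195, fw),
            CohortClass("female_cadre", "female", 55, 170, 1.0 - fw),
        )

    def coverage_rate(self, year: int) -> float:
        """Pension-insurance coverage: linear ramp, clamped outside the ramp."""
        (y0, c0), (y1, c1) = self.coverage_from, self.coverage_to
        if year <= y0:
            return c0
        if year >= y1:
            return c1
        return c0 + (c1 - c0) * (year - y0) / (y1 - y0)

    def validate(self) -> None:
        if not (0.01 <= self.transition_coef <= 0.014):
            raise ValueError(
                f"transition_coef={self.transition_coef} outside the "
                "admissible range [0.01, 0.014]")
        if not (0.6 <= self.pension_growth_multiplier <= 0.8):
            raise ValueError(
                f"pension_growth_multiplier={self.pension_growth_multiplier} "
                "outside the admissible range [0.6, 0.8]")
        if not (0.0 < self.contrib_wage_ratio <= 1.0):
            raise ValueError(
                f"contrib_wage_ratio={self.contrib_wage_ratio} must be in (0, 1]")
        for cls in self.classes:
            if not (self.entry_age < cls.retire_age < self.omega):
                raise ValueError(
                    f"class {cls.name}: need entry_age < retire_age < omega")
        if self.indexation not in ("as-printed", "retirement-year"):
            raise ValueError(f"indexation={self.indexation!r} unknown")
        if self.fixed_j not in ("mean", "median"):
            raise ValueError(f"fixed_j={self.fixed_j!r} unknown")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.start_year <= self.reform_year:
            raise ValueError("forecast must start after the reform year")


@dataclass(frozen=True)
class DiffARSpec:
    """First-order autoregression on first differences:
    dx_t = intercept + coef * dx_{t-1} + N(0, sd^2)."""

    intercept: float
    coef: float
    sd: float


@dataclass(frozen=True)
class VasicekSpec:
    """Discretized mean-reverting short rate:
    x_t = intercept + persistence * x_{t-1} + sd * N(0, 1)."""

    intercept: float
    persistence: float
    sd: float

    @property
    def stationary_mean(self) -> float:
        return self.intercept / (1.0 - self.persistence)


@dataclass(frozen=True)
class LogNormalSpec:
    """iid lognormal draws: exp(N(log_mean, log_sd^2))."""

    log_mean: float
    log_sd: float

    @property
    def mean(self) -> float:
        return float(np.exp(self.log_mean + 0.5 * self.log_sd ** 2))

    @property
    def median(self) -> float:
        return float(np.exp(self.log_mean))


@dataclass(frozen=True)
class NormalSpec:
    """iid normal draws, redrawn fresh each year."""

    mean: float
    sd: float


@dataclass
class RandomizationSpec:
    """Distributions driving the nine stochastic parameters.

    Unemployment and urbanization difference-AR processes operate in
    percentage points; wage growth in fractional units. Defaults are the
    fitted/assumed distributions of the study environment.
    """

    unemployment: DiffARSpec = field(
        default_factory=lambda: DiffARSpec(0.0, 0.5851, 0.2616))
    urbanization: DiffARSpec = field(
        default_factory=lambda: DiffARSpec(1.0476, 0.7042, 0.2815))
    wage_growth: DiffARSpec = field(
        default_factory=lambda: DiffARSpec(-0.0010, -0.3095, 0.0258))
    roi: VasicekSpec = field(
        default_factory=lambda: VasicekSpec(0.0015002, 0.95275, 0.0020282))
    bookkeeping: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(-3.173, 0.364))
    enterprise_rate: NormalSpec = field(
        default_factory=lambda: NormalSpec(0.16, 0.0204))
    individual_rate: NormalSpec = field(
        default_factory=lambda: NormalSpec(0.08, 0.0153))
    wage_growth_cap: float = 0.092   # salary growth never exceeds 9.20 %
    urbanization_cap: float = 0.8    # urbanization ceiling

    def validate(self) -> None:
        for name in ("unemployment", "urbanization", "wage_growth"):
            if getattr(self, name).sd < 0:
                raise ValueError(f"{name} innovation sd must be >= 0")
        if self.roi.sd < 0:
            raise ValueError("roi diffusion sd must be >= 0")
        if not (0.0 < self.roi.persistence < 1.0):
            raise ValueError("roi persistence must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Run configuration (file round-tripping)

@dataclass
class RunConfig:
    """Top-level configuration binding a bundle directory to a full run."""

    bundle_dir: str = "bundle"
    out_dir: str = "output"
    n_paths: int = 5000
    seed: int = 0
    policy: PolicyParams = field(default_factory=PolicyParams)
    randomization: RandomizationSpec = field(default_factory=RandomizationSpec)

    def validate(self) -> None:
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")
        self.policy.validate()
        self.randomization.validate()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if f.name == "policy":
            val = _build(PolicyParams, val or {})
        elif f.name == "randomization":
            val = _build_randomization(val or {})
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


def _build_randomization(data: dict) -> RandomizationSpec:
    sub = {"unemployment": DiffARSpec, "urbanization": DiffARSpec,
           "wage_growth": DiffARSpec, "roi": VasicekSpec,
           "bookkeeping": LogNormalSpec, "enterprise_rate": NormalSpec,
           "individual_rate": NormalSpec}
    kwargs = {}
    for key, val in data.items():
        if key in sub and isinstance(val, dict):
            kwargs[key] = sub[key](**val)
        else:
            kwargs[key] = val
    return RandomizationSpec(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent fields keep their defaults.

    Out-of-range overrides are rejected with a message naming the field.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    config = _build(RunConfig, data)
    config.validate()
    return config
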