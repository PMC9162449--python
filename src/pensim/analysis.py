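"""Post-hoc analytics: tau-scan elasticity of the accumulated balance,
the per-parameter influence index A, and decile backtracking of paths.

* The elasticity scan multiplies one parameter's entire fixed-scenario path
  by (1 + tau %) for tau in -25..-1, 1..25 (50 grid points), re-runs the
  deterministic pipeline, and classifies the direction of the end-of-horizon
  accumulated balance as same / reverse / mixed.
* The influence index fluctuates one parameter at a time (all others at
  their deterministic means), runs a Monte Carlo ensemble, and reports the
  mean yearly width of the 95 % band of the accumulated balance.
* Backtracking splits the ensemble into the bottom ("worse") and top
  ("better") deciles of the final accumulated balance and compares group
  mean parameter-value paths year by year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .config import PARAMETER_NAMES, PolicyParams

__all__ = ["SensitivityResult", "elasticity_scan", "InfluenceIndex",
           "influence_index", "influence_ranking", "BacktrackReport",
           "backtrack", "DEFAULT_TAUS"]

DEFAULT_TAUS = np.concatenate([np.arange(-25, 0), np.arange(1, 26)])

#: parameters whose scan requires re-projecting the demography
_DEMOGRAPHIC = ("mortality", "unemployment", "urbanization")

_PATH_KEY = {"unemployment": "u", "urbanization": "ub", "wage_growth": "g",
             "pension_growth": "rho", "roi": "roi", "bookkeeping": "j",
             "enterprise_rate": "b", "individual_rate": "c"}


@dataclass
class SensitivityResult:
    parameter: str
    taus: np.ndarray
    end_balance: np.ndarray       # accumulated balance at horizon end, trn
    balance_paths: np.ndarray     # (n_taus, n_years)
    years: np.ndarray
    direction: str                # same | reverse | mixed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.parameter, "tau": self.taus,
                             "end_balance": self.end_balance})


def _classify(end_values: np.ndarray) -> str:
    diffs = np.diff(end_values)
    tol = 1e-9 * max(1.0, float(np.abs(end_values).max()))
    if np.all(diffs >= -tol):
        return "same"
    if np.all(diffs <= tol):
        return "reverse"
    return "mixed"


def elasticity_scan(bundle_or_fitted, policy: PolicyParams | None = None,
                    parameter: str = "enterprise_rate",
                    taus: np.ndarray | None = None,
                    randomization=None) -> SensitivityResult:
    """Scan the accumulated-balance response to scaling one parameter path.

    The wage-growth scan scales g with the pension growth rate kept at its
    defining multiple of the scaled g; the pension-growth scan scales rho
    alone. Mortality scales the central death rates (before conversion to
    death probabilities).
    """
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}; expected one "
                         f"of {PARAMETER_NAMES}")
    policy = policy or PolicyParams()
    fitted = engine._ensure_fitted(bundle_or_fitted, policy, randomization)
    taus = DEFAULT_TAUS if taus is None else np.asarray(taus)

    horizon = policy.end_year - fitted.base_year
    base_path = engine._draw_paths(fitted, policy, horizon,
                                   deterministic=True)
    base_demog = engine.project_demography(fitted, policy, base_path["k"],
                                           base_path["u"], base_path["ub"])
    ends, paths, years = [], [], None
    for tau in taus:
        factor = 1.0 + tau / 100.0
        demog = base_demog
        scale = {}
        if parameter == "mortality":
            demog = engine.project_demography(
                fitted, policy, base_path["k"], base_path["u"],
                base_path["ub"], m_scale=factor)
        elif parameter == "unemployment":
            demog = engine.project_demography(
                fitted, policy, base_path["k"],
                np.minimum(base_path["u"] * factor, 1.0), base_path["ub"])
        elif parameter == "urbanization":
            demog = engine.project_demography(
                fitted, policy, base_path["k"], base_path["u"],
                np.minimum(base_path["ub"] * factor, 1.0))
        elif parameter == "wage_growth":
            scale = {"g": factor, "rho": factor}
        else:
            scale = {_PATH_KEY[parameter]: factor}
        out = engine.run_single_path(fitted, policy, base_path, demog,
                                     scale=scale)
        ind4 = out["table"]["ind4"].to_numpy()
        ends.append(ind4[-1])
        paths.append(ind4)
        years = out["table"]["year"].to_numpy()
    ends = np.asarray(ends)
    return SensitivityResult(parameter=parameter, taus=taus,
                             end_balance=ends,
                             balance_paths=np.asarray(paths), years=years,
                             direction=_classify(ends))


@dataclass
class InfluenceIndex:
    parameter: str
    a_index: float                 # mean yearly 95 % band width, trn yuan
    lower: np.ndarray
    upper: np.ndarray
    years: np.ndarray


def influence_index(bundle_or_fitted, policy: PolicyParams | None = None,
                    parameter: str = "mortality", n_paths: int = 500,
                    seed: int = 0, randomization=None) -> InfluenceIndex:
    """Mean yearly width of the accumulated balance's 95 % band when only
    the named parameter fluctuates."""
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    if n_paths < 100:
        import warnings
        warnings.warn("n_paths < 100 gives unstable empirical quantiles",
                      stacklevel=2)
    policy = policy or PolicyParams()
    result = engine.run_monte_carlo(bundle_or_fitted, policy,
                                    n_paths=n_paths, seed=seed,
                                    randomization=randomization,
                                    only=parameter, store_paths=False)
    arr = result.indicator_paths["ind4"]
    lower = np.quantile(arr, 0.025, axis=0)
    upper = np.quantile(arr, 0.975, axis=0)
    return InfluenceIndex(parameter=parameter,
                          a_index=float(np.mean(upper - lower)),
                          lower=lower, upper=upper, years=result.years)


def influence_ranking(bundle_or_fitted, policy: PolicyParams | None = None,
                      n_paths: int = 500, seed: int = 0,
                      randomization=None) -> pd.DataFrame:
    """Influence index A for all nine parameters, ranked by descending A."""
    policy = policy or PolicyParams()
    fitted = engine._ensure_fitted(bundle_or_fitted, policy, randomization)
    rows = [{"parameter": name,
             "a_index": influence_index(fitted, policy, name, n_paths,
                                        seed).a_index}
            for name in PARAMETER_NAMES]
    frame = pd.DataFrame(rows).sort_values("a_index", ascending=False)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.reset_index(drop=True)


@dataclass
class BacktrackReport:
    years: np.ndarray
    group_sizes: dict              # {"better": n, "worse": n}
    tables: dict                   # parameter -> DataFrame per year
    divergent: dict                # parameter -> bool

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name, tbl in self.tables.items():
            tbl = tbl.copy()
            tbl.insert(0, "parameter", name)
            frames.append(tbl)
        return pd.concat(frames, ignore_index=True)


def backtrack(result: engine.SimulationResult, min_run: int = 10,
              n_se: float = 2.0) -> BacktrackReport:
    """Compare group-mean parameter paths between final-balance deciles.

    "Worse" is the bottom decile of the final accumulated balance, "better"
    the top decile. A parameter is flagged divergent when the two group
    means differ by more than ``n_se`` pooled standard errors for at least
    ``min_run`` consecutive years.
    """
    if not result.param_paths:
        raise ValueError("the simulation result did not store parameter "
                         "paths (store_paths=False)")
    dist = engine.final_reserve_distribution(result)
    worse, better = dist["bottom_mask"], dist["top_mask"]
    n_w, n_b = int(worse.sum()), int(better.sum())
    if min(n_w, n_b) < 2:
        raise ValueError("ensemble too small to form decile groups")

    tables, divergent = {}, {}
    for name, arr in result.param_paths.items():
        mw, mb = arr[worse].mean(axis=0), arr[better].mean(axis=0)
        vw = arr[worse].var(axis=0, ddof=1)
        vb = arr[better].var(axis=0, ddof=1)
        se = np.sqrt(vw / n_w + vb / n_b)
        apart = np.abs(mb - mw) > n_se * se
        divergent[name] = bool(_longest_run(apart) >= min_run)
        tables[name] = pd.DataFrame({
            "year": result.years, "mean_worse": mw, "mean_better": mb,
            "se_pooled": se, "apart": apart})
    return BacktrackReport(years=result.years,
                           group_sizes={"better": n_b, "worse": n_w},
                           tables=tables, divergent=divergent)


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for flag in mask:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best
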