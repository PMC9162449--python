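# Methods

This note documents the model, its parameters and conventions, what the
synthetic data emulate, and the numerical and design choices behind
`pensim`. Monetary quantities are carried in yuan internally and reported in
trillions of yuan.

## Model overview

The pipeline projects the finances of a pay-as-you-go public pension scheme
with a social pooling account (employer contributions, rate b) and notional
individual accounts (employee contributions, rate c) over the calendar years
2022–2094. Each simulated future consists of

1. a mortality path (Lee–Carter index, converted to death probabilities),
2. a cohort-component population projection,
3. insured in-service/retired ledgers by retirement class,
4. yearly contribution and benefit flows (the actuarial model),
5. the six fund-reserve indicators driven by the accumulated-balance
   recursion.

The fund stock is dated end-2020 (4,440.17 bn yuan); years 2020–2021 are
bridged with the deterministic (mean) parameter recursions, so the reported
table starts in 2022 with the end-2021 stock as its opening balance.
Contributions and expenditures are booked at the start of each year; no
migration, no fiscal subsidies, no transfers of state-owned capital, no
delayed-retirement policies.

## Mortality

`fit_lee_carter` estimates ln m<sub>x,t</sub> = α<sub>x</sub> +
β<sub>x</sub>k<sub>t</sub> by the rank-1 singular-value decomposition of the
centred log surface (ordinary least squares), normalized to Σβ = 1, Σk = 0.
An optional inverse-residual-variance weighting refits by alternating least
squares; the default is unweighted because no weighting scheme is canonical.
The index forecast is a random walk with drift; the drift itself is
resampled per path from N(drift, se²) — a doubly stochastic forecast — so
ensemble fans widen with both innovation and estimation uncertainty. With
the innovation scale at zero the forecast is exactly linear.

Yearbook-style surfaces stop at age 89. Each projected year is closed out
with the Coale–Kisker method: the age-to-age log-rate increment declines
linearly from its value at the pivot age (default 84) to the increment that
forces m<sub>100</sub> = 0.8 (both configurable; the closure constants are
conventions, not estimates). Central rates convert to death probabilities by
the constant-hazard formula q = 1 − e^(−m); the ultimate age ω = 100 is
absorbing (q = 1).

## Population and insured ledgers

P<sub>t,x</sub> = P<sub>t−1,x−1</sub>(1 − q<sub>t,x</sub>) for x > 0; births
are Σ P<sup>F</sup><sub>t,x</sub>·TFR<sub>t</sub>·h̄<sub>x</sub> over ages
15–49 of the already-survived female population, split by the sex ratio at
birth, with no infant mortality applied in the year of birth (as the
recursion is written). In-service insureds aged e..r−1 are
P·(1−u)·ub·coverage·enterprise_share (enterprise share 93.70 %); retirees
are P·ub·coverage·retiree_share (94.40 %). The labor-participation factor is
not applied to retirees — they are outside the labor force; the two shares
are otherwise treated symmetrically. Coverage ramps linearly from 85 % in
2015 to 95 % in 2025 and is flat outside the ramp. Entry is at exactly
age e = 20.

Retirees are classified relative to the 1997 reform year z by the closed
age-interval formulas: old [r+t−z, ω], middle [max(r, r+t−z−1−l
<sub>m</sub>), r+t−z−1] with l<sub>m</sub> = r−e−1, new [r, t−z+e−1], each
intersected with [r, ω]. These intervals place a cohort retiring exactly in
year z with the "old people" (a one-cohort boundary convention); the
standalone classifier `classify_cohort` treats retirement at z as "middle",
the other defensible reading. The intervals partition [r, ω] for every t
(property-tested), and from t = z−e+ω+1 all retirees are "new".

## Actuarial model

Wages follow the seniority structure S<sub>t,x</sub> =
(1+s)<sup>x−e</sup>S<sub>t,e</sub> (s = 1.363 %/yr), with S<sub>t,e</sub>
pinned by the requirement that the insured-weighted mean equals the average
wage S̄<sub>t</sub>. Contributions in year t are levied on the previous
year's contributory wage d·S<sub>t−1,x−1</sub> with d = 0.6089.

Per-capita benefits at retirement year `ret`:

* old (ret ≤ z): R̂·S<sub>ret−1,r−1</sub> with R̂ = 0.7163;
* basic pension: (S̄<sub>ret−1</sub>/2)·[1 + mean contribution wage index]·
  n<sub>c</sub> %, n<sub>c</sub> = min(ret−z, r−e);
* transition pension (middle only): S̄<sub>ret−1</sub>·(mean index)·
  (r−e−(ret−z))·ε with ε = 1.2 % (admissible range 1–1.4 %);
* account annuity: 12·balance/m<sub>r</sub> (m<sub>r</sub> = 139/195/170
  months), where the balance compounds each credited contribution at the
  bookkeeping rate from its own year through the year before retirement.

Old/basic/transition pensions are indexed by the pension-growth product
Π<sub>h=ret..t</sub>(1+ρ<sub>h</sub>)/(1+ρ<sub>t</sub>), exactly as the
model's formulas print it; a config switch (`indexation =
"retirement-year"`) divides by (1+ρ<sub>ret</sub>) instead, the conventional
reading — the two differ by a per-cohort scalar. The account annuity is
nominally fixed after retirement (its formula carries no indexation
product). The individual account pays the annuity while age − r <
m<sub>r</sub>/12 (strict inequality at the boundary), pooling pays it
afterwards. Deaths refund the in-service account balance (no interest in the
death year) or, for retirees within the stipulated months, the remaining
factor max(0, m<sub>r</sub>/12 − (age−r) − 1) times the annuity.

Because the annuity is paid in whole annual installments, a cohort that
exhausts its stipulated months receives ⌈m<sub>r</sub>/12⌉ installments from
the individual account; inflow/outflow conservation therefore holds to
within one installment, which is the test's assertion. Accounting is at
cohort level (sex, class, retirement year) using cohort-average wages —
the model is written in aggregate sums, and within-cohort wage heterogeneity
is out of scope.

Two history conventions close the model where data predate the forecast:
the average-wage series is back-extrapolated geometrically at the mean
historical growth rate; pre-forecast salary-structure ratios use a uniform
in-service age distribution; pre-forecast contribution rates are held at
b = 0.16, c = 0.08 when accumulating existing cohorts' notional accounts.

## Indicators

Indicator 1 = expenditures/contributions; 2 = contributions − expenditures;
3 = max(0, −Ind2)/contributions; 4 = accumulated balance via
`accumulate(prev, i, flow)` — prev·(1+i)+flow when prev > 0, prev+flow
otherwise (deficits earn no interest, and the zero boundary uses the deficit
branch); 5 = prior-year-end balance / current expenditures when positive,
else 0; 6 = −Ind4/contributions when Ind4 < 0, blank otherwise. Trend
statistics follow the printed definitions: geometric average annual growth
for Indicator 1; (end − start)/steps for Indicators 2 and 4, where "steps"
is the number of yearly intervals (72 for 2022–2094); and (end − value at
the first gap year)/(years between) for Indicators 3 and 6.

## Stochastic parameters

Nine parameters are randomized: the mortality index plus

| parameter | process | default (study environment) | clip |
|---|---|---|---|
| unemployment u (pp) | Δu AR(1) | coef 0.5851, sd 0.2616 | u ≥ 0 |
| urbanization ub (pp) | Δub AR(1) | 1.0476 + 0.7042Δ, sd 0.2815 | ub ≤ 80 % |
| wage growth g | Δg AR(1) | −0.0010 − 0.3095Δ, sd 0.0258 | g ∈ [0, 9.2 %] |
| pension growth ρ | 0.8·g | multiplier in [0.6, 0.8] | — |
| ROI i | Vasicek | 0.0015002 + 0.95275i, sd 0.0020282, i₀ = 6.89 % | — |
| bookkeeping j | iid lognormal | ln(−3.173, 0.364) | — |
| enterprise rate b | iid normal | N(0.16, 0.0204²) | — |
| individual rate c | iid normal | N(0.08, 0.0153²) | — |

The unemployment and urbanization equations operate in percentage points
(the only units at which innovation scales of ~0.26–0.28 make sense); wage
growth is in fractions. b and c are redrawn fresh each year — their
distributions are marginal assumptions, not time-series fits. Each
difference recursion evolves on its latent level and the *emitted* value is
truncated to its bound each year; carrying post-clip differences instead
destabilizes the urbanization recursion whenever the history sits above the
cap. The short-rate recursion is fitted on daily observations and applied
per forecast year as its formula is written. The fixed-parameter scenario
sets every innovation to zero and every draw to its distribution mean
(bookkeeping at the lognormal mean exp(μ+σ²/2); a switch selects the median
instead).

With the default (printed) urbanization coefficients the recursion's
stationary yearly increment is ≈3.5 pp, so forecasts reach the 80 % ceiling
almost immediately and the urbanization influence index degenerates to
zero — the least-influential ranking of this parameter is built into the
model's own cap.

## Engine and analytics

One master seed spawns independent per-path substreams
(`numpy.random.SeedSequence.spawn`), so ensembles are reproducible and
independent of scheduling. Bands are pointwise empirical 2.5 %/97.5 %
quantiles. The final-reserve distribution sorts the end-of-horizon
accumulated balances; the bottom/top decile groups ("worse"/"better") hold
⌊n/10⌋ paths each.

The τ-scan multiplies one parameter's entire fixed-scenario path by
(1 + τ/100), τ ∈ {−25..−1, 1..25}, and re-runs the deterministic pipeline;
no re-clipping is applied to the scaled path (the scan means "the parameter
value times (1+τ%)"). Scaling wage growth keeps ρ at its defining multiple
of the scaled g; the pension-growth scan scales ρ alone; the mortality scan
scales central death rates before the q conversion. Direction classes come
from the signs of successive differences of the end-of-horizon balance over
the grid (monotone up = "same", down = "reverse", otherwise "mixed").
Directions for b (revenue only), ρ and j (expenditure only), and u are
structurally forced; the individual rate c moves both revenue (now) and
account annuities (later), so its accumulated-balance direction is
horizon-dependent — positive over short windows, and possibly negative over
the full horizon once annuity payback dominates.

The influence index fluctuates one parameter at a time (all others at their
deterministic means; wage growth and pension growth are randomized
separately, breaking the ρ = 0.8g tie for exactly these runs) and reports
A = the mean yearly width of the 95 % band of the accumulated balance.
Backtracking compares group-mean parameter paths between the worse and
better deciles; a parameter is flagged divergent when the group means differ
by more than 2 pooled standard errors for at least 10 consecutive years — an
explicit stand-in for a judgment that is usually made visually.

## Synthetic data

The generator fabricates every input series with configurable ground truth:
a rank-1 log-bilinear mortality surface (declining index, drift −1.8/yr,
innovation sd 0.4, residual sd 0.02, ages 0–89, 26 years), AR-in-differences
histories for unemployment (42 yr), urbanization (40 yr) and wage growth
(22 growth observations anchored so the last level is 63,182 yuan), 1,650
daily short-rate observations, 25 lognormal bookkeeping-rate observations,
a unimodal fertility schedule over ages 15–49 (beta-shaped, peak near 28), a
constant TFR of 1.45 with a sex ratio at birth easing 1.11→1.07 (medium-
variant-style paths; the real projection inputs are not printed anywhere, so
these are realistic placeholders and claim no correspondence), and a smooth
piecewise-linear pyramid with old-age decay emulating a low-fertility
East-Asian age structure (1.4 bn people, ~15 % aged 60+). Default recursion
truths equal the study environment's printed estimates.

What the synthetic data do *not* emulate: cohort effects or age-period
interactions in mortality beyond the single bilinear term; policy breaks in
the economic histories; within-cohort wage dispersion; correlation between
parameters (the model treats them independently); or the actual level path
of the real yearbook series. Passing tests therefore demonstrate that the
pipeline's estimators recover known structure and that the actuarial
arithmetic is exact — not that the projected indicator levels match any real
fund. The urbanization history is generated without the 80 % cap (the cap is
a forecast-time rule); with the printed coefficients it drifts above the cap,
which simply pins the forecast at 80 % from the start.

## Problem sizes and numerics

The full-scale configuration — 5,000 paths × 73 years × 101 ages — runs in
about 5 minutes on one CPU. The shipped test suite exercises the same code
at reduced sizes (80–300 path ensembles, a 2022–2045 horizon for
variational tests, 200 seeds for recovery rates), and
`scripts/acceptance.py` uses a 500-path ensemble at the full horizon and 150
paths per influence run; these sizes are the package's chosen defaults for
routine verification, and all of them are parameters, not constants.

Numerical conventions: pension tables and account balances are computed
per retirement cohort with vectorized prefix products (a consistency test
pins them to the scalar formula implementations at 1e−9); indexation
products use running cumulative products of (1+ρ); quantiles are numpy's
linear-interpolation empirical quantiles; zero-contribution years report
missing ratio indicators rather than infinities; a degenerate fit (constant
series, single-year surface, non-positive rates) raises rather than returning
garbage.

## Known limitations

* Cohort-level accounting ignores within-cohort heterogeneity in wages,
  retirement timing, and late enrolment (entry is exactly at age 20).
* The annual time step over-pays the individual-account annuity by up to
  one installment relative to a monthly model.
* The "as-printed" indexation divides by the current-year factor, which is
  unusual; the conventional variant is one switch away but changes levels.
* Parameter independence is assumed; real wage growth, ROI, and the
  bookkeeping rate are correlated.
* The printed urbanization recursion saturates its cap, making that
  parameter inert in forecasts.
* Survivor/disability benefits, administrative costs, fiscal subsidies, and
  delayed-retirement reforms are out of scope.
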