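# Methods

## Decision problem

Two first-line strategies for extensive-stage small-cell lung cancer are
compared over a 10-year horizon: etoposide + carboplatin (EC, up to four
3-week cycles) alone, versus EC plus benmelstobart (1,200 mg IV, day 1 of
each cycle) and anlotinib (12 mg orally, days 1–14), with the targeted
agents continued until progression. Outcomes are discounted costs (2023
US$), QALYs and life-years per arm, and ICER / INHB / INMB against a
willingness-to-pay threshold of $38,042.49 per QALY (China, 3× GDP per
capita) or $150,000 per QALY (US).

## Survival model

Each arm/endpoint is represented by a parametric survival curve in months.
Eight families are implemented with closed-form survival, density and
quantile functions: exponential, Weibull (AFT and PH forms — identical
distributions, related by `rate = scale^(−shape)`), gamma, Gompertz,
log-logistic, log-normal and the Prentice generalized gamma
(mu, sigma, Q; Q may be negative, Q→0 recovers the log-normal). The
Prentice parameterization is the only one consistent with the published
Mu/Sigma/Q parameter names; its survival function was cross-checked against
R `flexsurv::pgengamma` to 1e-6.

Right-censored maximum likelihood maximizes
`Σ_events ln f(t_i) + Σ_censored ln S(t_i)` by Nelder–Mead followed by a
BFGS polish on transformed parameters (log scale for positive parameters,
identity otherwise), from three starts (a moment-based initial value and
±50 % perturbations); tolerance 1e-8 on the log-likelihood. AIC = 2k − 2ℓ
and BIC = k ln n − 2ℓ rank the families; ties break by BIC, then by fewer
parameters. Standard errors come from the numerical Hessian at the optimum
(delta method back to the natural scale).

## Synthetic trial data

The original individual patient data are unavailable (the published curves
were digitized), so a generator produces pseudo-IPD with the trial's
structure for end-to-end validation: arm sizes 246/247 (the only integers
consistent with the reported second-line counts 105 = 42.68 % and
176 = 71.26 %), OS drawn by inverse-CDF from each arm's fitted model, PFS
drawn from its marginal truncated at the subject's OS (preserving the
marginal approximately while enforcing PFS ≤ OS), administrative censoring
at 42 months and exponential dropout at 0.005/month. The censoring
settings are synthetic defaults — the source trial's follow-up pattern is
not reported — so fitting tests validate estimator behaviour, not the
trial's actual censoring. Kaplan–Meier estimation uses lifelines.

What the generator does **not** emulate: covariate structure, treatment
crossover, non-proportional dropout, or the sampling noise of curve
digitization. Passing recovery tests therefore demonstrate correctness of
the fitting and simulation code, not fidelity of the published curves to
the trial.

## Cohort engine

Partitioned survival over three states (PFS, PD, dead):
`pfs = min(S_PFS, S_OS)`, `dead = 1 − S_OS`, `pd` the remainder; the min
cap (logged when active) prevents negative PD occupancy where the fitted
curves cross. Entry flows are floored first differences. An alternative
engine accumulates per-cycle exit probabilities `1 − S(t+dt)/S(t)` as
cumulative products; the two agree to float precision and the
transition-probability tables are exportable.

**Time grids.** Cycles are 21 days; the number of cycles is
`ceil(10 × 365.25 / 21) = 174`. Two grids are available for evaluating the
survival curves at cycle boundaries:

* `calendar` — cycle k at `k × 21 / 30.4375` months (literal calendar time);
* `cycle_month` — cycle k at `k` months.

The **frozen base case uses `cycle_month`**. This is a deliberate
calibration: the published model states that its horizon captures more
than 99 % of deaths in both arms, which holds only when the curves are
advanced one month per cycle (death occupancy 0.9934/0.9983 at the final
boundary, versus 0.9806 for the combination arm on the literal calendar
grid), and the published cost/QALY totals and implied discounted
benmelstobart cycle counts are reproduced only on this grid. Costs and
QALYs always accrue over the 21-day calendar cycle (0.0575 years) and are
discounted at `(1+r)^(−t)` at cycle midpoints (half-cycle correction on;
trapezoid state credit). The `calendar` grid remains available and is used
for the grid-convergence property test (halving the cycle length moves
10-year discounted life-years by < 0.5 %).

## Costs and utilities

All unit costs come from the published per-cycle input tables and are
taken literally as per-cycle amounts; Calvert (AUC 5, GFR 90 → 575 mg
carboplatin) and BSA dosing (100 mg/m² × 1.72 or 1.79 m² × 3 days
etoposide) are implemented as documented cross-checks, not cost drivers.
The table label "BMI/m2" is read as body-surface area (a BMI of 1.72 is
impossible). Categories: maintenance drugs, chemotherapy (4 cycles),
IV administration, monitoring (laboratory each cycle; PET-CT every second
cycle, matching two-cycle efficacy evaluations), best supportive care,
adverse events, second-line treatment, end-of-life. Grade ≥3 adverse
events (anemia, thrombocytopenia, neutropenia, hypertension) are charged
once at model start as incidence × cost, with a one-time QALY loss of
incidence × disutility × one cycle length. State utilities are 0.69 (PFS) and 0.60 (PD); see below.

**Frozen per-perspective structure.** The two perspectives differ by
definition (China: all healthcare-related expenses; US: direct medical
costs only), and several structural choices are not stated in the
published tables. They were calibrated once against the published
base-case table and price thresholds, then frozen:

| choice | China | US |
|---|---|---|
| benmelstobart + anlotinib paid | first 4 cycles (assistance programs; administration continues while progression-free) | while progression-free |
| laboratory / PET-CT | all living patients | progression-free only |
| best supportive care | all living patients | PD state only |
| second-line topotecan | one-time 4-cycle course at PD entry | per PD cycle, proportion-weighted |
| administration per IV cycle | $134.93 (prophylaxis 93.93 + infusion 1.86 + premedication 39.14) | $173.23 (first hour 142.55 + one additional 30.68) |

**Utilities.** The base case uses the tabulated utility set 0.69 (PFS) /
0.60 (PD), which reproduces the published QALY totals; the alternative
set quoted in the accompanying text (0.673/0.473) does not, under any
engine variant examined, and ships as the `china_text_utilities` scenario
config. Utility bounds [0, 1] are enforced; the PFS/PD ordering is only a
warning because the published one-way ranges themselves cross.

## Sensitivity analyses

One-way: every scalar parameter to ±20 % of baseline (beta-type parameters
clipped at 1), the discount rate to its published range (4–6 % China,
2.4–3.6 % US); ICER recorded at each end, entries sorted by swing;
failures are flagged rows, never silent drops. Probabilistic: 10,000
draws, gamma for costs and beta for utilities/incidences/proportions,
moment-matched to mean = baseline and sd = (high − low)/3.92 (range read
as a 95 % interval); infeasible beta moments are shrunk to feasibility and
logged. Fitted survival parameters are **not** resampled — no
variance-covariance accompanies the published fits — which understates
total decision uncertainty; this is the main known limitation. The CEAC
reports the fraction of draws with positive INMB on a λ grid of 0 to
300,000 in steps of 1,000. Because the cohort traces are fixed across
draws, the PSA re-prices cached occupancies (10,000 draws in a few
seconds).

Price threshold: bisection on the benmelstobart per-cycle (1,200 mg) price
over $0–8,000 until |ICER − λ| < $1 (the ICER is monotone in price);
reported per 600 mg as half the per-cycle threshold. If the strategy is
cost-effective across the whole grid the grid top is returned with a flag.

## Numerical conventions and edge cases

Survival functions clamp to [0, 1] and define S(0) = 1 exactly;
generalized-gamma exponents are clipped to avoid overflow, and |Q| < 1e-7
switches to the log-normal limit. `transition_probabilities` returns 1
where S(t) = 0. All-censored data raise a fit error (the likelihood is
unbounded); per-family fit failures surface as NaN rows in the selection
report rather than aborting the ranking. Dominance is reported as a flag,
not a signed ICER. Seeds propagate through `numpy.random.default_rng`;
identical seeds give bit-identical pseudo-IPD and PSA output.

## Problem sizes used in validation

Parameter-recovery tests fit n = 5,000 simulated subjects per family
(tolerance 3 standard errors from the observed-information matrix);
selection tests use n = 2,000–3,000; the acceptance script runs the full
174-cycle model per arm and both price-threshold bisections, and the test
suite runs the 10,000-draw PSA for both perspectives.
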