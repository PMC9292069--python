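# Methods

## The model

`pandemic_cea` is a condition-agnostic cost-effectiveness framework for the
*indirect* health harms of a pandemic — conditions such as depression,
excessive alcohol use, or homelessness whose prevalence rose because of the
pandemic rather than because of infection itself — and for mitigation
interventions aimed at them. Each condition is modeled independently in two
sections.

**Added burden.** Given a pre-pandemic adult prevalence `p` and a pandemic
relative risk `RR`, total prevalence during the pandemic is `p·RR` and excess
prevalence is `p·(RR − 1)` (floored at zero, with a warning, for `RR < 1`;
`p·RR > 1` is rejected as implausible). Scaled to `N` adults (default one
million), excess cases generate QALY losses and societal costs through
per-episode values split into a short-term and a long-term component:

```
excess_QALYs_short = p·(RR−1)·N · q_st · s
excess_QALYs_long  = p·(RR−1)·N · q_lt · s / (1+r)^T
excess_cost_short  = p·(RR−1)·N · c_st
excess_cost_long   = p·(RR−1)·N · c_lt / (1+r)^T
```

where `q`/`c` are QALY losses and costs per episode, `r` is the annual
discount rate (default 3%), `T` the mean lag of long-term outcomes (default
10 years, a point mass — long-term outcomes are discounted once at the mean,
not integrated over a lag distribution), and `s ∈ (0, 1]` a severity
multiplier on *health outcomes only* (the bundled homelessness scenario uses
`s = 0.25`: acute pandemic-related homelessness is assumed to have one quarter
of the literature-derived health consequences of chronic homelessness).
Whether `s` also scales costs is a flag, off by default, because the severity
adjustment is defined in terms of health-outcome values. Per-episode QALY
losses may be supplied directly or assembled from a morbidity/mortality
decomposition, `u·d + f·Q` (utility decrement × duration + case fatality ×
QALYs per death); the two routes are algebraically identical and tested as
such. One affected adult corresponds to one episode: prevalence is treated as
period prevalence over the modeled episode window.

**Intervention outcomes.** An intervention reaches `coverage` (default 20%)
of *all* affected adults — pre-existing and pandemic-attributable cases alike
— and removes the condition in `efficacy` of participants:

```
participants  = p·RR·N · coverage
cases_averted = participants · efficacy
```

One averted case avoids both per-episode components (QALYs with the severity
multiplier, long-term discounted exactly as in the burden section). The
intervention cost, `participants · cost_per_participant`, is charged once in
year one, undiscounted — the modeled programs are short in duration. QALYs
gained are reported as lifetime totals (short + discounted long); only costs
are phased over time.

**Accrual schedule and net savings.** Averted costs accrue over time:
by default 60/90/95% of short-term and 0/20/50% of long-term averted costs are
incurred by 1/3/10 years, and 100/100% over the lifetime. Net savings at
horizon `h` are

```
net(h) = f_st(h)·averted_short + f_lt(h)·averted_long_discounted − intervention_cost
```

The schedule validates that fractions are in [0, 1], nondecreasing across the
horizon order, and end at (1, 1) for the lifetime entry — which makes net
savings nondecreasing across horizons for any valid schedule.

**Cost-effectiveness classification.** Versus doing nothing: positive lifetime
net savings with QALYs gained → *dominant*; a net lifetime cost with QALYs
gained → an ICER, net cost per QALY gained; zero QALYs gained → flagged
undefined. Dominance is invariant to population scale (both numerator and
denominator are linear in `N`).

## Calibration of the bundled scenarios

Six scenarios ship with the package (depression, intimate partner violence,
homelessness, excessive alcohol use, opioid use disorder, stroke mortality),
reconstructed from published per-million-adult summary values (2020 USD)
stored in `data/bundled_scenarios.yaml`. The underlying per-episode parameter
lists are not public, so calibration deterministically back-solves them:

1. The printed per-episode cost is interpreted as the *undiscounted*
   short + long cost per episode, which pins down the excess caseload:
   `excess = (cost_ST + cost_LT·(1+r)^T) / cost_per_episode`, and hence the
   baseline prevalence `p = excess / ((RR−1)·N)`.
2. Per-episode costs and QALY losses divide the printed excess cells by the
   caseload (QALY cells additionally by the severity multiplier; long-term
   cells are un-discounted through `(1+r)^T` before storage so the forward
   model re-discounts them).
3. `cost_per_participant` divides the printed program cost by the participant
   count, and `efficacy` is set so cases averted reproduce the printed QALYs
   gained. Efficacy is calibrated from the health target rather than the
   monetary ones because it is a health parameter; the monetary outputs then
   follow with no further freedom.

This choice is self-validating in three ways. First, the recovered baseline
prevalences are epidemiologically plausible without being fitted to anything
(depression 22.1%, excessive alcohol use 7.9%, IPV 6.4%, opioid use disorder
1.4%, homelessness 0.47%, at-risk-of-in-hospital-stroke-death 0.0095%).
Second, the recovered efficacies land on round values (0.250, 0.210, 0.150,
0.390) as literature-derived effect sizes would. Third — the genuine
out-of-sample check — the 3-year net savings are *never used* in calibration,
yet the forward model reproduces every printed 3-year cell to within the
tables' own rounding.

**Tolerances.** Calibrated cells (burden, QALYs gained, program cost) are
reproduced exactly and checked at 0.5% relative tolerance. Net-savings cells
are differences of ≈$100M accrued quantities each printed at $0.1M resolution,
so rounding of the printed inputs propagates to roughly ±$0.3M absolute in the
prediction; net-savings targets are therefore checked at
max(1% relative, 3 × printed rounding unit), i.e. ±$0.3M for the $M-scale
rows and ±$1,500 for the stroke row. Observed discrepancies are far inside
these bands (largest: ±$0.12M).

The stroke scenario has no long-term component (its long-term cells are
absent) and uses 100% coverage of the at-risk pool, with the fixed campaign
cost spread per person (`stroke_reach_adjustment`).

`backsolve_averted_costs` inverts the accrual schedule: given an intervention
cost and net savings at two horizons it solves the 2×2 linear system for the
averted short/long costs (erroring on singular fraction matrices and warning
on negative solutions). Forward-predicting a third horizon from that solution
is exact for model-generated inputs — a property checked on 1,000 random
scenarios — and reproduces the published held-out 3-year cells within 1%.

## Sensitivity analysis

**PSA.** Monte-Carlo propagation over user-declared parameter distributions.
Each draw jointly resamples all listed parameters (independently — no
correlation structure is modeled), reruns burden → intervention end-to-end,
and the outputs (lifetime QALYs gained, net savings per horizon) are
summarised by mean and an empirical 95% prediction interval (2.5/97.5
percentiles, linear "type-7" interpolation). Draws are generated from
`numpy.random.default_rng(seed)`; identical seed and configuration give
bit-identical summaries. Sampled values outside a parameter's domain are
resampled and counted; draws producing an invalid model state (e.g. total
prevalence > 1) are rejected and redrawn, with a hard error if rejections
exceed half of all attempts.

Distribution families follow health-economics convention: relative risks
lognormal, probabilities beta, costs gamma — each matched so its 2.5/97.5%
quantiles equal a supplied 95% interval (solved in closed form for the
lognormal, by root-finding on the quantile function for beta and gamma).
Point, uniform and modified-PERT families are also available. For the
lognormal the two degrees of freedom are spent on the interval bounds, so the
implied median is the geometric mean of the bounds and can differ from the
deterministic base-case value when the published range is asymmetric
(depression: base RR 1.37, implied median 1.75); matching the stated range
was preferred over re-centering on the base case, since the range is the only
published uncertainty statement. The default PSA set, when no distributions
are configured, varies only the relative risk on its published range —
the only parameter with a published uncertainty interval; ranges for costs
and efficacy must be supplied by the user.

The published prediction-interval endpoints for the original analysis are not
reproduction targets: the distribution families and the set of varied
parameters behind them were never published. The PSA machinery is instead
verified by construction: all-point-mass PSA equals the deterministic
pipeline (percentiles exactly; the mean to machine precision), the
lognormal sampler empirically recovers its interval at n = 10⁶ within 1%,
and a uniform distribution on a linearly-entering parameter yields a PSA mean
converging to the deterministic run at the distribution mean.

**One-way DSA.** Deterministic rerun per value of a single dotted parameter
path with all else at base case. Setting a relative risk outside the stored
uncertainty range widens the range metadata rather than erroring (required
for the bundled homelessness sweep 6.67 → 1.67). Quartering the homelessness
RR shrinks QALYs gained (1,648 → 413) and all savings from the 3-year horizon
on, turns year 1 into a net cost, and leaves rent subsidies dominant. The
year-1 net is *not* monotone in RR: the program cost scales with the eligible
pool, so at low RR the year-1 net cost shrinks in magnitude while remaining
negative.

## Random scenario generator

`random_scenario(seed)` draws internally consistent scenarios for
property-based testing: baseline prevalence log-uniform on 0.001–0.3, RR
uniform on [1, min(8, 0.99/baseline)] (so total prevalence stays below 1),
per-episode costs log-uniform on 10³–10⁵ USD, QALY losses log-uniform on
0.01–5, efficacy uniform on 0.05–0.8, coverage uniform on 0.05–1, and a
severity multiplier below 1 in a quarter of draws. These ranges bracket the
six calibrated scenarios. The generator emulates the *arithmetic* envelope of
realistic condition/intervention pairs, not their empirical joint
distribution — costs and QALY losses are drawn independently, whereas real
conditions correlate them — so property tests passing on these scenarios
demonstrate algebraic correctness (round-trips, monotonicity, linearity), not
epidemiological realism.

## Numerical choices and edge cases

- All arithmetic is double precision; no rounding happens inside the model.
  Human-readable tables round money to $0.1M with net costs in parentheses;
  JSON outputs carry full-precision numbers with an explicit `USD_2020` units
  field and round-trip exactly.
- `RR = 1` yields exactly zero excess burden; `RR < 1` floors excess at zero
  with a warning; `baseline·RR > 1` raises.
- `discount(v, r, 0) = v` exactly; negative years or rates raise.
- The accrual back-solver rejects fraction matrices with determinant below
  1e-12 and warns on negative solved costs.
- Configuration parsing rejects unknown keys everywhere (catching typos) and
  names the offending key and constraint in every error.
- Zero QALYs gained makes the CE classification "undefined" rather than
  dividing by zero.

## Problem sizes

The bundled analysis is a six-scenario deterministic computation — effectively
instantaneous. Default PSA draw count is 10,000; the test suite uses 300–4,000
draws for distributional checks and 10⁶ direct sampler draws for
quantile-recovery checks, sizes at which Monte-Carlo error is far below the
asserted tolerances. Property sweeps use 1,000 random scenarios.

## Known limitations

- No disease progression or state-transition modeling; each condition is a
  one-shot prevalence/episode model, and conditions do not interact.
- No productivity losses or spillover costs (e.g. onto children); costs are
  direct medical + non-medical only, from a societal perspective.
- Intervention costs are single-charge in year one even for programs that
  plausibly recur over multiple years.
- No comparison between alternative interventions for the same condition and
  no cost-sharing across simultaneously deployed interventions.
- PSA samples parameters independently; a rank-correlation structure is not
  implemented.
- Calibrated baseline prevalences and efficacies are back-solved, not
  transcribed from primary sources; they are internally consistent with the
  published summary tables but should not be cited as literature values.
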