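# pandemic-cea

Cost-effectiveness modeling of the *indirect* health harms of a pandemic —
depression, excessive alcohol use, opioid use disorder, homelessness, intimate
partner violence, stroke mortality — and of evidence-based interventions that
mitigate them. Built for health-economics and public-health analysts who need
rapid, transparent estimates of what failing to mitigate costs, and what
mitigation returns, per million adults.

## Model

Each condition is modeled in two sections.

**Added burden.** With pre-pandemic prevalence *p*, pandemic relative risk
*RR*, and population *N* adults, excess cases are *p·(RR−1)·N*. Each excess
case carries short-term and long-term per-episode QALY losses and societal
costs (2020 USD); long-term consequences occur at a mean lag of *T* = 10 years
and are discounted at *r* = 3%/year:

    excess_QALYs = p(RR−1)N · s · (q_st + q_lt/(1+r)^T)
    excess_cost  = p(RR−1)N · (c_st + c_lt/(1+r)^T)

with *s* a severity multiplier on health outcomes (0.25 for acute,
pandemic-related homelessness). QALY losses combine morbidity (utility
decrement × duration) and mortality (case fatality × QALYs lost per death).

**Intervention outcomes.** An intervention reaches a fraction (default 20%) of
*all* affected adults and removes the condition in `efficacy` of participants.
Averted cases avoid both per-episode components; program costs are charged
once, undiscounted, in year one. Averted costs accrue over time
(60/90/95% of short-term and 0/20/50% of long-term costs by 1/3/10 years), so
net savings at horizon *h* are

    net(h) = f_st(h)·averted_short + f_lt(h)·averted_long − program_cost

An intervention that saves money over the lifetime while gaining QALYs is
**dominant** versus doing nothing; otherwise a net cost per QALY gained (ICER)
is reported. Probabilistic sensitivity analysis (Monte Carlo over lognormal /
beta / gamma / PERT / uniform parameter distributions matched to 95%
intervals) and one-way deterministic sweeps quantify uncertainty.

Six calibrated scenarios are bundled, reconstructed by deterministically
back-solving published per-million summary values (see
[docs/methods.md](docs/methods.md) for the calibration and its out-of-sample
validation).

## Worked example

Run the six bundled scenarios for one million adults:

```sh
pandemic-cea run --out out/
```

```
                Condition                                   Intervention QALYs Gained Intervention Cost CE (lifetime)   Net 1y   Net 3y  Net 10y
      Depressive symptoms Cognitive-behavioral therapy + antidepressants       12,707            $44.5M      Dominant   $61.5M  $161.7M  $241.5M
Intimate partner violence                       Nurse-family partnership       22,186           $164.7M      Dominant ($69.8M)    $5.2M   $54.6M
             Homelessness                                 Rent subsidies        1,648            $47.1M      Dominant  ($4.7M)   $45.4M   $92.4M
    Excessive alcohol use               Screening and brief intervention        4,835             $6.6M      Dominant    $9.0M   $52.5M  $107.5M
      Opioid use disorder                  Medication-assisted treatment        5,674            $56.2M      Dominant ($36.1M) ($10.5M)   $14.5M
         Stroke mortality                      Public awareness campaign          388           $14,350      Dominant $147,498 $228,422 $241,909
```

Reading the depression row: treating 20% of adults with depressive symptoms
(CBT + antidepressants, $44.5M program cost) gains 12,707 QALYs and is
dominant — by year 1 the averted medical and non-medical costs already exceed
the program cost by $61.5M, growing to $241.5M by year 10. Parentheses mark
net costs: nurse-family partnership for IPV costs $69.8M net in year 1 but
saves $54.6M by year 10 (and 22,186 QALYs, the largest health gain of the
six). All six strategies are dominant over the lifetime.

The command also writes `burden.csv`, `interventions.csv` (one row per
condition × horizon) and `summary.json` (full precision, with version, seed
and config hash embedded).

A one-way sensitivity sweep on the homelessness relative risk:

```sh
pandemic-cea dsa --scenario homelessness --parameter condition.rr_pandemic --values 6.67,1.67 --out out/
```

```
 value  qalys_gained_total  net_savings_year1  net_savings_year3  net_savings_year10  net_savings_lifetime ce_class
  6.67         1648.000000      -4.734859e+06       4.541123e+07        9.238693e+07          1.683261e+08 dominant
  1.67          412.617691      -1.185489e+06       1.136983e+07        2.313136e+07          4.214463e+07 dominant
```

Even if homelessness rose only 67% instead of 567%, rent subsidies remain
dominant — savings just arrive later (year 1 is a net cost; the 3-year
horizon is positive).

Other subcommands: `psa` (probabilistic sensitivity analysis, seeded and
bit-reproducible), `scenarios` (list/export the bundled back-solved
parameters), `validate` (check a YAML/JSON configuration without running).
Custom conditions and interventions are defined in the same configuration
document; unknown keys are rejected with the offending key named.

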