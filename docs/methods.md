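# Methods

This note documents the model implemented in `smokesim`, its assumptions,
default parameters, numerical choices, and the limits of what the synthetic
input bundle can demonstrate.

## Model structure and within-year order

The simulator is a deterministic, discrete annual-time compartmental model.
State is a grid of expected counts by single age (0–99 plus an open 100+
bin), gender, and smoking status: never smoker, current smoker, or former
smoker by completed years since quitting (yearly bins 1–15 and an absorbing
16+ bin). Yearly bins are the finest resolution any duration-dependent
relapse or relative-risk schedule can need; coarser groupings aggregate from
them.

The within-year order of operations is fixed and tested:

1. policy effects (one-off prevalence shocks for level changes; sustained
   multipliers on initiation and cessation),
2. Markov smoking transitions (initiation, cessation, relapse and
   years-quit bin advancement),
3. status-specific mortality, from which smoking-attributable deaths (SADs)
   are recorded,
4. aging (deaths → aging → births; the top bin accumulates survivors, and
   births computed from start-of-year female counts enter age 0 as never
   smokers).

Reported prevalence for year *t* is taken after step 1, so a policy's
implementation-year reduction is visible in the year it takes effect; SADs
for year *t* are the deaths occurring during that year. The smoking
transition step itself is a pure Markov operation with no aging or
mortality, which lets it be verified in isolation against a per-individual
stochastic simulation (`smokesim.microsim`).

## Smoking transitions

* **Initiation** is permitted through age 29, where uptake levels off, and
  is measured as the net age-on-age prevalence difference — this year's
  rate at age *a* minus last year's rate at age *a−1* — converted to a
  probability among never smokers. Negative differences are clamped to
  zero; the clamp is what guarantees non-negative compartment counts, and
  the declining part of the cross-sectional curve is instead produced by
  cessation. No initiation is imputed below the first measured age.
* **Cessation** is tracked strictly above age 29 as an annual first-quit
  probability, 5%/year in the default bundle before relapse.
* **Relapse** depends on years since quitting. The packaged default
  schedule declines monotonically from 12%/year in the first year of
  abstinence to 0.5%/year at 16+ years. It is a documented, configurable
  placeholder with the canonical qualitative shape (high early relapse,
  near-permanent quitting after many years), not a claim about any
  particular survey.

## Mortality attribution

All-cause mortality per cell is split by status by solving for the
never-smoker rate that recombines exactly (to machine precision; tested at
1e-12) with the cell's status shares and relative risks. Because the
never-smoker rate is re-solved per cell per year, attribution adapts as
prevalence changes. SADs are the excess deaths of current and former
smokers over the never-smoker rate, counted at ages 30+ — the default
relative risks are 1 below 30, so younger smokers accrue no attributable
deaths until their cohort reaches 30.

Default relative risks: current smokers 2.1 at ages 30+ (a typical
high-income-cohort all-cause value), former smokers decaying linearly from
2.1 at one year quit to 1.0 at 16+ years. Both are configurable;
`RelativeRisks.scaled()` supports sensitivity runs such as rescaling the
excess risk to a current-smoker RR of 1.6, which strictly lowers SADs
(tested as a direction, not a magnitude).

If a cell's overall mortality and relative risk imply a status-specific
rate above 1, the rate is clamped to 1 with a runtime warning; the default
bundle's mortality cap (0.45 in the top bin) keeps every cell away from
this regime.

## Policy engine

Seven domains: price/tax, smoke-free air, mass media, marketing bans,
health warnings, cessation treatment, youth access. Effect sizes at full
strength:

| domain | prevalence | initiation | cessation |
|---|---|---|---|
| price, per 10% real increase | 6/4/2/1% by age band 15–17/18–24/25–34/35+ | same | same (18+) |
| smoke-free air (additive) | worksite 9%, restaurant 3%, bar 1.5%, other 1% | same | same |
| media campaign | 3.25/1.8/0.5% (high/moderate/low), doubled alongside other policies | same | same |
| marketing ban | 10/6/2% (comprehensive/total/weak) | 12/8/2% | +6/+4/0% |
| warnings | 4/1% (strong/weak) | 4/1% | +10/+2% |
| cessation treatment (full) | 6.75% | — | +55% |
| youth access | 30/15/3% under 16, 20/10/2% ages 16–17 (strong/moderate/low) | same | — (under-18 only) |

Design choices where the design was genuinely open:

* **Combination.** Effects combine multiplicatively,
  `E = 1 − Π(1 − e_d)`: commutative, associative, bounded below 100%, and a
  domain already partly implemented leaves less headroom for a stronger
  level (incrementality: moving from level L to L contributes zero).
  Cessation *increases* compose as a product of `(1 + e_d)` factors.
* **Implementation-year vs sustained semantics.** The combined prevalence
  effect `E(t)` is computed each year relative to base-year levels; the
  one-off prevalence shock applied in year *t* is the ratio
  `(1 − E(t))/(1 − E(t−1))`. A policy implemented once therefore produces
  exactly one prevalence reduction, yearly price changes produce yearly
  shocks, and a weakening level (e.g. falling real prices) returns recent
  quitters (bin 1, clamped to those available) to smoking. Rate multipliers
  `(1 − E_init)` and `(1 + E_cess)` apply in every year at the sustained
  level, including the implementation year.
* **Prevalence shocks quit into bin 1.** Smokers removed by a prevalence
  effect must go somewhere; quitting is the mechanism, so they enter the
  first years-quit bin and are subsequently exposed to relapse.
* **Price functional form.** Constant-elasticity compounding
  `1 − r^(ln(1−x)/ln 1.1)` makes the per-10% statement exact at r = 1.1,
  compounds sensibly across the 2.3-fold observed price range (linear
  extrapolation would exceed 100% at high ratios), and yields a negative
  reduction for price falls. Ages below 15 take the 15–17 band; the
  under-18 price and youth-access effects act on prevalence and initiation
  only.
* **Enforcement** scales smoke-free and marketing effects linearly from 50%
  of full strength at score 0 to 100% at score 1 (the qualitative statement
  "weakened by as much as 50%" pins only the endpoints).
* **Media synergy.** The media effect doubles in any year in which at least
  one other domain sits above its base-year level; the doubling is applied
  to all three channels (prevalence, initiation, cessation) uniformly.
* **Bound scenarios** rescale each domain's effect sizes before
  combination: ±50% for smoke-free, marketing, warnings and media; −50%/
  +100% for cessation treatment; 0%/+50% for youth access; ±25% for price.
  Bounds propagate through entire runs, giving nested prevalence paths
  (upper ≤ central ≤ lower, verified every year).

## Scenarios

The counterfactual freezes every domain and the real price at base-year
levels; by construction its combined effect is identically zero, and a
frozen run is bit-for-bit identical to a run with the policy engine
disabled (tested). Single-policy scenarios let one domain follow its actual
path with all others frozen. Contribution shares divide each single-policy
relative prevalence reduction by the sum over domains (shares total 100%
before rounding) — the multiplicative combination makes attribution
meaningful only relative to that sum. The maximal-policy schedule raises
every domain to its top, fully enforced level from a start year and raises
the tax share of retail price from 60% to 75%; with full pass-through and a
constant pre-tax price this multiplies the real price by 0.40/0.25 = 1.6.
Pass-through is a modelling decision: the conversion from a tax share to a
price change is not determined by the tax statement alone.

## Synthetic input bundle

`make_brazil_like_fixture` generates the packaged study conditions:

* **Baseline smoking (1989).** Current-smoking prevalence is flat within
  the printed survey age groups (male 34.1/48.4/45.5/33.5%, female
  24.2/31.4/23.7/18.4% for 18–24/25–44/45–64/65+), with a linear uptake
  ramp from age 12 to the 18–24 level. The 18+ aggregates must also equal
  the printed 43.3% (male) and 27.0% (female); since aggregates depend on
  population weights, the 18+ age distribution is exponentially tilted per
  gender and the tilt parameter solved by bracketed root finding (the
  aggregate is not monotone in the tilt, so the bracket is found by sign
  scan). Former-smoker shares rise linearly with age to a 28% cap and are
  spread over years-quit bins geometrically (ratio 0.85) with the tail in
  16+.
* **Transitions.** Cessation 5%/year above 29; initiation derived from the
  baseline curve assuming a stationary pre-base-year prevalence profile;
  the default relapse schedule above.
* **Demography.** Gompertz-like mortality with an infant bump and a male
  excess, capped at 0.45; single-peak fertility with total fertility 2.85;
  a quasi-stable pyramid (survivorship discounted by 2.5%/year past
  growth) scaled to 145 million. These are smooth placeholders for census
  inputs: they make the bundle internally consistent, not demographically
  accurate.
* **Policy history.** Real prices interpolate 1.0 → 2.0 (1998) → 2.3
  (2010), flat thereafter. Milestones: weak marketing restrictions already
  at base; 1996 weak warnings, low-intensity media, partial smoke-free
  coverage, first cessation-treatment availability, weak youth-access
  enforcement; 2000 smoke-free and marketing strengthening; 2001 strong
  (graphic) warnings; 2002/2006 media escalation; 2004 broader cessation
  treatment; 2005 comprehensive marketing ban; 2007 broader smoke-free
  coverage and moderate youth enforcement. The milestone *years* follow the
  documented policy history; the coverage fractions and enforcement scores
  within them are synthetic, chosen once.

Everything is deterministic given the seed (the construction is
closed-form; the seed seeds only the stochastic oracles and any downstream
sampling).

**What passing tests do and do not show.** The bundle demonstrates the
machinery: accounting identities, invariants, oracle agreement, and
qualitative behaviour (policy-attributable declines near the published
magnitudes, price dominating the decomposition). It does not reproduce real
survey demography, the true former-smoker duration distribution, cohort
relative-risk age patterns, or migration; absolute death counts are
properties of the synthetic bundle only.

## Numerical choices and degenerate inputs

* Counts are expected values (floats); compartment sums are conserved by
  the transition step to 1e-9 relative and checked after every operation.
* Negative compartment counts beyond −1e-9 raise an internal error;
  tiny negative round-off is clipped to zero.
* Adjusted transition rates outside [0, 1] and status-specific mortality
  above 1 are clamped with a runtime warning.
* Empty cells in mortality partitioning keep the overall rate for all
  statuses.
* Prevalence aggregation over an empty selection is an error, not NaN.
* The scenario loop is pure floating-point arithmetic with no randomness:
  identical inputs give bitwise-identical outputs.

## Problem sizes

The default run simulates 101 ages × 2 genders × 18 smoking compartments
over 62 years (1989–2050); the full scenario set (counterfactual, three
bound variants, seven single-policy runs, status quo and maximal-policy
comparison) completes in a few seconds on one CPU. The stochastic oracles
use 10⁵ individuals (smoking chain) and 200 replicates (demography), sized
so that three Monte Carlo standard errors resolve discrepancies of about
0.5% in compartment fractions.

## Known limitations

* No migration, no income/affordability feedback on price elasticity, no
  social-norm feedbacks (policy effects are unidirectional), no
  second-hand-smoke or maternal-smoking mortality, no smoking intensity
  (cigarettes/day), no cause-specific mortality.
* Demographic rates are held constant over the projection; there is no
  time trend in mortality or fertility.
* The relapse and relative-risk defaults are placeholders standing in for
  survey- and cohort-derived schedules; conclusions sensitive to their
  exact values should treat them as free parameters.
* Monotonicity of prevalence in policy levels holds for sustained level
  increases; a level raised and later lowered by a subsequent milestone
  is, by design, a weakening and can raise prevalence relative to the
  unmodified schedule.
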