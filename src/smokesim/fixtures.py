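"""Self-consistent synthetic input bundles.

The original model was driven by national census demography, a 1989
household smoking survey, a Netherlands survey of former smokers by years
since quitting, and US cohort-study relative risks.  None of those are
distributed as machine-readable files, so this module generates synthetic
stand-ins that are internally consistent and reproduce the quantities that
are printed: the 1989 smoking prevalences by age group and gender (including
their 18+ aggregates), an initial adult cessation rate of about 5% per year,
a real cigarette price doubling by 1998 and reaching 2.3x the 1989 level by
2010, and the policy milestone years of the 1990s and 2000s.

Demographic curves (population pyramid, mortality, fertility) are smooth
parametric shapes chosen to look like a middle-income country around 1990;
they are documented placeholders, so absolute death counts from this bundle
are not claims about Brazil.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .demography import DemographicRates
from .errors import ValidationError
from .grids import FEMALE, MALE, N_AGES_DEFAULT
from .mortality import SAD_AGE_MIN, RelativeRisks
from .policy import DOMAINS, PolicySchedule
from .smoking import (INIT_AGE_MAX, N_QUIT_BINS, SmokingState, TransitionRates,
                      derive_initiation_rates)

#: 1989 survey current-smoking prevalence by age group, percent
#: (age_lo, age_hi): (male, female)
BASELINE_PREVALENCE_1989: dict[tuple[int, int], tuple[float, float]] = {
    (18, 24): (34.1, 24.2),
    (25, 44): (48.4, 31.4),
    (45, 64): (45.5, 23.7),
    (65, 200): (33.5, 18.4),
}

#: printed 18-and-above aggregates the synthetic pyramid must reproduce
BASELINE_ADULT_PREVALENCE_1989: tuple[float, float] = (43.3, 27.0)

#: initial annual quit probability of the adult smoking population
BASELINE_CESSATION_RATE: float = 0.05

#: default current-smoker all-cause mortality relative risk at ages >= 30
DEFAULT_RR_CURRENT: float = 2.1

#: duration-dependent annual relapse probabilities, years-quit bins 1..16+;
#: a documented monotone-decreasing placeholder schedule (configurable)
DEFAULT_RELAPSE: np.ndarray = np.array(
    [0.12, 0.08, 0.06, 0.05, 0.04, 0.035, 0.03, 0.025, 0.02, 0.018,
     0.016, 0.014, 0.012, 0.011, 0.010, 0.005])


@dataclass
class FixtureBundle:
    """A complete, validated input set for the simulation model."""

    base_year: int
    horizon: int
    population: np.ndarray
    demographic_rates: DemographicRates
    smoking: SmokingState
    transitions: TransitionRates
    relative_risks: RelativeRisks
    schedule: PolicySchedule
    seed: int = 0


# ---------------------------------------------------------------------------
# parametric demographic shapes
# ---------------------------------------------------------------------------

def _mortality_curve(n_ages: int) -> np.ndarray:
    """Gompertz-like adult mortality with an infant bump; male excess."""
    ages = np.arange(n_ages)
    base = 0.0004 * np.exp(0.082 * ages)
    base[0] += 0.035  # infant mortality
    base[1:5] += 0.002
    m = np.empty((n_ages, 2))
    m[:, MALE] = base * 1.2
    m[:, FEMALE] = base * 0.85
    # cap so status-specific rates (never-smoker rate x relative risk) stay
    # valid probabilities even in cells dominated by never smokers
    return np.clip(m, 0.0, 0.45)


def _fertility_curve(n_ages: int, tfr: float = 2.85) -> np.ndarray:
    """Smooth single-peak age-specific fertility integrating to the total
    fertility rate."""
    ages = np.arange(n_ages)
    shape = np.exp(-0.5 * ((ages - 26.0) / 6.5) ** 2)
    shape[(ages < 15) | (ages > 49)] = 0.0
    return shape / shape.sum() * tfr


def _survivorship_pyramid(mortality: np.ndarray, growth: float = 0.025,
                          total: float = 145e6) -> np.ndarray:
    """Quasi-stable population: survivorship discounted by past growth."""
    n = mortality.shape[0]
    surv = np.cumprod(np.vstack([np.ones((1, 2)), 1.0 - mortality[:-1]]), axis=0)
    weights = surv * np.exp(-growth * np.arange(n))[:, None]
    return weights / weights.sum() * total


def _tilt_adult_ages(pop_col: np.ndarray, prev_col: np.ndarray,
                     target: float, adult_age: int = 18) -> np.ndarray:
    """Exponentially tilt the 18+ age distribution so the population-weighted
    adult prevalence hits ``target`` exactly.

    The tilt ``w(a) * exp(theta * (a - 45) / 10)`` preserves smoothness and
    total adult count; theta is solved by bracketed root finding on a scanned
    sign change (the aggregate is not monotone in theta because the
    prevalence-by-age profile is hump-shaped).
    """
    ages = np.arange(pop_col.shape[0])
    adult = ages >= adult_age
    w = pop_col[adult]
    p = prev_col[adult]
    t = (ages[adult] - 45.0) / 10.0

    def agg(theta: float) -> float:
        ww = w * np.exp(theta * t)
        return float(ww @ p / ww.sum()) - target

    thetas = np.linspace(-4.0, 4.0, 161)
    vals = np.array([agg(th) for th in thetas])
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValidationError(
            f"adult prevalence target {target} unattainable by age reweighting")
    i = sign_change[0]
    theta = brentq(agg, thetas[i], thetas[i + 1], xtol=1e-13)
    out = pop_col.copy()
    tilted = w * np.exp(theta * t)
    out[adult] = tilted / tilted.sum() * w.sum()
    return out


def _baseline_prevalence_curve(n_ages: int, gender: int) -> np.ndarray:
    """Single-age current-smoking prevalence: flat within the printed survey
    age groups, with a linear uptake ramp from age 12 to the 18-24 level."""
    prev = np.zeros(n_ages)
    for (lo, hi), vals in BASELINE_PREVALENCE_1989.items():
        prev[lo:min(hi, n_ages - 1) + 1] = vals[gender] / 100.0
    p18 = BASELINE_PREVALENCE_1989[(18, 24)][gender] / 100.0
    for a in range(12, 18):
        prev[a] = p18 * (a - 12) / 6.0
    return prev


def _former_share_curve(n_ages: int) -> np.ndarray:
    """Former-smoker share of the population by age (both genders): zero
    before the mid-20s, rising with age as cohorts accumulate quitters."""
    ages = np.arange(n_ages)
    return np.clip(0.004 * (ages - 24), 0.0, 0.28)


def _quit_duration_weights() -> np.ndarray:
    """Distribution over years-quit bins: geometric attrition of recent
    quitters with the remaining mass in the absorbing 16+ bin."""
    w = 0.85 ** np.arange(1, N_QUIT_BINS)
    tail = 0.85 ** N_QUIT_BINS / (1 - 0.85)
    w = np.append(w, tail)
    return w / w.sum()


def default_relative_risks(n_ages: int = N_AGES_DEFAULT,
                           rr_current: float = DEFAULT_RR_CURRENT) -> RelativeRisks:
    """Current-smoker relative risk ``rr_current`` at ages >= 30 (1 below),
    with former-smoker risk declining linearly to 1 at the 16+ years-quit
    bin.  A configurable placeholder for unavailable cohort-study values."""
    cur = np.ones((n_ages, 2))
    cur[SAD_AGE_MIN:] = rr_current
    decay = (N_QUIT_BINS - np.arange(1, N_QUIT_BINS + 1)) / (N_QUIT_BINS - 1.0)
    former = 1.0 + (cur[..., None] - 1.0) * decay
    return RelativeRisks(cur, former)


# ---------------------------------------------------------------------------
# policy schedule
# ---------------------------------------------------------------------------

def brazil_policy_schedule(base_year: int = 1989) -> PolicySchedule:
    """Milestone schedule for the 1989-2010 tracking period.

    Real prices double by 1998 and reach 2.3x the base level by 2010 (held
    flat thereafter).  Milestones: weak advertising restrictions already in
    place at base; 1996 brings weak warnings, education/media programmes,
    partial smoke-free coverage, first cessation-treatment availability and
    weak youth-access enforcement; smoke-free and marketing rules strengthen
    in 2000; graphic warnings arrive in 2001; marketing restrictions escalate
    to a comprehensive ban by 2005; city smoking bans broaden smoke-free
    coverage from 2007.  Exact coverage fractions and enforcement scores are
    synthetic choices anchored to those milestone years.
    """
    price = {base_year: 1.0, 1998: 2.0, 2010: 2.3}
    policies = {
        base_year: {
            "marketing": {"level": "weak", "enforcement": 0.5},
        },
        1996: {
            "warnings": {"level": "weak"},
            "media": {"level": "low"},
            "smokefree": {"components": {"worksite": 0.2, "restaurant": 0.2},
                          "enforcement": 0.5},
            "cessation_treatment": {"level": 0.25},
            "youth_access": {"level": "low"},
        },
        2000: {
            "smokefree": {"components": {"worksite": 0.4, "restaurant": 0.4,
                                         "other": 0.3},
                          "enforcement": 0.6},
            "marketing": {"level": "total", "enforcement": 0.7},
        },
        2001: {
            "warnings": {"level": "strong"},
        },
        2002: {
            "media": {"level": "moderate"},
        },
        2004: {
            "cessation_treatment": {"level": 0.5},
        },
        2005: {
            "marketing": {"level": "comprehensive", "enforcement": 0.8},
        },
        2006: {
            "media": {"level": "high"},
        },
        2007: {
            "smokefree": {"components": {"worksite": 0.6, "restaurant": 0.6,
                                         "bar": 0.3, "other": 0.5},
                          "enforcement": 0.7},
            "youth_access": {"level": "moderate"},
        },
    }
    return PolicySchedule(base_year, price, policies)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def make_brazil_like_fixture(seed: int = 0, base_year: int = 1989,
                             horizon: int = 2050,
                             rr_current: float = DEFAULT_RR_CURRENT,
                             ) -> FixtureBundle:
    """Complete Brazil-like input bundle.

    Deterministic given ``seed`` (the construction itself is closed-form;
    the seed is carried for the stochastic microsimulation oracle and any
    downstream sampling).
    """
    n_ages = N_AGES_DEFAULT
    mortality = _mortality_curve(n_ages)
    fertility = _fertility_curve(n_ages)
    rates = DemographicRates(fertility, mortality, sex_ratio_at_birth=0.512)

    population = _survivorship_pyramid(mortality)
    prev = np.column_stack([_baseline_prevalence_curve(n_ages, g) for g in (MALE, FEMALE)])
    for g, target in ((MALE, BASELINE_ADULT_PREVALENCE_1989[0] / 100.0),
                      (FEMALE, BASELINE_ADULT_PREVALENCE_1989[1] / 100.0)):
        population[:, g] = _tilt_adult_ages(population[:, g], prev[:, g], target)

    former_share = _former_share_curve(n_ages)[:, None] * np.ones((1, 2))
    former_share = np.minimum(former_share, 0.95 - prev)  # keep never share positive
    never_share = 1.0 - prev - former_share

    current = population * prev
    former_total = population * former_share
    never = population * never_share
    former = former_total[..., None] * _quit_duration_weights()
    smoking = SmokingState(never, current, former)

    cessation = np.zeros((n_ages, 2))
    cessation[INIT_AGE_MAX + 1:] = BASELINE_CESSATION_RATE
    initiation = derive_initiation_rates(prev, prev, never_share=never_share)
    transitions = TransitionRates(initiation, cessation, DEFAULT_RELAPSE.copy())

    return FixtureBundle(
        base_year=base_year, horizon=horizon, population=population,
        demographic_rates=rates, smoking=smoking, transitions=transitions,
        relative_risks=default_relative_risks(n_ages, rr_current),
        schedule=brazil_policy_schedule(base_year), seed=int(seed))


def make_toy_fixture(n_ages: int = 3, count: float = 100.0,
                     mortality: float = 0.0, fertility: float = 0.0,
                     fertility_age: int = 1, prevalence: float = 0.2,
                     cessation: float = 0.05, relapse: float = 0.0,
                     base_year: int = 2000, horizon: int = 2010,
                     seed: int = 0) -> FixtureBundle:
    """Tiny closed-form-checkable world for oracle tests.

    Every cell holds ``count`` people split evenly by gender, with uniform
    mortality, a single fertile age, uniform adult prevalence and no policy
    activity (all domains at base levels, flat prices).
    """
    if n_ages < 3:
        raise ValidationError("toy fixture needs at least 3 ages")
    pop = np.full((n_ages, 2), count / 2.0)
    fert = np.zeros(n_ages)
    fert[fertility_age] = fertility
    rates = DemographicRates(fert, np.full((n_ages, 2), float(mortality)),
                             sex_ratio_at_birth=0.5)

    prev = np.zeros((n_ages, 2))
    adult = np.arange(n_ages) > INIT_AGE_MAX
    if adult.any():
        prev[adult] = prevalence
    current = pop * prev
    never = pop - current
    former = np.zeros((n_ages, 2, N_QUIT_BINS))
    smoking = SmokingState(never, current, former)

    cess = np.zeros((n_ages, 2))
    cess[INIT_AGE_MAX + 1:] = cessation
    transitions = TransitionRates(np.zeros((n_ages, 2)), cess,
                                  np.full(N_QUIT_BINS, float(relapse)))

    schedule = PolicySchedule(base_year, {base_year: 1.0}, {})
    return FixtureBundle(
        base_year=base_year, horizon=horizon, population=pop,
        demographic_rates=rates, smoking=smoking, transitions=transitions,
        relative_risks=default_relative_risks(n_ages), schedule=schedule,
        seed=int(seed))
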