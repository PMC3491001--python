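"""Scenario engine: the simulation model and its results objects.

:class:`TobaccoPolicyModel` composes the demography, smoking-transition,
policy and mortality-attribution machinery into a deterministic annual loop
from a base year to a horizon.  Within each simulated year the order of
operations is fixed: policy effects (one-off prevalence shocks for level
changes, sustained multipliers on initiation/cessation), then the Markov
smoking transitions, then status-specific mortality (from which
smoking-attributable deaths are recorded), then aging and births.

``model.run()`` produces a single :class:`ScenarioResult`;
``model.fit()`` runs the standard scenario set - the counterfactual with
all policies frozen at base-year levels, the full schedule at lower/central/
upper effect-size bounds, and single-policy runs - and returns a
:class:`PolicyImpactResults` carrying deaths averted, relative prevalence
reductions, per-policy contribution shares, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographicRates, age_survivors
from .errors import ValidationError
from .grids import FEMALE, MALE
from .mortality import (RelativeRisks, StatusMortality, compute_sads,
                        cumulative_sads, partition_mortality_grid)
from .policy import (BOUND_VARIANTS, DEFAULT_BOUNDS, DOMAINS, EffectBounds,
                     PolicyEffects, PolicySchedule, apply_prevalence_shock,
                     apply_rate_effects, schedule_to_effects)
from .smoking import (SmokingState, TransitionRates, compute_prevalence,
                      step_smoking_states)

ADULT_AGE: int = 18


@dataclass
class ScenarioResult:
    """One deterministic run: yearly states, prevalence and SADs.

    ``states`` holds the start-of-year smoking state (after any policy
    prevalence shock), so ``prevalence`` reflects the year in which a policy
    takes effect.  ``sads`` are the smoking-attributable deaths occurring
    during each year.
    """

    label: str
    bound: str
    base_year: int
    years: np.ndarray
    states: list[SmokingState]
    sads: pd.Series
    prevalence: pd.DataFrame  # columns male/female/both, ages 18+

    @property
    def cumulative_sads(self) -> pd.Series:
        """Running total of SADs from the base year (non-decreasing)."""
        return self.sads.cumsum()

    def state_at(self, year: int) -> SmokingState:
        idx = int(year) - self.base_year
        if not 0 <= idx < len(self.states):
            raise ValidationError(f"year {year} outside simulated range")
        return self.states[idx]

    def prevalence_series(self, age_lo: int = ADULT_AGE, age_hi: int | None = None,
                          gender: str | None = None) -> pd.Series:
        vals = [compute_prevalence(s, age_lo, age_hi, gender) for s in self.states]
        return pd.Series(vals, index=self.years, name=f"prevalence_{age_lo}+")

    def cumulative_sads_between(self, year_lo: int, year_hi: int) -> float:
        return cumulative_sads(self.sads, year_lo, year_hi)

    def summary(self) -> pd.DataFrame:
        out = self.prevalence.copy()
        out["sads"] = self.sads
        out["cumulative_sads"] = self.cumulative_sads
        return out


def deaths_averted(policy: ScenarioResult, counterfactual: ScenarioResult,
                   year: int | None = None,
                   year_range: tuple[int, int] | None = None) -> float:
    """Counterfactual SADs minus policy-scenario SADs, for one year or
    cumulatively over an inclusive range."""
    if not np.array_equal(policy.years, counterfactual.years):
        raise ValidationError("scenarios cover different horizons")
    if (year is None) == (year_range is None):
        raise ValidationError("specify exactly one of year or year_range")
    if year is not None:
        return float(counterfactual.sads.loc[year] - policy.sads.loc[year])
    lo, hi = year_range
    return (counterfactual.cumulative_sads_between(lo, hi)
            - policy.cumulative_sads_between(lo, hi))


def relative_reduction(policy_prev: float, reference_prev: float) -> float:
    """Percent decline of a policy-scenario prevalence from a reference."""
    if reference_prev == 0:
        raise ValidationError("reference prevalence must be nonzero")
    return (reference_prev - policy_prev) / reference_prev * 100.0


def decompose_contributions(reductions: dict[str, float]) -> dict[str, float]:
    """Share of the summed single-policy reductions attributed to each policy.

    Because policy effects combine multiplicatively, each policy's
    contribution is expressed relative to the sum over all single-policy
    reductions; shares total 100 before rounding.
    """
    if not reductions:
        raise ValidationError("no reductions supplied")
    if any(r < 0 for r in reductions.values()):
        raise ValidationError("reductions must be >= 0")
    total = sum(reductions.values())
    if total <= 0:
        raise ValidationError("at least one reduction must be positive")
    return {d: r / total * 100.0 for d, r in reductions.items()}


def build_fctc_schedule(schedule: PolicySchedule, start_year: int = 2011,
                        tax_share_from: float = 0.60,
                        tax_share_to: float = 0.75) -> PolicySchedule:
    """Maximal-policy schedule from ``start_year`` onward.

    From ``start_year``: the tax share of retail price rises from
    ``tax_share_from`` to ``tax_share_to``; with full pass-through and a
    constant pre-tax price the real price is multiplied by
    ``(1 - from) / (1 - to)`` (0.40/0.25 = 1.6 for the defaults).  Smoke-free
    air laws become complete and fully enforced, the marketing ban
    comprehensive, media campaigns high-intensity, cessation treatment fully
    available, and youth access strongly enforced; all maintained thereafter.
    """
    if not 0 <= tax_share_from < tax_share_to < 1:
        raise ValidationError("tax shares must satisfy 0 <= from < to < 1")
    index = schedule.to_dict()["price_index"]
    years = np.array(sorted(index), dtype=float)
    values = np.array([index[int(y)] for y in years])
    idx_prev = float(np.interp(start_year - 1, years, values))
    mult = (1.0 - tax_share_from) / (1.0 - tax_share_to)
    return schedule.with_updates(
        start_year,
        {
            "smokefree": {"components": {"worksite": 1.0, "restaurant": 1.0,
                                         "bar": 1.0, "other": 1.0},
                          "enforcement": 1.0},
            "marketing": {"level": "comprehensive", "enforcement": 1.0},
            "media": {"level": "high"},
            "cessation_treatment": {"level": "complete"},
            "youth_access": {"level": "strong"},
        },
        price_knots={start_year - 1: idx_prev, start_year: idx_prev * mult},
    )


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class TobaccoPolicyModel:
    """Deterministic tobacco-control policy simulation model.

    Parameters
    ----------
    population : (n_ages, 2) array
        Base-year counts by age and gender (consistent with ``smoking``).
    demographic_rates : DemographicRates
        Annual fertility and all-cause mortality (held constant over the run).
    smoking : SmokingState
        Base-year never/current/former-by-years-quit counts.
    transitions : TransitionRates
        Background initiation, cessation and relapse probabilities.
    relative_risks : RelativeRisks
        All-cause mortality relative risks for current and former smokers.
    schedule : PolicySchedule
        Policy levels and real prices from the base year onward.
    base_year, horizon : int
        Simulated period, inclusive of both endpoints.
    """

    def __init__(self, population, demographic_rates: DemographicRates,
                 smoking: SmokingState, transitions: TransitionRates,
                 relative_risks: RelativeRisks, schedule: PolicySchedule,
                 base_year: int, horizon: int = 2050,
                 bounds: EffectBounds = DEFAULT_BOUNDS) -> None:
        if base_year > horizon:
            raise ValidationError("base year must not exceed the horizon")
        smoking.validate_against_population(np.asarray(population, dtype=float))
        if demographic_rates.n_ages != smoking.n_ages:
            raise ValidationError("demographic rates and state on different grids")
        self.population = np.asarray(population, dtype=float)
        self.demographic_rates = demographic_rates
        self.smoking = smoking
        self.transitions = transitions
        self.relative_risks = relative_risks
        self.schedule = schedule
        self.base_year = int(base_year)
        self.horizon = int(horizon)
        self.bounds = bounds

    @classmethod
    def from_bundle(cls, bundle, horizon: int | None = None) -> "TobaccoPolicyModel":
        """Build from a :class:`~smokesim.fixtures.FixtureBundle`."""
        return cls(bundle.population, bundle.demographic_rates, bundle.smoking,
                   bundle.transitions, bundle.relative_risks, bundle.schedule,
                   bundle.base_year,
                   bundle.horizon if horizon is None else horizon)

    # -- single runs ----------------------------------------------------

    def run(self, schedule: PolicySchedule | None = None, bound: str = "central",
            label: str | None = None, disable_policies: bool = False,
            relative_risks: RelativeRisks | None = None) -> ScenarioResult:
        """Run one deterministic scenario.

        ``disable_policies`` bypasses the policy engine entirely (used to
        verify the counterfactual identity: a schedule frozen at base-year
        levels must reproduce this run exactly).
        """
        schedule = schedule if schedule is not None else self.schedule
        rr = relative_risks if relative_risks is not None else self.relative_risks
        n_ages = self.smoking.n_ages
        state = self.smoking.copy()
        rates = self.demographic_rates

        adult_lo = ADULT_AGE if n_ages > ADULT_AGE else 0
        years = np.arange(self.base_year, self.horizon + 1)
        states: list[SmokingState] = []
        sads = np.zeros(len(years))
        prev_rows = np.zeros((len(years), 3))
        prior_effect = np.zeros(n_ages)

        for i, year in enumerate(years):
            if disable_policies:
                effects = PolicyEffects.zero(n_ages)
            else:
                effects = schedule_to_effects(schedule, int(year), bound,
                                              n_ages, self.bounds)
            state = apply_prevalence_shock(state, effects.prevalence, prior_effect)
            states.append(state.copy())
            prev_rows[i] = (compute_prevalence(state, adult_lo, gender="male"),
                            compute_prevalence(state, adult_lo, gender="female"),
                            compute_prevalence(state, adult_lo))
            pop_start = state.population()
            trans = apply_rate_effects(self.transitions, effects)
            state = step_smoking_states(state, trans)
            sm = partition_mortality_grid(rates.mortality, state, rr)
            sads[i] = compute_sads(state, sm).sum()
            births = float(rates.fertility @ pop_start[:, FEMALE])
            state = _age_and_survive(state, sm, births, rates.sex_ratio_at_birth)
            prior_effect = effects.prevalence

        prevalence = pd.DataFrame(prev_rows, index=years,
                                  columns=["male", "female", "both"])
        prevalence.index.name = "year"
        return ScenarioResult(
            label=label or ("counterfactual" if disable_policies else "scenario"),
            bound=bound, base_year=self.base_year, years=years, states=states,
            sads=pd.Series(sads, index=years, name="sads"),
            prevalence=prevalence)

    def run_counterfactual(self, label: str = "counterfactual") -> ScenarioResult:
        """All policies frozen at their base-year levels."""
        return self.run(self.schedule.frozen_at(self.base_year), label=label)

    def run_single_policy(self, domain: str, bound: str = "central") -> ScenarioResult:
        """Only one domain follows its actual path; the rest stay at base."""
        return self.run(self.schedule.single_domain(domain), bound=bound,
                        label=f"{domain}_only")

    # -- the full scenario set -------------------------------------------

    def fit(self, bounds: tuple[str, ...] = BOUND_VARIANTS,
            single_policies: bool = True) -> "PolicyImpactResults":
        """Run the standard scenario set and return results.

        Runs the counterfactual, the full schedule at each requested bound
        variant, and (optionally) each single-policy scenario at central
        bounds.
        """
        counterfactual = self.run_counterfactual()
        policy = {b: self.run(bound=b, label="all_policies") for b in bounds}
        singles = ({d: self.run_single_policy(d) for d in DOMAINS}
                   if single_policies else {})
        return PolicyImpactResults(model=self, counterfactual=counterfactual,
                                   policy=policy, singles=singles)


def _survive_and_shift(arr2d: np.ndarray, mort2d: np.ndarray) -> np.ndarray:
    return age_survivors(arr2d * (1.0 - mort2d))


def _age_and_survive(state: SmokingState, sm: StatusMortality, births: float,
                     sex_ratio_at_birth: float) -> SmokingState:
    """Status-specific survival, aging (open top bin), and births into the
    never-smoker compartment."""
    never = _survive_and_shift(state.never, sm.never)
    current = _survive_and_shift(state.current, sm.current)
    former_surv = state.former * (1.0 - sm.former)
    former = np.zeros_like(former_surv)
    former[1:] = former_surv[:-1]
    former[-1] += former_surv[-1]
    never[0, MALE] = births * sex_ratio_at_birth
    never[0, FEMALE] = births * (1.0 - sex_ratio_at_birth)
    return SmokingState(never, current, former)


@dataclass
class PolicyImpactResults:
    """Scenario comparison: the counterfactual, the full policy schedule at
    each bound variant, and single-policy runs."""

    model: TobaccoPolicyModel
    counterfactual: ScenarioResult
    policy: dict[str, ScenarioResult]
    singles: dict[str, ScenarioResult] = field(default_factory=dict)

    def deaths_averted(self, year: int | None = None,
                       year_range: tuple[int, int] | None = None,
                       bound: str = "central",
                       scenario: str | None = None) -> float:
        res = self.singles[scenario] if scenario else self.policy[bound]
        return deaths_averted(res, self.counterfactual, year=year,
                              year_range=year_range)

    def relative_reduction(self, year: int, bound: str = "central",
                           gender: str | None = None,
                           scenario: str | None = None) -> float:
        res = self.singles[scenario] if scenario else self.policy[bound]
        col = gender or "both"
        return relative_reduction(res.prevalence.loc[year, col],
                                  self.counterfactual.prevalence.loc[year, col])

    def contributions(self, year: int) -> dict[str, float]:
        """Per-policy share (percent) of the summed single-policy prevalence
        reductions in ``year``."""
        if not self.singles:
            raise ValidationError("fit() was run without single-policy scenarios")
        reductions = {d: max(0.0, self.relative_reduction(year, scenario=d))
                      for d in self.singles}
        return decompose_contributions(reductions)

    def summary(self, years: tuple[int, ...] = (2000, 2010, 2050)) -> pd.DataFrame:
        """Prevalence by scenario and year (percent, ages 18+, both genders),
        with percent reductions relative to the counterfactual and deaths
        averted by the full policy set."""
        years = tuple(y for y in years
                      if self.counterfactual.years[0] <= y <= self.counterfactual.years[-1])
        rows = {}
        rows["counterfactual"] = [self.counterfactual.prevalence.loc[y, "both"] * 100
                                  for y in years]
        for b, res in self.policy.items():
            rows[f"all_policies[{b}]"] = [res.prevalence.loc[y, "both"] * 100
                                          for y in years]
        for d, res in self.singles.items():
            rows[res.label] = [res.prevalence.loc[y, "both"] * 100 for y in years]
        df = pd.DataFrame(rows, index=[f"prevalence_{y}" for y in years]).T
        for y in years:
            df[f"reduction_{y}_pct"] = [
                relative_reduction(df.loc[r, f"prevalence_{y}"],
                                   rows["counterfactual"][years.index(y)])
                if r != "counterfactual" else 0.0
                for r in df.index]
        last = years[-1]
        averted = {r: np.nan for r in df.index}
        for b, res in self.policy.items():
            averted[f"all_policies[{b}]"] = deaths_averted(
                res, self.counterfactual, year_range=(self.counterfactual.years[0], last))
        for d, res in self.singles.items():
            averted[res.label] = deaths_averted(
                res, self.counterfactual, year_range=(self.counterfactual.years[0], last))
        df[f"deaths_averted_through_{last}"] = pd.Series(averted)
        return df.round(3)

    def __str__(self) -> str:
        return self.summary().to_string()


def run_scenario(bundle, schedule: PolicySchedule | None = None,
                 horizon: int | None = None, bound: str = "central",
                 label: str | None = None) -> ScenarioResult:
    """Convenience wrapper: run one scenario directly from a fixture bundle."""
    model = TobaccoPolicyModel.from_bundle(bundle, horizon=horizon)
    return model.run(schedule=schedule, bound=bound, label=label)
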