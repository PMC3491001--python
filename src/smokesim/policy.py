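"""Policy effect sizes, schedules, and their conversion to annual effects.

Seven policy domains are modelled: cigarette price (tax), smoke-free air
laws, mass-media campaigns, marketing restrictions, health warnings,
cessation treatment, and youth-access restrictions.  Each domain level maps
to fractional effects on three channels:

* prevalence - a one-off reduction of current smokers in the year a level
  change takes effect,
* initiation - an ongoing multiplicative reduction of initiation rates while
  the level is sustained,
* cessation  - an ongoing multiplicative increase of cessation rates.

Effects combine multiplicatively: a newly added policy's effect is scaled by
(1 - effect of policies already in place), so the combined reduction stays
below 100% and is order-independent.  Each domain contributes only its
increment over its base-year level.  Enforcement scales smoke-free and
marketing effects linearly between 50% (no enforcement) and 100% (full).
Media-campaign effects double in years when any other domain sits above its
base-year level.  Lower/central/upper bound variants rescale each domain's
effect sizes to bracket the uncertainty of the underlying policy literature.

Price is a level effect recomputed every year from the real price relative
to the base year, with constant-elasticity compounding so that a 10% price
increase produces exactly the per-age-band reduction of the effect table and
large cumulative increases remain bounded below 100%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import ScheduleError, ValidationError
from .smoking import SmokingState, TransitionRates

DOMAINS: tuple[str, ...] = (
    "price", "smokefree", "media", "marketing", "warnings",
    "cessation_treatment", "youth_access",
)

# ---------------------------------------------------------------------------
# effect-size tables (fractional reductions; cessation entries are increases)
# ---------------------------------------------------------------------------

#: per-10%-price-increase prevalence reduction by age band (lo, hi, effect);
#: ages below 15 take the 15-17 value
PRICE_BANDS: tuple[tuple[int, int, float], ...] = (
    (0, 17, 0.06), (18, 24, 0.04), (25, 34, 0.02), (35, 10**9, 0.01),
)

#: additive smoke-free air components at full coverage
SMOKEFREE_COMPONENTS: Mapping[str, float] = {
    "worksite": 0.09, "restaurant": 0.03, "bar": 0.015, "other": 0.01,
}

#: mutually exclusive media campaign levels (doubled alongside other policies)
MEDIA_LEVELS: Mapping[str, float] = {
    "none": 0.0, "low": 0.005, "moderate": 0.018, "high": 0.0325,
}

#: mutually exclusive marketing-ban levels: (prevalence, initiation, cessation)
MARKETING_LEVELS: Mapping[str, tuple[float, float, float]] = {
    "none": (0.0, 0.0, 0.0),
    "weak": (0.02, 0.02, 0.0),
    "total": (0.06, 0.08, 0.04),
    "comprehensive": (0.10, 0.12, 0.06),
}

#: mutually exclusive warning-label levels: (prevalence, initiation, cessation)
WARNING_LEVELS: Mapping[str, tuple[float, float, float]] = {
    "none": (0.0, 0.0, 0.0),
    "weak": (0.01, 0.01, 0.02),
    "strong": (0.04, 0.04, 0.10),
}

#: full cessation-treatment programme: (prevalence, initiation, cessation)
CESSATION_TX_FULL: tuple[float, float, float] = (0.0675, 0.0, 0.55)

#: youth-access levels: (effect under 16, effect ages 16-17); prevalence and
#: initiation only
YOUTH_LEVELS: Mapping[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "low": (0.03, 0.02),
    "moderate": (0.15, 0.10),
    "strong": (0.30, 0.20),
}

_CESSATION_TX_LEVELS: Mapping[str, float] = {
    "none": 0.0, "partial": 0.5, "complete": 1.0,
}

_ORDINAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "media": ("none", "low", "moderate", "high"),
    "marketing": ("none", "weak", "total", "comprehensive"),
    "warnings": ("none", "weak", "strong"),
    "youth_access": ("none", "low", "moderate", "strong"),
}


@dataclass(frozen=True)
class EffectBounds:
    """Per-domain (lower, upper) effect-size multipliers for bound scenarios.

    Defaults reflect the spread of the policy-evaluation literature:
    +/-50% for smoke-free air, marketing, warnings and media; -50%/+100% for
    cessation treatment (treatment delivery could improve); 0%/+50% for
    youth access (many studies find no effect); +/-25% for price, where the
    evidence is most consistent.
    """

    multipliers: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "price": (0.75, 1.25),
        "smokefree": (0.5, 1.5),
        "media": (0.5, 1.5),
        "marketing": (0.5, 1.5),
        "warnings": (0.5, 1.5),
        "cessation_treatment": (0.5, 2.0),
        "youth_access": (0.0, 1.5),
    })

    def __post_init__(self) -> None:
        for d, (lo, hi) in self.multipliers.items():
            if d not in DOMAINS:
                raise ValidationError(f"unknown domain {d!r} in bounds")
            if not lo <= 1.0 <= hi:
                raise ValidationError(f"bounds for {d} must straddle 1: {lo}, {hi}")

    def multiplier(self, domain: str, variant: str) -> float:
        if variant == "central":
            return 1.0
        lo, hi = self.multipliers[domain]
        if variant == "lower":
            return lo
        if variant == "upper":
            return hi
        raise ValidationError(f"unknown bound variant {variant!r}")


DEFAULT_BOUNDS = EffectBounds()

BOUND_VARIANTS: tuple[str, ...] = ("lower", "central", "upper")


@dataclass(frozen=True)
class PolicySpec:
    """One domain's setting: a level label (or coverage fractions for the
    additive smoke-free components, or an availability fraction for
    cessation treatment) plus an enforcement score in [0, 1]."""

    domain: str
    level: str | float | None = None
    components: Mapping[str, float] | None = None
    enforcement: float = 1.0

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ScheduleError(f"unknown policy domain {self.domain!r}")
        if not 0.0 <= self.enforcement <= 1.0:
            raise ValidationError("enforcement score must lie in [0, 1]")
        if self.domain == "smokefree":
            comps = self.components or {}
            for name, cov in comps.items():
                if name not in SMOKEFREE_COMPONENTS:
                    raise ScheduleError(f"unknown smoke-free component {name!r}")
                if not 0.0 <= cov <= 1.0:
                    raise ValidationError("smoke-free coverage must lie in [0, 1]")
        elif self.domain == "cessation_treatment":
            frac = self._cessation_fraction()
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("cessation-treatment availability in [0, 1]")
        elif self.domain in _ORDINAL_LEVELS:
            label = self.level or "none"
            if label not in _ORDINAL_LEVELS[self.domain]:
                raise ScheduleError(
                    f"unknown {self.domain} level {label!r}; "
                    f"expected one of {_ORDINAL_LEVELS[self.domain]}")

    def _cessation_fraction(self) -> float:
        if self.level is None:
            return 0.0
        if isinstance(self.level, str):
            try:
                return _CESSATION_TX_LEVELS[self.level]
            except KeyError:
                raise ScheduleError(
                    f"unknown cessation_treatment level {self.level!r}") from None
        return float(self.level)

    def strength(self) -> float:
        """Scalar ordering used to decide whether a level is above base."""
        if self.domain == "smokefree":
            return sum((self.components or {}).values())
        if self.domain == "cessation_treatment":
            return self._cessation_fraction()
        if self.domain in _ORDINAL_LEVELS:
            return float(_ORDINAL_LEVELS[self.domain].index(self.level or "none"))
        return 0.0

    @classmethod
    def parse(cls, domain: str, obj) -> "PolicySpec":
        """Build from a config mapping (or bare level label)."""
        if obj is None:
            return cls(domain)
        if isinstance(obj, (str, int, float)):
            return cls(domain, level=obj)
        if not isinstance(obj, Mapping):
            raise ScheduleError(f"cannot parse policy spec for {domain}: {obj!r}")
        return cls(domain,
                   level=obj.get("level"),
                   components=dict(obj.get("components", {})) or None,
                   enforcement=float(obj.get("enforcement", 1.0)))

    def to_dict(self) -> dict:
        d: dict = {"enforcement": self.enforcement}
        if self.level is not None:
            d["level"] = self.level
        if self.components:
            d["components"] = dict(self.components)
        return d


NO_POLICY: Mapping[str, PolicySpec] = {d: PolicySpec(d) for d in DOMAINS}


# ---------------------------------------------------------------------------
# elementary effect operations
# ---------------------------------------------------------------------------

def price_effect(price_ratio: float, age: int, multiplier: float = 1.0) -> float:
    """Fractional prevalence reduction from a real-price ratio at one age.

    Constant-elasticity compounding: with per-10% reduction x for the age
    band, the reduction is ``1 - ratio ** (ln(1 - x) / ln(1.1))``, so a
    ratio of exactly 1.1 returns x, large increases stay below 1, and a
    ratio below 1 yields a negative reduction (prevalence increase).
    """
    if price_ratio <= 0:
        raise ValidationError("price ratio must be positive")
    x = _price_band_effect(age) * multiplier
    if x <= 0:
        return 0.0
    return 1.0 - price_ratio ** (math.log1p(-x) / math.log(1.1))


def _price_band_effect(age: int) -> float:
    for lo, hi, x in PRICE_BANDS:
        if lo <= age <= hi:
            return x
    return PRICE_BANDS[-1][2]


def _price_effect_ages(price_ratio: float, n_ages: int,
                       multiplier: float = 1.0) -> np.ndarray:
    if price_ratio <= 0:
        raise ValidationError("price ratio must be positive")
    x = np.array([_price_band_effect(a) for a in range(n_ages)]) * multiplier
    with np.errstate(divide="ignore"):
        expo = np.log1p(-x) / math.log(1.1)
    return np.where(x > 0, 1.0 - price_ratio ** expo, 0.0)


def combined_effect(effects: Iterable[float]) -> float:
    """Multiplicative combination ``1 - prod(1 - e_i)``.

    Commutative and associative; bounded below 1; the empty set combines to
    0.  Negative effects (price decreases) are allowed.
    """
    out = 1.0
    for e in effects:
        if e >= 1.0:
            raise ValidationError("individual effects must be < 1")
        out *= 1.0 - e
    return 1.0 - out


def _combine_reductions(stack: list[np.ndarray]) -> np.ndarray:
    if not stack:
        raise ValidationError("empty effect stack")
    if np.any(np.vstack(stack) >= 1.0):
        raise ValidationError("individual effects must be < 1")
    return 1.0 - np.prod(1.0 - np.vstack(stack), axis=0)


def _enforcement_factor(score: float) -> float:
    # linear from 50% of the full effect at score 0 to 100% at score 1
    return 0.5 + 0.5 * float(np.clip(score, 0.0, 1.0))


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

class PolicySchedule:
    """Policy levels and real cigarette prices for every simulated year.

    Levels are specified as sparse milestones (``{year: {domain: spec}}``)
    and forward-filled: a level persists until replaced.  The price index is
    given as knots and linearly interpolated between them, held flat beyond
    the last knot.  The base year must be present.
    """

    def __init__(self, base_year: int,
                 price_knots: Mapping[int, float],
                 policies: Mapping[int, Mapping[str, PolicySpec | Mapping | str | float]],
                 ) -> None:
        self.base_year = int(base_year)
        if not price_knots:
            raise ScheduleError("price index requires at least one knot")
        self._price_years = np.array(sorted(price_knots), dtype=float)
        self._price_values = np.array([price_knots[int(y)] for y in self._price_years])
        if np.any(self._price_values <= 0):
            raise ScheduleError("price index values must be positive")
        if self.base_year < self._price_years[0]:
            raise ScheduleError("price index must cover the base year")

        self._milestones: dict[int, dict[str, PolicySpec]] = {}
        for year, block in policies.items():
            parsed: dict[str, PolicySpec] = {}
            for domain, obj in block.items():
                parsed[domain] = (obj if isinstance(obj, PolicySpec)
                                  else PolicySpec.parse(domain, obj))
            self._milestones[int(year)] = parsed
        if any(y < self.base_year for y in self._milestones):
            raise ScheduleError("policy milestones precede the base year")

    # -- lookups --------------------------------------------------------

    def price_ratio(self, year: int) -> float:
        """Real price relative to the base year (base-year ratio is the
        interpolated index at base year, normalised to itself)."""
        base = float(np.interp(self.base_year, self._price_years, self._price_values))
        val = float(np.interp(year, self._price_years, self._price_values))
        return val / base

    def spec(self, domain: str, year: int) -> PolicySpec:
        if domain not in DOMAINS:
            raise ScheduleError(f"unknown policy domain {domain!r}")
        best: PolicySpec | None = None
        for y in sorted(self._milestones):
            if y > year:
                break
            if domain in self._milestones[y]:
                best = self._milestones[y][domain]
        return best if best is not None else NO_POLICY[domain]

    def domain_above_base(self, domain: str, year: int) -> bool:
        if domain == "price":
            return abs(self.price_ratio(year) - self.price_ratio(self.base_year)) > 1e-12
        return self.spec(domain, year).strength() > self.spec(domain, self.base_year).strength()

    # -- derived schedules ---------------------------------------------

    def frozen_at(self, year: int) -> "PolicySchedule":
        """All domains and the price index held at their levels in ``year``.

        ``frozen_at(base_year)`` is the counterfactual schedule; freezing at
        a later year gives a status-quo projection.
        """
        block = {d: self.spec(d, year) for d in DOMAINS}
        return PolicySchedule(self.base_year,
                              {self.base_year: 1.0,
                               self.base_year + 1: self.price_ratio(year)}
                              if year != self.base_year else {self.base_year: 1.0},
                              {self.base_year: block})

    def single_domain(self, domain: str) -> "PolicySchedule":
        """Only ``domain`` follows its actual path; all others are frozen at
        their base-year levels."""
        if domain not in DOMAINS:
            raise ScheduleError(f"unknown policy domain {domain!r}")
        base_block = {d: self.spec(d, self.base_year) for d in DOMAINS if d != domain}
        policies: dict[int, dict[str, PolicySpec]] = {self.base_year: dict(base_block)}
        if domain != "price":
            for y, block in sorted(self._milestones.items()):
                if domain in block:
                    policies.setdefault(y, {})[domain] = block[domain]
        price = (dict(zip((int(y) for y in self._price_years), self._price_values))
                 if domain == "price" else {self.base_year: 1.0})
        return PolicySchedule(self.base_year, price, policies)

    def with_updates(self, year: int,
                     block: Mapping[str, PolicySpec | Mapping | str | float],
                     price_knots: Mapping[int, float] | None = None) -> "PolicySchedule":
        policies = {y: dict(b) for y, b in self._milestones.items()}
        merged = policies.setdefault(int(year), {})
        for domain, obj in block.items():
            merged[domain] = (obj if isinstance(obj, PolicySpec)
                              else PolicySpec.parse(domain, obj))
        knots = dict(zip((int(y) for y in self._price_years), self._price_values))
        if price_knots:
            knots.update({int(y): float(v) for y, v in price_knots.items()})
        return PolicySchedule(self.base_year, knots, policies)

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        return {
            "base_year": self.base_year,
            "price_index": {int(y): float(v) for y, v in
                            zip(self._price_years, self._price_values)},
            "policies": {y: {d: s.to_dict() for d, s in block.items()}
                         for y, block in sorted(self._milestones.items())},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PolicySchedule":
        try:
            base_year = int(d["base_year"])
            price = {int(y): float(v) for y, v in d["price_index"].items()}
            policies = {int(y): dict(block) for y, block in d.get("policies", {}).items()}
        except (KeyError, TypeError, ValueError) as exc:
            raise ScheduleError(f"malformed schedule config: {exc}") from exc
        return cls(base_year, price, policies)

    def __eq__(self, other) -> bool:
        return isinstance(other, PolicySchedule) and self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# schedule -> per-year effects
# ---------------------------------------------------------------------------

@dataclass
class PolicyEffects:
    """Combined per-age effects for one year: fractional reductions on
    prevalence and initiation, fractional increase on cessation."""

    prevalence: np.ndarray
    initiation: np.ndarray
    cessation: np.ndarray

    @classmethod
    def zero(cls, n_ages: int) -> "PolicyEffects":
        z = np.zeros(n_ages)
        return cls(z.copy(), z.copy(), z.copy())


def _domain_level_effects(domain: str, spec: PolicySpec, n_ages: int,
                          multiplier: float, doubled: bool = False,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (prevalence, initiation, cessation) effect arrays for one domain
    level versus no policy at all (before incremental adjustment)."""
    ages = np.arange(n_ages)
    prev = np.zeros(n_ages)
    init = np.zeros(n_ages)
    cess = np.zeros(n_ages)
    if domain == "smokefree":
        e = sum(SMOKEFREE_COMPONENTS[c] * cov
                for c, cov in (spec.components or {}).items())
        e *= _enforcement_factor(spec.enforcement) * multiplier
        prev[:] = init[:] = cess[:] = e
    elif domain == "media":
        e = MEDIA_LEVELS[spec.level or "none"] * multiplier
        if doubled:
            e *= 2.0
        prev[:] = init[:] = cess[:] = e
    elif domain == "marketing":
        p, i, c = MARKETING_LEVELS[spec.level or "none"]
        f = _enforcement_factor(spec.enforcement) * multiplier
        prev[:] = p * f
        init[:] = i * f
        cess[:] = c * f
    elif domain == "warnings":
        p, i, c = WARNING_LEVELS[spec.level or "none"]
        prev[:] = p * multiplier
        init[:] = i * multiplier
        cess[:] = c * multiplier
    elif domain == "cessation_treatment":
        frac = spec._cessation_fraction() * multiplier
        p, _, c = CESSATION_TX_FULL
        prev[:] = p * frac
        cess[:] = c * frac
    elif domain == "youth_access":
        under16, y16_17 = YOUTH_LEVELS[spec.level or "none"]
        young = ages < 16
        mid = (ages >= 16) & (ages < 18)
        prev[young] = under16 * multiplier
        prev[mid] = y16_17 * multiplier
        init[:] = prev  # prevalence and initiation only; no cessation channel
    else:
        raise ScheduleError(f"domain {domain!r} has no level table")
    return prev, init, cess


def _incremental(e_year: np.ndarray, e_base: np.ndarray,
                 increase: bool = False) -> np.ndarray:
    """Effect of this year's level over the base-year level, renormalised
    through the product rule (an already-present partial policy shrinks the
    headroom of the full one)."""
    if increase:
        return (1.0 + e_year) / (1.0 + e_base) - 1.0
    return 1.0 - (1.0 - e_year) / (1.0 - e_base)


def schedule_to_effects(schedule: PolicySchedule, year: int,
                        bound: str = "central", n_ages: int = 101,
                        bounds: EffectBounds = DEFAULT_BOUNDS) -> PolicyEffects:
    """Combined per-age effect triplet for one year of a schedule.

    Each domain contributes the increment of its year level over its
    base-year level; prevalence/initiation reductions combine through the
    product rule and cessation increases multiply.  Bound multipliers are
    applied per domain before combination.  At base-year levels everywhere
    the result is exactly zero (counterfactual identity).
    """
    base = schedule.base_year
    others_above = any(schedule.domain_above_base(d, year)
                       for d in DOMAINS if d != "media")
    prev_stack: list[np.ndarray] = []
    init_stack: list[np.ndarray] = []
    cess_factor = np.ones(n_ages)

    for domain in DOMAINS:
        mult = bounds.multiplier(domain, bound)
        if domain == "price":
            e_y = _price_effect_ages(schedule.price_ratio(year), n_ages, mult)
            e_b = _price_effect_ages(schedule.price_ratio(base), n_ages, mult)
            p_y, i_y = e_y, e_y
            # the under-18 price band acts on prevalence/initiation only
            c_y = np.where(np.arange(n_ages) >= 18, e_y, 0.0)
            p_b, i_b = e_b, e_b
            c_b = np.where(np.arange(n_ages) >= 18, e_b, 0.0)
        else:
            spec_y = schedule.spec(domain, year)
            spec_b = schedule.spec(domain, base)
            p_y, i_y, c_y = _domain_level_effects(
                domain, spec_y, n_ages, mult,
                doubled=(domain == "media" and others_above))
            p_b, i_b, c_b = _domain_level_effects(domain, spec_b, n_ages, mult)
        prev_stack.append(_incremental(p_y, p_b))
        init_stack.append(_incremental(i_y, i_b))
        cess_factor *= 1.0 + _incremental(c_y, c_b, increase=True)

    return PolicyEffects(
        prevalence=_combine_reductions(prev_stack),
        initiation=_combine_reductions(init_stack),
        cessation=cess_factor - 1.0,
    )


# ---------------------------------------------------------------------------
# applying effects to a state and to transition rates
# ---------------------------------------------------------------------------

def apply_prevalence_shock(state: SmokingState,
                           effect_now: np.ndarray,
                           effect_prior: np.ndarray | None = None) -> SmokingState:
    """One-off prevalence adjustment for newly effective policy levels.

    Current smokers are multiplied by ``(1 - E_now) / (1 - E_prior)`` per
    age, where E is the combined prevalence effect relative to the base
    year; smokers removed by a reduction quit into former bin 1 (quitting is
    the mechanism by which prevalence falls).  If the combined effect
    weakens (e.g. real prices fall), recent quitters in bin 1 return to
    smoking, clamped to those available.
    """
    effect_now = np.asarray(effect_now, dtype=float)
    if effect_prior is None:
        effect_prior = np.zeros_like(effect_now)
    else:
        effect_prior = np.asarray(effect_prior, dtype=float)
    if effect_now.shape != (state.n_ages,) or effect_prior.shape != (state.n_ages,):
        raise ValidationError("effects must be per-age arrays matching the state")
    if np.any(effect_now >= 1.0) or np.any(effect_prior >= 1.0):
        raise ValidationError("prevalence effects must be < 1")
    mult = (1.0 - effect_now) / (1.0 - effect_prior)
    out = state.copy()
    delta = out.current * (1.0 - mult[:, None])  # >0: smokers leaving
    leaving = np.clip(delta, 0.0, None)
    returning = np.minimum(np.clip(-delta, 0.0, None), out.former[..., 0])
    out.current = out.current - leaving + returning
    out.former[..., 0] = out.former[..., 0] + leaving - returning
    return out


def apply_rate_effects(rates: TransitionRates,
                       effects: PolicyEffects) -> TransitionRates:
    """Sustained-year adjustment of transition rates.

    Initiation is multiplied by (1 - initiation effect) and cessation by
    (1 + cessation effect), per age; results outside [0, 1] are clamped with
    a warning.
    """
    init = rates.initiation * (1.0 - effects.initiation[:, None])
    cess = rates.cessation * (1.0 + effects.cessation[:, None])
    if np.any(init < 0) or np.any(init > 1) or np.any(cess > 1) or np.any(cess < 0):
        warnings.warn("adjusted transition rates clamped to [0, 1]",
                      RuntimeWarning, stacklevel=2)
    return TransitionRates(np.clip(init, 0.0, 1.0), np.clip(cess, 0.0, 1.0),
                           rates.relapse.copy(), rates.init_age_max)


def apply_effects(state: SmokingState, rates: TransitionRates,
                  effects: PolicyEffects,
                  prior_effects: PolicyEffects | None = None,
                  ) -> tuple[SmokingState, TransitionRates]:
    """Apply one year's policy effects to a state and its transition rates.

    ``prior_effects`` is the previous year's combined effect (zero for newly
    implemented policies), so only the incremental prevalence change acts as
    a one-off shock while rate adjustments reflect the full sustained level.
    """
    prior = prior_effects.prevalence if prior_effects is not None else None
    return (apply_prevalence_shock(state, effects.prevalence, prior),
            apply_rate_effects(rates, effects))
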