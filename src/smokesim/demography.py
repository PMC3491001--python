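"""Annual cohort-component population projection.

The population is carried as an age x gender grid of counts and evolved one
year at a time: each cohort first survives that year's mortality, survivors
age by one year (the top bin accumulating), and births enter age 0 split by
the sex ratio at birth.  Rates are annual probabilities, not hazards, and
fertility applies to start-of-year female counts.  Migration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .grids import FEMALE, MALE, as_grid, check_same_grid


@dataclass
class DemographicRates:
    """Fertility and all-cause mortality on a shared age grid.

    Parameters
    ----------
    fertility : (n_ages,) array
        Births per woman per year by maternal age; >= 0.
    mortality : (n_ages, 2) array
        Probability of dying within the year, by age and gender, in [0, 1]
        (the top bin may be 1).
    sex_ratio_at_birth : float
        Fraction of births that are male.
    """

    fertility: np.ndarray
    mortality: np.ndarray
    sex_ratio_at_birth: float = 0.512

    def __post_init__(self) -> None:
        self.fertility = np.asarray(self.fertility, dtype=float)
        self.mortality = as_grid(self.mortality, name="mortality")
        if self.fertility.ndim != 1:
            raise ValidationError("fertility must be a 1-D per-age array")
        if self.fertility.shape[0] != self.mortality.shape[0]:
            raise ValidationError("fertility and mortality on different age grids")
        if np.any(self.fertility < 0) or not np.all(np.isfinite(self.fertility)):
            raise ValidationError("fertility rates must be finite and >= 0")
        if np.any(self.mortality > 1):
            raise ValidationError("mortality probabilities must be <= 1")
        if not 0.0 <= self.sex_ratio_at_birth <= 1.0:
            raise ValidationError("sex_ratio_at_birth must be in [0, 1]")

    @property
    def n_ages(self) -> int:
        return self.mortality.shape[0]


def expected_births(pop: np.ndarray, rates: DemographicRates) -> float:
    """Total births from start-of-year female counts."""
    pop = as_grid(pop, name="population")
    check_same_grid(pop, rates.mortality, "population and rates")
    return float(rates.fertility @ pop[:, FEMALE])


def age_survivors(survivors: np.ndarray) -> np.ndarray:
    """Shift survivors up one age; the open top bin accumulates."""
    out = np.zeros_like(survivors)
    out[1:] = survivors[:-1]
    out[-1] += survivors[-1]
    return out


def evolve_population(pop: np.ndarray, rates: DemographicRates) -> np.ndarray:
    """Project the population one year forward through deaths, aging, births.

    Within-year order is deaths -> aging -> births: each cohort survives
    mortality, survivors move up one age (top bin open-ended), and births
    computed from start-of-year female counts enter age 0.

    Returns the next-year age x gender grid.  Conservation holds exactly:
    ``deaths + survivors == pop`` per cell, and the next-year total equals
    births plus total survivors.
    """
    pop = as_grid(pop, name="population")
    check_same_grid(pop, rates.mortality, "population and mortality")
    survivors = pop * (1.0 - rates.mortality)
    out = age_survivors(survivors)
    births = float(rates.fertility @ pop[:, FEMALE])
    out[0, MALE] = births * rates.sex_ratio_at_birth
    out[0, FEMALE] = births * (1.0 - rates.sex_ratio_at_birth)
    return out


def deaths(pop: np.ndarray, rates: DemographicRates) -> np.ndarray:
    """Deaths during the year, per age x gender cell."""
    pop = as_grid(pop, name="population")
    check_same_grid(pop, rates.mortality, "population and mortality")
    return pop * rates.mortality
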