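"""Stochastic per-individual simulations of the same processes.

The deterministic model evolves expected counts; these microsimulations draw
each individual's transitions (or each cell's deaths and births) at random
with the identical rates.  By the law of large numbers their compartment
fractions converge to the deterministic projection, which makes them an
independent oracle for the compartmental code paths: any systematic
discrepancy beyond Monte Carlo error indicates a modelling bug.

Individual smoking states are encoded as integers: 0 never, 1 current,
2..17 former smoker with years-quit bin 1..16.
"""

from __future__ import annotations

import numpy as np

from .demography import DemographicRates
from .errors import ValidationError
from .grids import FEMALE, MALE
from .smoking import N_QUIT_BINS, TransitionRates

NEVER, CURRENT = 0, 1
_FORMER0 = 2  # state code of former bin 1


def microsimulate_smoking_cohort(n: int, years: int, age0: int, gender: int,
                                 rates: TransitionRates,
                                 p_never: float, p_current: float,
                                 p_former: np.ndarray,
                                 seed: int = 0) -> np.ndarray:
    """Simulate one cohort's smoking states individual by individual.

    The cohort starts at ``age0`` with the given initial state distribution
    and ages one year per step (no mortality, matching the pure Markov
    transition step).  Returns the fraction of individuals in each of the
    ``2 + N_QUIT_BINS`` states after each year, shape ``(years + 1, 18)``.
    """
    p_former = np.asarray(p_former, dtype=float)
    if p_former.shape != (N_QUIT_BINS,):
        raise ValidationError(f"p_former must have {N_QUIT_BINS} bins")
    probs = np.concatenate([[p_never, p_current], p_former])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("initial state probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    states = rng.choice(len(probs), size=n, p=probs / probs.sum())

    out = np.zeros((years + 1, 2 + N_QUIT_BINS))
    out[0] = np.bincount(states, minlength=2 + N_QUIT_BINS) / n
    for t in range(years):
        age = age0 + t
        u = rng.random(n)
        new = states.copy()

        init = rates.initiation[min(age, rates.n_ages - 1), gender]
        cess = rates.cessation[min(age, rates.n_ages - 1), gender]

        is_never = states == NEVER
        new[is_never & (u < init)] = CURRENT

        is_cur = states == CURRENT
        new[is_cur & (u < cess)] = _FORMER0

        for k in range(N_QUIT_BINS):
            in_bin = states == _FORMER0 + k
            rel = rates.relapse[k]
            new[in_bin & (u < rel)] = CURRENT
            stays = in_bin & (u >= rel)
            new[stays] = _FORMER0 + min(k + 1, N_QUIT_BINS - 1)

        states = new
        out[t + 1] = np.bincount(states, minlength=2 + N_QUIT_BINS) / n
    return out


def microsimulate_population_year(pop: np.ndarray, rates: DemographicRates,
                                  seed: int = 0) -> np.ndarray:
    """One stochastic replicate of a single demographic year.

    Deaths are binomial per age x gender cell and total births Poisson with
    the deterministic expectation, so replicate means converge to
    :func:`smokesim.demography.evolve_population`.
    """
    rng = np.random.default_rng(seed)
    pop = np.asarray(pop)
    if not np.allclose(pop, np.round(pop)):
        raise ValidationError("microsimulation needs integer counts")
    counts = np.round(pop).astype(np.int64)
    deaths = rng.binomial(counts, rates.mortality)
    survivors = (counts - deaths).astype(float)
    out = np.zeros_like(survivors)
    out[1:] = survivors[:-1]
    out[-1] += survivors[-1]
    births = rng.poisson(float(rates.fertility @ counts[:, FEMALE].astype(float)))
    males = rng.binomial(births, rates.sex_ratio_at_birth) if births > 0 else 0
    out[0, MALE] = males
    out[0, FEMALE] = births - males
    return out
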