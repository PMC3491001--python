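"""Never/current/former smoking states and their first-order Markov step.

Every population cell is split into never smokers, current smokers, and
former smokers indexed by completed years since quitting (yearly bins 1..15
plus an absorbing 16+ bin, so duration-dependent relapse can be expressed at
full resolution and aggregated to any coarser grouping).

Annual transitions:

* never -> current through net initiation, allowed through age 29 (smoking
  uptake levels off there);
* current -> former (bin 1) through cessation, tracked strictly above 29;
* former bin k -> current through duration-dependent relapse, otherwise the
  bin advances to k+1 (16+ is absorbing).

The step is a pure Markov transition: aging and mortality are composed
separately by the scenario engine, so the chain can be checked in isolation
against a per-individual stochastic simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InternalError, ValidationError
from .grids import GENDERS, as_grid, check_same_grid

#: yearly years-quit bins 1..15 plus absorbing 16+
N_QUIT_BINS: int = 16

#: initiation allowed through this age; cessation tracked strictly above it
INIT_AGE_MAX: int = 29

_NEG_TOL = 1e-9


@dataclass
class SmokingState:
    """Counts by age x gender x smoking status for one year.

    ``former`` has shape ``(n_ages, 2, N_QUIT_BINS)``; bin index k holds
    people who quit k+1 years ago (index 15 = 16+ years).
    """

    never: np.ndarray
    current: np.ndarray
    former: np.ndarray

    def __post_init__(self) -> None:
        self.never = as_grid(self.never, name="never")
        self.current = as_grid(self.current, name="current", n_ages=self.never.shape[0])
        self.former = np.asarray(self.former, dtype=float)
        if self.former.shape != (self.never.shape[0], 2, N_QUIT_BINS):
            raise ValidationError(
                f"former must have shape (n_ages, 2, {N_QUIT_BINS}), "
                f"got {self.former.shape}")
        if np.any(self.former < -_NEG_TOL) or not np.all(np.isfinite(self.former)):
            raise ValidationError("former counts must be finite and >= 0")
        self.former = np.clip(self.former, 0.0, None)

    @property
    def n_ages(self) -> int:
        return self.never.shape[0]

    def population(self) -> np.ndarray:
        """Total count per age x gender cell."""
        return self.never + self.current + self.former.sum(axis=-1)

    def copy(self) -> "SmokingState":
        return SmokingState(self.never.copy(), self.current.copy(), self.former.copy())

    def validate_against_population(self, pop: np.ndarray, rtol: float = 1e-9) -> None:
        """Check never + current + sum(former) matches ``pop`` per cell."""
        pop = as_grid(pop, name="population")
        total = self.population()
        check_same_grid(total, pop, "state and population")
        scale = np.maximum(pop, 1.0)
        if np.any(np.abs(total - pop) > rtol * scale):
            raise ValidationError("smoking-state counts do not sum to population")

    # -- tabular / JSON round-trips -------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long table with columns age, gender, state, years_quit, count."""
        rows = []
        n = self.n_ages
        for a in range(n):
            for gi, g in enumerate(GENDERS):
                rows.append((a, g, "never", 0, self.never[a, gi]))
                rows.append((a, g, "current", 0, self.current[a, gi]))
                for k in range(N_QUIT_BINS):
                    rows.append((a, g, "former", k + 1, self.former[a, gi, k]))
        return pd.DataFrame(rows, columns=["age", "gender", "state", "years_quit", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SmokingState":
        n = int(df["age"].max()) + 1
        never = np.zeros((n, 2))
        current = np.zeros((n, 2))
        former = np.zeros((n, 2, N_QUIT_BINS))
        gender_index = {g: i for i, g in enumerate(GENDERS)}
        for age, g, state, yq, count in df[
                ["age", "gender", "state", "years_quit", "count"]].itertuples(index=False):
            gi = gender_index[g]
            if state == "never":
                never[int(age), gi] = count
            elif state == "current":
                current[int(age), gi] = count
            elif state == "former":
                former[int(age), gi, int(yq) - 1] = count
            else:
                raise ValidationError(f"unknown smoking state {state!r}")
        return cls(never, current, former)

    def to_json(self) -> str:
        return json.dumps({
            "never": self.never.tolist(),
            "current": self.current.tolist(),
            "former": self.former.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "SmokingState":
        d = json.loads(text)
        return cls(np.array(d["never"]), np.array(d["current"]), np.array(d["former"]))


@dataclass
class TransitionRates:
    """Annual initiation, cessation and relapse probabilities.

    initiation : (n_ages, 2), nonzero only for ages <= INIT_AGE_MAX
        Probability that a never smoker takes up smoking this year.
    cessation : (n_ages, 2), nonzero only for ages > INIT_AGE_MAX
        Probability that a current smoker makes a first-time quit this year
        (before relapse).
    relapse : (N_QUIT_BINS,)
        Probability that a former smoker in years-quit bin k returns to
        smoking this year.
    """

    initiation: np.ndarray
    cessation: np.ndarray
    relapse: np.ndarray
    init_age_max: int = INIT_AGE_MAX

    def __post_init__(self) -> None:
        self.initiation = as_grid(self.initiation, name="initiation")
        self.cessation = as_grid(self.cessation, name="cessation",
                                 n_ages=self.initiation.shape[0])
        self.relapse = np.asarray(self.relapse, dtype=float)
        if self.relapse.shape != (N_QUIT_BINS,):
            raise ValidationError(f"relapse must have shape ({N_QUIT_BINS},)")
        for name, arr in (("initiation", self.initiation),
                          ("cessation", self.cessation),
                          ("relapse", self.relapse)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} rates must lie in [0, 1]")
        cut = min(self.init_age_max + 1, self.initiation.shape[0])
        if np.any(self.initiation[cut:] > 0):
            raise ValidationError(
                f"initiation defined only for ages <= {self.init_age_max}")
        if np.any(self.cessation[:cut] > 0):
            raise ValidationError(
                f"cessation tracked only for ages > {self.init_age_max}")

    @property
    def n_ages(self) -> int:
        return self.initiation.shape[0]

    def copy(self) -> "TransitionRates":
        return TransitionRates(self.initiation.copy(), self.cessation.copy(),
                               self.relapse.copy(), self.init_age_max)


def derive_initiation_rates(prev_now: np.ndarray,
                            prev_last: np.ndarray,
                            never_share: np.ndarray | None = None,
                            init_age_max: int = INIT_AGE_MAX) -> np.ndarray:
    """Net initiation from consecutive prevalence curves.

    Initiation at age a is measured as the difference between this year's
    smoking rate at age a and last year's rate at age a-1, converted to a
    probability among never smokers by dividing by the never-smoker share.
    Negative differences (a declining cohort curve) are clamped to zero so
    state counts can never go negative.

    Parameters
    ----------
    prev_now, prev_last : arrays of prevalence in [0, 1]
        Either 1-D per-age curves or (n_ages, 2) per-gender grids, defined
        at least through ``init_age_max``.
    never_share : array, optional
        Share of never smokers at each age; defaults to ``1 - prev_now``
        (adequate below 30 where former smokers are rare).

    Returns
    -------
    array of the same shape as ``prev_now`` with zeros above ``init_age_max``.
    """
    prev_now = np.asarray(prev_now, dtype=float)
    prev_last = np.asarray(prev_last, dtype=float)
    if prev_now.shape != prev_last.shape:
        raise ValidationError("prevalence curves on different grids")
    for name, arr in (("prev_now", prev_now), ("prev_last", prev_last)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError(f"{name} outside [0, 1]")
    if never_share is None:
        never_share = 1.0 - prev_now
    else:
        never_share = np.asarray(never_share, dtype=float)
        if never_share.shape != prev_now.shape:
            raise ValidationError("never_share on a different grid")

    diff = np.empty_like(prev_now)
    diff[0] = 0.0  # no younger age to difference against
    diff[1:] = prev_now[1:] - prev_last[:-1]
    np.clip(diff, 0.0, None, out=diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        init = np.where(never_share > 0, diff / np.where(never_share > 0, never_share, 1.0), 0.0)
    init = np.clip(init, 0.0, 1.0)
    init[np.arange(prev_now.shape[0]) > init_age_max] = 0.0
    return init


def step_smoking_states(state: SmokingState, rates: TransitionRates) -> SmokingState:
    """One annual Markov transition (initiation, cessation, relapse).

    Former-smoker bins advance one year of abstinence unless the person
    relapses; this year's quitters enter bin 1.  No aging or mortality is
    applied here.  Output depends only on the input state and rates
    (first-order property).
    """
    if rates.n_ages != state.n_ages:
        raise ValidationError("rates and state on different age grids")
    new_smokers = state.never * rates.initiation
    quitters = state.current * rates.cessation
    relapsed = state.former * rates.relapse  # (n_ages, 2, bins)
    staying = state.former - relapsed

    former = np.zeros_like(state.former)
    former[..., 1:] = staying[..., :-1]
    former[..., -1] += staying[..., -1]  # 16+ absorbing
    former[..., 0] = quitters

    never = state.never - new_smokers
    current = state.current - quitters + new_smokers + relapsed.sum(axis=-1)

    for name, arr in (("never", never), ("current", current), ("former", former)):
        if np.any(arr < -_NEG_TOL):
            raise InternalError(f"negative {name} count after transition step")
    return SmokingState(np.clip(never, 0, None), np.clip(current, 0, None), former)


def compute_prevalence(state: SmokingState, age_lo: int = 0,
                       age_hi: int | None = None,
                       gender: str | None = None) -> float:
    """Current-smoker share of the population over an age range.

    ``age_hi`` is inclusive and defaults to the top bin; ``gender`` is
    ``"male"``, ``"female"`` or ``None`` for both.  Aggregation weights each
    cell by its population count.
    """
    if age_hi is None:
        age_hi = state.n_ages - 1
    if not (0 <= age_lo <= age_hi < state.n_ages):
        raise ValidationError(f"invalid age range [{age_lo}, {age_hi}]")
    sl = slice(age_lo, age_hi + 1)
    if gender is None or gender == "both":
        gs = slice(None)
    elif gender in GENDERS:
        gs = GENDERS.index(gender)
    else:
        raise ValidationError(f"unknown gender selector {gender!r}")
    total = state.population()[sl, gs].sum()
    if total <= 0:
        raise ValidationError("empty selection: no population in range")
    return float(state.current[sl, gs].sum() / total)
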