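"""Smoking-attributable mortality via relative risks.

All-cause mortality per age x gender cell is split into status-specific
rates by solving for the never-smoker rate that, weighted by the cell's
status shares and relative risks, recombines exactly to the overall rate:

    m_never = m_overall / (p_never + rr_cur * p_cur + sum_k rr_former(k) * p_former(k))

Smoking-attributable deaths (SADs) are then the excess deaths of current and
former smokers over what they would suffer at the never-smoker rate.
Because the never-smoker rate is re-solved per cell per year, attribution
adapts as prevalence changes.  SADs are counted from age 30 upward: the
excess-risk schedule is 1 below that age, so younger cohorts contribute no
attributable deaths until they reach 30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grids import as_grid
from .smoking import N_QUIT_BINS, SmokingState

#: attributable deaths are counted at ages >= this
SAD_AGE_MIN: int = 30


@dataclass
class RelativeRisks:
    """All-cause mortality relative risks versus never smokers.

    current : (n_ages, 2), all >= 1
    former : (n_ages, 2, N_QUIT_BINS), >= 1 and non-increasing in years quit
        (risk declines toward the never-smoker level with abstinence).
    """

    current: np.ndarray
    former: np.ndarray

    def __post_init__(self) -> None:
        self.current = as_grid(self.current, name="rr_current")
        self.former = np.asarray(self.former, dtype=float)
        if self.former.shape != (self.current.shape[0], 2, N_QUIT_BINS):
            raise ValidationError(
                f"rr_former must have shape (n_ages, 2, {N_QUIT_BINS})")
        if np.any(self.current < 1) or np.any(self.former < 1):
            raise ValidationError("relative risks must be >= 1")
        if np.any(np.diff(self.former, axis=-1) > 1e-12):
            raise ValidationError("rr_former must be non-increasing in years quit")

    @property
    def n_ages(self) -> int:
        return self.current.shape[0]

    def scaled(self, factor_minus_one_scale: float) -> "RelativeRisks":
        """Rescale excess risk (rr - 1) by a common factor.

        Used for sensitivity runs, e.g. moving the current-smoker relative
        risk from about 2.1 down to 1.6 while keeping the former-smoker
        decay shape.
        """
        return RelativeRisks(
            1.0 + (self.current - 1.0) * factor_minus_one_scale,
            1.0 + (self.former - 1.0) * factor_minus_one_scale,
        )


@dataclass
class StatusMortality:
    """Status-specific annual death probabilities per cell."""

    never: np.ndarray            # (n_ages, 2)
    current: np.ndarray          # (n_ages, 2)
    former: np.ndarray           # (n_ages, 2, N_QUIT_BINS)


def partition_mortality(overall_mortality: float,
                        shares: tuple[float, float, np.ndarray],
                        rr_current: float,
                        rr_former: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Split one cell's overall mortality rate by smoking status.

    ``shares`` is ``(p_never, p_current, p_former_by_bin)`` and must sum to 1.
    Returns ``(m_never, m_current, m_former_by_bin)``; recombining these with
    the shares reproduces the overall rate.
    """
    p_never, p_cur, p_former = shares
    p_former = np.asarray(p_former, dtype=float)
    total = p_never + p_cur + p_former.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"status shares must sum to 1, got {total}")
    if not 0.0 <= overall_mortality <= 1.0:
        raise ValidationError("overall mortality must lie in [0, 1]")
    rr_former = np.asarray(rr_former, dtype=float)
    denom = p_never + rr_current * p_cur + float(rr_former @ p_former)
    m_never = overall_mortality / denom
    m_current = rr_current * m_never
    if m_current > 1.0:
        warnings.warn("status-specific mortality exceeded 1 and was clamped",
                      RuntimeWarning, stacklevel=2)
        m_current = 1.0
    return m_never, m_current, np.minimum(rr_former * m_never, 1.0)


def partition_mortality_grid(overall: np.ndarray, state: SmokingState,
                             rr: RelativeRisks) -> StatusMortality:
    """Vectorised :func:`partition_mortality` over a full grid.

    Empty cells keep the overall rate for every status.
    """
    overall = as_grid(overall, name="overall mortality", n_ages=state.n_ages)
    if np.any(overall > 1):
        raise ValidationError("mortality probabilities must be <= 1")
    if rr.n_ages != state.n_ages:
        raise ValidationError("relative risks and state on different grids")
    pop = state.population()
    safe_pop = np.where(pop > 0, pop, 1.0)
    p_never = state.never / safe_pop
    p_cur = state.current / safe_pop
    p_former = state.former / safe_pop[..., None]
    denom = p_never + rr.current * p_cur + (rr.former * p_former).sum(axis=-1)
    denom = np.where(pop > 0, denom, 1.0)
    m_never = overall / denom
    m_current = rr.current * m_never
    m_former = rr.former * m_never[..., None]
    if np.any(m_current > 1.0) or np.any(m_former > 1.0):
        warnings.warn("status-specific mortality exceeded 1 and was clamped",
                      RuntimeWarning, stacklevel=2)
        m_current = np.minimum(m_current, 1.0)
        m_former = np.minimum(m_former, 1.0)
    return StatusMortality(m_never, m_current, m_former)


def compute_sads(state: SmokingState, status_mortality: StatusMortality,
                 age_min: int = SAD_AGE_MIN) -> np.ndarray:
    """Smoking-attributable deaths per age x gender cell.

    Excess deaths of smokers and former smokers relative to the never-smoker
    rate, zero below ``age_min``.  Non-negative whenever all relative risks
    are >= 1; a negative total signals rr < 1 input.
    """
    sm = status_mortality
    excess = (state.current * (sm.current - sm.never)
              + (state.former * (sm.former - sm.never[..., None])).sum(axis=-1))
    excess[:min(age_min, state.n_ages)] = 0.0
    return excess


def cumulative_sads(yearly: pd.Series, year_lo: int, year_hi: int) -> float:
    """Inclusive sum of a yearly SAD series over [year_lo, year_hi]."""
    yearly = pd.Series(yearly)
    missing = [y for y in range(year_lo, year_hi + 1) if y not in yearly.index]
    if missing:
        raise ValidationError(f"SAD series missing years {missing[:5]}")
    return float(yearly.loc[year_lo:year_hi].sum())
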