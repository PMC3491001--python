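"""Age x gender grids and their tabular (CSV) representation.

Counts and rates are dense float arrays of shape ``(n_ages, 2)``.  Axis 0 is
single-year age ascending from 0; the final row is an open-ended top bin that
accumulates survivors.  Axis 1 is gender in the fixed order ``(male, female)``.

The default grid spans ages 0..100 with 100+ as the open top bin, but every
operation accepts smaller grids (toy worlds for oracle tests) as long as the
two sides of an operation agree on the grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError

GENDERS: tuple[str, str] = ("male", "female")
MALE: int = 0
FEMALE: int = 1

#: default number of single-year ages (0..99 plus the open 100+ bin)
N_AGES_DEFAULT: int = 101


def as_grid(values, n_ages: int | None = None, name: str = "grid",
            allow_negative: bool = False) -> np.ndarray:
    """Coerce ``values`` to a float ``(n_ages, 2)`` array and validate it.

    Parameters
    ----------
    values : array-like
        Anything ``np.asarray`` accepts; must have shape ``(n, 2)``.
    n_ages : int, optional
        If given, the required number of age rows.
    name : str
        Used in error messages.
    allow_negative : bool
        Rates derived from differences may be negative; counts may not.
    """
    arr = np.array(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(GENDERS):
        raise GridMismatchError(
            f"{name}: expected shape (n_ages, 2), got {arr.shape}")
    if n_ages is not None and arr.shape[0] != n_ages:
        raise GridMismatchError(
            f"{name}: expected {n_ages} age rows, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite values")
    if not allow_negative and np.any(arr < 0):
        raise ValidationError(f"{name}: negative values not allowed")
    return arr


def check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "operands") -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"{what} on different grids: {a.shape} vs {b.shape}")


def grid_to_frame(grid: np.ndarray, value_name: str = "value") -> pd.DataFrame:
    """Long-format DataFrame with columns ``age, gender, value``."""
    grid = as_grid(grid, allow_negative=True)
    n = grid.shape[0]
    return pd.DataFrame({
        "age": np.repeat(np.arange(n), 2),
        "gender": list(GENDERS) * n,
        value_name: grid.reshape(-1),
    })


def frame_to_grid(df: pd.DataFrame, value_name: str = "value") -> np.ndarray:
    """Inverse of :func:`grid_to_frame`; tolerant of row order."""
    for col in ("age", "gender", value_name):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    ages = np.sort(df["age"].unique())
    if not np.array_equal(ages, np.arange(len(ages))):
        raise ValidationError("ages must be contiguous integers starting at 0")
    grid = np.zeros((len(ages), 2))
    seen = np.zeros((len(ages), 2), dtype=bool)
    gender_index = {g: i for i, g in enumerate(GENDERS)}
    for age, gender, value in df[["age", "gender", value_name]].itertuples(index=False):
        try:
            gi = gender_index[gender]
        except KeyError:
            raise ValidationError(f"unknown gender label {gender!r}") from None
        grid[int(age), gi] = value
        seen[int(age), gi] = True
    if not seen.all():
        raise ValidationError("incomplete grid: some age/gender cells missing")
    return grid


def read_grid_csv(path, value_name: str = "value") -> np.ndarray:
    return frame_to_grid(pd.read_csv(path), value_name=value_name)


def write_grid_csv(grid: np.ndarray, path, value_name: str = "value") -> None:
    grid_to_frame(grid, value_name=value_name).to_csv(path, index=False)
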