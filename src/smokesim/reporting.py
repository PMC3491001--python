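"""Comparison tables, long-format exports and basic plots.

Prevalence is rendered as percent to one decimal and death counts as
integers only at this boundary; the CSV exports keep unrounded values so
every reported number can be recomputed from the emitted series.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scenario import ScenarioResult, deaths_averted


def render_comparison_table(results: list[ScenarioResult],
                            years: tuple[int, ...] | None = None,
                            metric: str = "prevalence") -> pd.DataFrame:
    """Scenarios as rows, years as columns.

    ``metric`` is ``"prevalence"`` (percent, 1 decimal, ages 18+, both
    genders), ``"sads"`` or ``"cumulative_sads"`` (rounded to integers).
    When exactly one scenario is labelled ``counterfactual`` and the metric
    is a death count, a ``deaths_averted:<label>`` row is appended for each
    other scenario (the accounting identity row of the published tables).
    """
    if not results:
        raise ValidationError("need at least one scenario result")
    if years is None:
        years = (int(results[0].years[0]), int(results[0].years[-1]))
    rows = {}
    for res in results:
        if metric == "prevalence":
            rows[res.label] = [round(res.prevalence.loc[y, "both"] * 100, 1)
                               for y in years]
        elif metric == "sads":
            rows[res.label] = [int(round(res.sads.loc[y])) for y in years]
        elif metric == "cumulative_sads":
            rows[res.label] = [int(round(res.cumulative_sads.loc[y])) for y in years]
        else:
            raise ValidationError(f"unknown metric {metric!r}")
    table = pd.DataFrame(rows, index=[str(y) for y in years]).T
    cf = [r for r in results if r.label == "counterfactual"]
    if len(cf) == 1 and metric in ("sads", "cumulative_sads"):
        for res in results:
            if res.label == "counterfactual":
                continue
            if metric == "sads":
                vals = [int(round(deaths_averted(res, cf[0], year=y))) for y in years]
            else:
                base = int(cf[0].years[0])
                vals = [int(round(deaths_averted(res, cf[0], year_range=(base, y))))
                        for y in years]
            table.loc[f"deaths_averted:{res.label}"] = vals
    return table


def results_to_long_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Unrounded long-format export: scenario, bound, year, metric, group,
    value."""
    records = []
    for res in results:
        for year in res.years:
            for group in ("male", "female", "both"):
                records.append((res.label, res.bound, int(year), "prevalence",
                                group, res.prevalence.loc[year, group]))
            records.append((res.label, res.bound, int(year), "sads", "both",
                            res.sads.loc[year]))
            records.append((res.label, res.bound, int(year), "cumulative_sads",
                            "both", res.cumulative_sads.loc[year]))
    return pd.DataFrame(records, columns=["scenario", "bound", "year", "metric",
                                          "group", "value"])


def plot_prevalence(results: list[ScenarioResult], path=None):
    """Line chart of adult smoking prevalence per scenario; saves to ``path``
    if given, else returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for res in results:
        ax.plot(res.years, res.prevalence["both"] * 100,
                label=f"{res.label} ({res.bound})")
    ax.set_xlabel("year")
    ax.set_ylabel("smoking prevalence, ages 18+ (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_sads(results: list[ScenarioResult], path=None):
    """Line chart of yearly smoking-attributable deaths per scenario."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for res in results:
        ax.plot(res.years, res.sads, label=f"{res.label} ({res.bound})")
    ax.set_xlabel("year")
    ax.set_ylabel("smoking-attributable deaths per year")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
        return None
    return fig
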