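"""Input/output: bundle persistence, config parsing, input validation.

All tabular data travel as plain CSV (RFC 4180, UTF-8, header required);
policy schedules and run configuration as YAML; full smoking states can be
checkpointed as JSON.  Percentages are stored as proportions everywhere
inside the package and scaled to percent only at the reporting boundary.

Exit-code convention for the command-line tool: 0 ok, 1 validation failure,
2 I/O error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import DemographicRates
from .errors import ConfigError, SmokesimError, ValidationError
from .fixtures import FixtureBundle
from .grids import read_grid_csv, write_grid_csv
from .mortality import RelativeRisks
from .policy import DOMAINS, PolicySchedule
from .smoking import N_QUIT_BINS, SmokingState, TransitionRates

EXIT_OK, EXIT_VALIDATION, EXIT_IO = 0, 1, 2


@dataclass
class RunConfig:
    """Paths and options for a command-line simulation run."""

    bundle_dir: str | None = None
    base_year: int = 1989
    horizon: int = 2050
    scenarios: list[str] = field(default_factory=lambda: ["counterfactual", "all"])
    bounds: list[str] = field(default_factory=lambda: ["central"])
    output_dir: str = "smokesim-output"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.base_year < self.horizon <= self.base_year + 200:
            raise ConfigError("require base_year < horizon <= base_year + 200")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------

_FILES = {
    "population": "population.csv",
    "mortality": "mortality.csv",
    "fertility": "fertility.csv",
    "smoking": "smoking_state.csv",
    "initiation": "initiation.csv",
    "cessation": "cessation.csv",
    "relapse": "relapse.csv",
    "rr_current": "rr_current.csv",
    "rr_former": "rr_former.csv",
    "schedule": "schedule.yaml",
    "meta": "meta.yaml",
}


def save_bundle(bundle: FixtureBundle, directory) -> Path:
    """Write a fixture bundle as a directory of CSV/YAML files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_grid_csv(bundle.population, d / _FILES["population"])
    write_grid_csv(bundle.demographic_rates.mortality, d / _FILES["mortality"])
    pd.DataFrame({"age": np.arange(len(bundle.demographic_rates.fertility)),
                  "value": bundle.demographic_rates.fertility}
                 ).to_csv(d / _FILES["fertility"], index=False)
    bundle.smoking.to_frame().to_csv(d / _FILES["smoking"], index=False)
    write_grid_csv(bundle.transitions.initiation, d / _FILES["initiation"])
    write_grid_csv(bundle.transitions.cessation, d / _FILES["cessation"])
    pd.DataFrame({"years_quit": np.arange(1, N_QUIT_BINS + 1),
                  "value": bundle.transitions.relapse}
                 ).to_csv(d / _FILES["relapse"], index=False)
    write_grid_csv(bundle.relative_risks.current, d / _FILES["rr_current"])
    rr_rows = []
    for k in range(N_QUIT_BINS):
        frame = pd.DataFrame({
            "age": np.repeat(np.arange(bundle.relative_risks.n_ages), 2),
            "gender": ["male", "female"] * bundle.relative_risks.n_ages,
            "years_quit": k + 1,
            "value": bundle.relative_risks.former[:, :, k].reshape(-1),
        })
        rr_rows.append(frame)
    pd.concat(rr_rows).to_csv(d / _FILES["rr_former"], index=False)
    with open(d / _FILES["schedule"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.schedule.to_dict(), fh, sort_keys=True)
    with open(d / _FILES["meta"], "w", encoding="utf-8") as fh:
        yaml.safe_dump({"base_year": bundle.base_year, "horizon": bundle.horizon,
                        "seed": bundle.seed}, fh)
    return d


def load_bundle(directory) -> FixtureBundle:
    """Inverse of :func:`save_bundle`."""
    d = Path(directory)
    try:
        with open(d / _FILES["meta"], "r", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
        population = read_grid_csv(d / _FILES["population"])
        mortality = read_grid_csv(d / _FILES["mortality"])
        fert_df = pd.read_csv(d / _FILES["fertility"]).sort_values("age")
        smoking = SmokingState.from_frame(pd.read_csv(d / _FILES["smoking"]))
        initiation = read_grid_csv(d / _FILES["initiation"])
        cessation = read_grid_csv(d / _FILES["cessation"])
        relapse_df = pd.read_csv(d / _FILES["relapse"]).sort_values("years_quit")
        rr_current = read_grid_csv(d / _FILES["rr_current"])
        rr_former_df = pd.read_csv(d / _FILES["rr_former"])
        with open(d / _FILES["schedule"], "r", encoding="utf-8") as fh:
            schedule = PolicySchedule.from_dict(yaml.safe_load(fh))
    except OSError as exc:
        raise SmokesimError(f"cannot read bundle: {exc}") from exc
    n_ages = population.shape[0]
    rr_former = np.ones((n_ages, 2, N_QUIT_BINS))
    gi = {"male": 0, "female": 1}
    for age, g, yq, value in rr_former_df[
            ["age", "gender", "years_quit", "value"]].itertuples(index=False):
        rr_former[int(age), gi[g], int(yq) - 1] = value
    return FixtureBundle(
        base_year=int(meta["base_year"]), horizon=int(meta["horizon"]),
        population=population,
        demographic_rates=DemographicRates(fert_df["value"].to_numpy(), mortality),
        smoking=smoking,
        transitions=TransitionRates(initiation, cessation,
                                    relapse_df["value"].to_numpy()),
        relative_risks=RelativeRisks(rr_current, rr_former),
        schedule=schedule, seed=int(meta.get("seed", 0)))


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of :func:`validate_inputs`: a list of human-readable
    violations with their locations; empty iff the bundle is valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "all input invariants satisfied"
        return "\n".join(f"- {v}" for v in self.violations)


def validate_inputs(bundle: FixtureBundle, rtol: float = 1e-9) -> ValidationReport:
    """Check every documented input invariant; list each violation with its
    location rather than stopping at the first."""
    v: list[str] = []
    pop = np.asarray(bundle.population, dtype=float)
    if np.any(pop < 0):
        for a, g in zip(*np.where(pop < 0)):
            v.append(f"population[age={a}, gender={'male' if g == 0 else 'female'}] "
                     f"is negative ({pop[a, g]:g})")
    rates = bundle.demographic_rates
    if np.any(rates.mortality < 0) or np.any(rates.mortality > 1):
        v.append("mortality rates outside [0, 1]")
    if np.any(rates.fertility < 0):
        v.append("negative fertility rates")

    state = bundle.smoking
    total = state.population()
    scale = np.maximum(pop, 1.0)
    bad = np.abs(total - pop) > rtol * scale
    for a, g in zip(*np.where(bad)):
        v.append(f"smoking-state counts at age={a}, "
                 f"gender={'male' if g == 0 else 'female'} sum to {total[a, g]:.6g} "
                 f"but population is {pop[a, g]:.6g}")
    for name, arr in (("never", state.never), ("current", state.current),
                      ("former", state.former)):
        if np.any(arr < 0):
            v.append(f"negative {name}-smoker counts")

    tr = bundle.transitions
    for name, arr in (("initiation", tr.initiation), ("cessation", tr.cessation),
                      ("relapse", tr.relapse)):
        if np.any(arr < 0) or np.any(arr > 1):
            v.append(f"{name} rates outside [0, 1]")

    rr = bundle.relative_risks
    if np.any(rr.current < 1) or np.any(rr.former < 1):
        v.append("relative risks below 1")
    if np.any(np.diff(rr.former, axis=-1) > 1e-9):
        v.append("former-smoker relative risks increase with years quit")

    try:
        for year in range(bundle.base_year, bundle.horizon + 1):
            bundle.schedule.price_ratio(year)
            for domain in DOMAINS:
                bundle.schedule.spec(domain, year)
    except SmokesimError as exc:
        v.append(f"policy schedule does not cover the horizon: {exc}")
    if bundle.schedule.base_year != bundle.base_year:
        v.append("schedule base year differs from bundle base year")
    return ValidationReport(v)
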