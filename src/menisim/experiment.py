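"""Replication engine: full runs of both paradigms and the sensitivity sweep.

A replication simulates a 20-year (1040-week) system window. 1040 patients
arrive by a Poisson-like process; in the traditional paradigm they queue
for donor menisci (timing out to TKA at 104 weeks), in the 3DP paradigm
each is transplanted immediately at arrival with a printed implant. Every
transplanted patient then follows the annual-cycle Markov model from their
own surgery date; costs are accrued per week/event and binned into calendar
years. Experiments average 10 independent replications.

Random streams are derived from a master seed by named substreams
(patient arrivals, donors, per-patient trajectory uniforms), so paradigms
and scenarios compared under the same seed share their patients and
trajectory randomness (common random numbers).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .costing import CostTable, accrue_patient_cost
from .model_core import HealthState, Scenario, TransitionMatrix, scenario_matrix
from .progression import Trajectory, simulate_post_transplant
from .queue_sim import (
    QueueDisposition,
    QueueOutcome,
    run_allocation,
    sample_donor_arrivals,
    sample_patient_arrivals,
)

__all__ = [
    "TRADITIONAL",
    "THREE_DP",
    "SimulationConfig",
    "YearlyOutputs",
    "ExperimentResult",
    "run_replication",
    "run_experiment",
    "run_sensitivity",
    "load_config",
]

TRADITIONAL = "traditional"
THREE_DP = "3dp"

# Substream identifiers (SeedSequence spawn keys) per replication.
_STREAM_PATIENTS = 0
_STREAM_DONORS = 1
_STREAM_TRAJECTORIES = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration for one paradigm/scenario experiment.

    Defaults reproduce the study conditions: 1040 patients arriving with
    mean interarrival 1 week over a 20-year horizon, a 104-week waiting
    timeout, donor interarrival means drawn from Uniform(1, 5) weeks, an
    intermediate-entry cap of 2, and averages over 10 replications.
    """

    paradigm: str = TRADITIONAL
    scenario: Scenario = Scenario.ORIGINAL
    n_patients: int = 1040
    horizon_years: int = 20
    weeks_per_year: int = 52
    wait_threshold: float = 104.0
    patient_mean_interarrival: float = 1.0
    donor_mean_range: tuple[float, float] = (1.0, 5.0)
    donor_mean_per_gap: bool = True
    n_replications: int = 10
    seed: int = 0
    intermediate_cap: int = 2
    r_to_ro_new_entry: bool = True
    costs: CostTable | None = None
    matrix_override: "TransitionMatrix | None" = None

    def __post_init__(self) -> None:
        if self.paradigm not in (TRADITIONAL, THREE_DP):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if min(self.n_patients, self.horizon_years, self.n_replications) < 1:
            raise ValueError("n_patients, horizon_years, n_replications must be >= 1")
        if self.wait_threshold <= 0 or self.wait_threshold > self.horizon_weeks:
            raise ValueError("wait_threshold must lie in (0, horizon]")
        object.__setattr__(self, "scenario", Scenario(self.scenario))

    @property
    def horizon_weeks(self) -> float:
        return float(self.horizon_years * self.weeks_per_year)

    @property
    def cost_table(self) -> CostTable:
        if self.costs is not None:
            return self.costs
        return CostTable.three_dp() if self.paradigm == THREE_DP else CostTable.traditional()

    @property
    def transition_matrix(self) -> "TransitionMatrix":
        if self.matrix_override is not None:
            return self.matrix_override
        return scenario_matrix(self.scenario)


@dataclass(frozen=True)
class YearlyOutputs:
    """Cumulative outputs at the end of each calendar year 1..horizon.

    ``cum_tka_waiting`` counts TKAs forced by the queue timeout,
    ``cum_tka_post`` those reached through the post-transplant Markov
    model, and ``cum_cost_usd`` the gross cost of all patients so far.
    """

    years: np.ndarray
    cum_tka_waiting: np.ndarray
    cum_tka_post: np.ndarray
    cum_cost_usd: np.ndarray

    @property
    def cum_tka_total(self) -> np.ndarray:
        return self.cum_tka_waiting + self.cum_tka_post

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "cum_tka_waiting": self.cum_tka_waiting,
                "cum_tka_post": self.cum_tka_post,
                "cum_tka_total": self.cum_tka_total,
                "cum_cost_usd": self.cum_cost_usd,
            }
        )


@dataclass(frozen=True)
class ExperimentResult:
    """Replication average of :class:`YearlyOutputs`, with standard errors."""

    mean: YearlyOutputs
    sem: YearlyOutputs
    n_replications: int

    def frame(self) -> pd.DataFrame:
        out = self.mean.frame()
        sem = self.sem.frame()
        for col in ("cum_tka_waiting", "cum_tka_post", "cum_tka_total", "cum_cost_usd"):
            out[f"sem_{col}"] = sem[col]
        return out


def _replication_rngs(seed: int, replication: int) -> dict[int, np.random.Generator]:
    return {
        stream: np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replication, stream)))
        for stream in (_STREAM_PATIENTS, _STREAM_DONORS, _STREAM_TRAJECTORIES)
    }


def _year_of(week: float, weeks_per_year: int, horizon_years: int) -> int:
    """Calendar year of an event week: year y covers weeks (52(y-1), 52y]."""
    return min(horizon_years, max(1, math.ceil(week / weeks_per_year)))


def run_replication(config: SimulationConfig, replication: int = 0) -> YearlyOutputs:
    """Run one seeded replication and return its cumulative yearly outputs."""
    rngs = _replication_rngs(config.seed, replication)
    horizon = config.horizon_weeks
    wpy = config.weeks_per_year
    years = config.horizon_years
    matrix = config.transition_matrix
    costs = config.cost_table

    arrivals = sample_patient_arrivals(
        config.n_patients, config.patient_mean_interarrival, rngs[_STREAM_PATIENTS]
    )
    # One uniform per patient-cycle, drawn identically for every paradigm and
    # scenario under the same seed: the common-random-number backbone.
    traj_uniforms = rngs[_STREAM_TRAJECTORIES].random((config.n_patients, years))

    if config.paradigm == TRADITIONAL:
        donors = sample_donor_arrivals(
            horizon,
            rngs[_STREAM_DONORS],
            config.donor_mean_range,
            resample_mean_per_gap=config.donor_mean_per_gap,
        )
        dispositions = run_allocation(arrivals, donors, config.wait_threshold)
    else:
        dispositions = [
            QueueDisposition(i, t, QueueOutcome.TRANSPLANTED, t)
            for i, t in enumerate(arrivals)
        ]

    tka_waiting = np.zeros(years)
    tka_post = np.zeros(years)
    cost = np.zeros(years)
    for disp in dispositions:
        trajectory: Trajectory | None = None
        if disp.outcome == QueueOutcome.TRANSPLANTED:
            n_cycles = max(0, int((horizon - disp.event_week) // wpy))
            trajectory = simulate_post_transplant(
                matrix,
                n_cycles,
                config.intermediate_cap,
                uniforms=traj_uniforms[disp.patient],
                r_to_ro_new_entry=config.r_to_ro_new_entry,
            )
            if trajectory.reached_tka:
                week = disp.event_week + wpy * trajectory.tka_cycle
                tka_post[_year_of(week, wpy, years) - 1] += 1
        elif disp.event_week <= horizon:  # timeouts past the horizon are censored
            tka_waiting[_year_of(disp.event_week, wpy, years) - 1] += 1
        for week, usd in accrue_patient_cost(disp, trajectory, costs, horizon, wpy):
            cost[_year_of(week, wpy, years) - 1] += usd

    return YearlyOutputs(
        years=np.arange(1, years + 1),
        cum_tka_waiting=np.cumsum(tka_waiting),
        cum_tka_post=np.cumsum(tka_post),
        cum_cost_usd=np.cumsum(cost),
    )


def run_experiment(config: SimulationConfig) -> ExperimentResult:
    """Average ``config.n_replications`` independent replications."""
    runs = [run_replication(config, rep) for rep in range(config.n_replications)]
    waiting = np.vstack([r.cum_tka_waiting for r in runs])
    post = np.vstack([r.cum_tka_post for r in runs])
    cost = np.vstack([r.cum_cost_usd for r in runs])
    years = runs[0].years

    def sem(stack: np.ndarray) -> np.ndarray:
        if len(runs) == 1:
            return np.zeros(stack.shape[1])
        return stack.std(axis=0, ddof=1) / math.sqrt(len(runs))

    return ExperimentResult(
        mean=YearlyOutputs(years, waiting.mean(0), post.mean(0), cost.mean(0)),
        sem=YearlyOutputs(years, sem(waiting), sem(post), sem(cost)),
        n_replications=len(runs),
    )


def run_sensitivity(
    base_config: SimulationConfig,
    scenarios: Sequence[Scenario | str] | None = None,
) -> dict[Scenario, ExperimentResult]:
    """Run the implant-quality sweep with common random numbers.

    Every scenario reuses the master seed and substream construction of
    ``base_config``, so differences between scenarios reflect only the
    transition-matrix scaling. Requires the 3DP paradigm (the sweep varies
    implant quality).
    """
    if base_config.paradigm != THREE_DP:
        raise ValueError("the sensitivity sweep applies to the 3dp paradigm")
    if scenarios is None:
        scenarios = list(Scenario)
    results: dict[Scenario, ExperimentResult] = {}
    for scenario in scenarios:
        scenario = Scenario(scenario)
        results[scenario] = run_experiment(
            dataclasses.replace(base_config, scenario=scenario)
        )
    return results


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML or JSON file.

    Recognised keys mirror the dataclass fields; an optional ``costs``
    mapping mirrors the cost table (``no_issue``, ``repair``,
    ``reoperation``, ``tka``, ``waiting_per_week``, ``transplantation``).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        raw: Mapping = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    raw = dict(raw)
    if "costs" in raw and raw["costs"] is not None:
        raw["costs"] = CostTable(**raw["costs"])
    if "donor_mean_range" in raw:
        raw["donor_mean_range"] = tuple(raw["donor_mean_range"])
    return SimulationConfig(**raw)
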