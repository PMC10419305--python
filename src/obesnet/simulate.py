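"""Simulation orchestration: warm-up, monthly stepping, demographic churn,
scenarios and aggregation.

Each simulated month applies, in a fixed documented order:

1. one network slot (offers / acceptances / memory roll);
2. the TPB behaviour step (neighbourhood means, inflows, stocks,
   NORMAL -> DIETING transitions, diet countdown and success bookkeeping);
3. the energy-balance weight update;
4. demographics (age advance, scheduled adolescent entrants and deaths).

Changing this order is a breaking change.  A warm-up phase of network and
behaviour stepping with weights and demographics frozen lets the contact
structure reach its stationary topology before outcomes are recorded.
Aggregation produces the reference-series shape (mean/median BMI per
year x gender x age group); yearly network snapshots feed the topography
reports.

Scenarios follow a 3 x 3 grid of falling/static/rising trends in the
external-factor series and in the mean BMI of 16-year-old entrants, plus a
network-effect on/off switch for counterfactual comparisons (off disables
the norms flow and the neighbourhood condition of the diet trigger).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .behaviour import (
    ActivationBuffer,
    inflows_vector,
    neighbour_mean_bmi,
    transitions_vector,
    update_stocks_vector,
)
from .energy import EnergyCoefficients, ExternalFactorSeries, intake_vector, tee_vector, weight_update_vector
from .errors import ConfigurationError, ExtinctionError
from .groups import AGE_GROUP_LABELS, Gender
from .network import CandidateIndex, NetworkMetrics, NetworkState, compute_metrics, step_network
from .params import ParameterSet
from .population import (
    Population,
    PopulationProfile,
    STATE_DIETING,
    STATE_NORMAL,
    generate_population,
    pal_category,
    sample_entrant,
)

__all__ = [
    "ScenarioSpec",
    "SimulationConfig",
    "SimulationResult",
    "apply_scenario",
    "compare_runs",
    "run",
]

#: Scenario numbering of the 3 x 3 (external factor, adolescent BMI) grid.
SCENARIO_GRID: dict[tuple[str, str], int] = {
    ("static", "static"): 1,
    ("falling", "rising"): 2,
    ("falling", "static"): 3,
    ("falling", "falling"): 4,
    ("static", "rising"): 5,
    ("static", "falling"): 6,
    ("rising", "rising"): 7,
    ("rising", "static"): 8,
    ("rising", "falling"): 9,
}

Trend = Literal["falling", "static", "rising"]


class ScenarioSpec(BaseModel):
    """One cell of the scenario grid plus the network-effect switch.

    ``annual_rate`` is the fractional change per year applied to whichever
    quantity is trending; ``rate_multiplier`` scales it (2 for the
    doubled-rate runs).
    """

    ef_trend: Trend = "static"
    adolescent_trend: Trend = "static"
    annual_rate: float = Field(default=0.005, ge=0.0)
    rate_multiplier: float = Field(default=1.0, gt=0.0)
    network_effect: Literal["on", "off"] = "on"

    @property
    def number(self) -> int:
        return SCENARIO_GRID[(self.ef_trend, self.adolescent_trend)]

    @classmethod
    def from_number(cls, number: int, **kwargs) -> "ScenarioSpec":
        for (ef, adol), num in SCENARIO_GRID.items():
            if num == number:
                return cls(ef_trend=ef, adolescent_trend=adol, **kwargs)
        raise ConfigurationError(f"scenario number must be 1..9, got {number}")

    def yearly_factor(self, trend: str, years_elapsed: int) -> float:
        rate = self.annual_rate * self.rate_multiplier
        if trend == "static":
            return 1.0
        sign = 1.0 if trend == "rising" else -1.0
        return float((1.0 + sign * rate) ** years_elapsed)


class SimulationConfig(BaseModel):
    """Everything one simulation run needs.

    ``horizon_months`` counts simulated months after warm-up; aggregates
    are recorded for the initial year and after every 12 months.  Births
    and deaths are annual quotas scheduled evenly across months.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_initial: int = Field(default=1000, ge=1)
    horizon_months: int = Field(default=120, ge=0)
    warmup_months: int = Field(default=24, ge=0)
    births_per_year: int = Field(default=12, ge=0)
    deaths_per_year: int = Field(default=7, ge=0)
    seed: int = 0
    start_year: int = 0
    params: ParameterSet = Field(default_factory=ParameterSet)
    profile: PopulationProfile = Field(default_factory=PopulationProfile)
    external_factors: Optional[ExternalFactorSeries] = None
    scenario: Optional[ScenarioSpec] = None
    entrant_bmi_mean: float = Field(default=22.0, gt=12.0, lt=60.0)
    energy_coeffs: Optional[EnergyCoefficients] = None
    initial_population: Optional[Population] = None
    collect_metrics_every: int = Field(default=12, ge=0)
    collect_event_log: bool = True
    collect_samples: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.initial_population is not None and self.initial_population.n_alive == 0:
            raise ValueError("initial population has no living agents")
        return self

    def resolved_external_factors(self) -> ExternalFactorSeries:
        """The APCCC series actually used: the configured one, under any
        scenario trend, or a flat baseline series."""
        n_years = self.horizon_months // 12 + 1
        series = self.external_factors or ExternalFactorSeries.constant(
            2200.0, self.start_year, n_years
        )
        if self.scenario is not None and self.scenario.ef_trend != "static":
            values = {
                year: series.values[year]
                * self.scenario.yearly_factor(self.scenario.ef_trend, year - self.start_year)
                for year in series.values
            }
            series = ExternalFactorSeries(values=values, baseline_year=series.baseline_year)
        return series

    def entrant_mean_for_year(self, year: int) -> float:
        mean = self.entrant_bmi_mean
        if self.scenario is not None:
            mean *= self.scenario.yearly_factor(
                self.scenario.adolescent_trend, year - self.start_year
            )
        return mean

    @property
    def network_effect(self) -> bool:
        return self.scenario is None or self.scenario.network_effect == "on"


@dataclass
class SimulationResult:
    """Outputs of one run.

    ``reference`` is the aggregate BMI table (year x gender x age group,
    mean and median plus cell count); ``metrics`` the per-snapshot network
    topography; ``events`` a JSONL-able log of births, deaths, diet
    episodes and per-month total norms flow.
    """

    reference: pd.DataFrame
    metrics: list[tuple[int, NetworkMetrics]]
    population: Population
    state: NetworkState
    config: SimulationConfig
    events: list[dict] = dc_field(default_factory=list)
    samples: dict[int, pd.DataFrame] = dc_field(default_factory=dict)

    @property
    def final_agent_count(self) -> int:
        return self.population.n_alive


def _aggregate_year(pop: Population, year: int,
                    collect_samples: bool) -> tuple[list[dict], pd.DataFrame | None]:
    rows = []
    alive = pop.alive
    bmi = pop.bmi
    groups = pop.age_group
    for g in (0, 1):
        for a in range(len(AGE_GROUP_LABELS)):
            mask = alive & (pop.gender == g) & (groups == a)
            cell = bmi[mask]
            rows.append(
                {
                    "year": year,
                    "gender": str(Gender(g)),
                    "age_group": AGE_GROUP_LABELS[a],
                    "mean_bmi": float(np.mean(cell)) if len(cell) else float("nan"),
                    "median_bmi": float(np.median(cell)) if len(cell) else float("nan"),
                    "n": int(len(cell)),
                }
            )
    samples = None
    if collect_samples:
        samples = pd.DataFrame(
            {"gender": pop.gender[alive], "age_group": groups[alive], "bmi": bmi[alive]}
        )
    return rows, samples


def _monthly_quota(rate_per_year: int, month_in_year: int) -> int:
    """Events scheduled for this month (1..12) under an even annual quota."""
    return (rate_per_year * month_in_year) // 12 - (rate_per_year * (month_in_year - 1)) // 12


def run(config: SimulationConfig) -> SimulationResult:
    """Run one simulation; deterministic given the config (incl. seed)."""
    params = config.params
    net = params.network
    behaviour = params.behaviour
    coeffs = config.energy_coeffs or EnergyCoefficients()
    ef = config.resolved_external_factors()
    network_effect = config.network_effect

    seq = np.random.SeedSequence(config.seed)
    rng_init, rng_net, rng_beh, rng_energy, rng_demo = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )

    if config.initial_population is not None:
        pop = config.initial_population.copy()
    else:
        pop = generate_population(config.n_initial, config.start_year, rng_init, config.profile)
    # positions live on the network map; rescale if the profile map differs
    if abs(config.profile.map_size - net.z) > 1e-12:
        scale = net.z / config.profile.map_size
        pop.pos_x = pop.pos_x * scale
        pop.pos_y = pop.pos_y * scale

    state = NetworkState(len(pop), net.memory_window)
    index = CandidateIndex(pop, net.ra)
    buffer = ActivationBuffer(behaviour.theta_lag, len(pop))
    diet_start_weight = np.zeros(len(pop))
    next_id = int(pop.id.max()) + 1 if len(pop) else 0

    events: list[dict] = []
    metrics: list[tuple[int, NetworkMetrics]] = []
    samples: dict[int, pd.DataFrame] = {}
    rows: list[dict] = []

    def log(entry: dict) -> None:
        if config.collect_event_log:
            events.append(entry)

    def behaviour_step(month: int, warmup: bool) -> None:
        nonlocal diet_start_weight
        nb_mean, nb_has = neighbour_mean_bmi(pop, state, net.neighbour_weight_min)
        attitudes, norms, pbc = inflows_vector(pop, behaviour, nb_mean, nb_has, network_effect)
        update_stocks_vector(pop, buffer, attitudes + norms + pbc, behaviour)
        started = transitions_vector(pop, behaviour, nb_mean, nb_has, rng_beh, network_effect)
        diet_start_weight[started] = pop.weight[started]
        log({"month": month, "type": "norms_flow", "total": float(norms[pop.alive].sum()),
             "warmup": warmup})
        for i in started:
            log({"month": month, "type": "diet_start", "id": int(pop.id[i]),
                 "duration": int(pop.diet_months[i])})

    def diet_countdown(month: int) -> None:
        dieting = pop.alive & (pop.state == STATE_DIETING)
        pop.diet_months[dieting] -= 1
        done = dieting & (pop.diet_months <= 0)
        idx = np.flatnonzero(done)
        if len(idx):
            lost = diet_start_weight[idx] - pop.weight[idx]
            pop.success_score[idx] += lost
            pop.state[idx] = STATE_NORMAL
            pop.diet_months[idx] = 0
            for i in idx:
                log({"month": month, "type": "diet_end", "id": int(pop.id[i]),
                     "kg_lost": float(diet_start_weight[i] - pop.weight[i])})

    # --- initial aggregates -------------------------------------------------
    year_rows, year_samples = _aggregate_year(pop, config.start_year, config.collect_samples)
    rows.extend(year_rows)
    if year_samples is not None:
        samples[config.start_year] = year_samples

    # --- warm-up: network + behaviour with weights and demographics frozen --
    for month in range(-config.warmup_months, 0):
        step_network(pop, net, state, rng_net, index)
        behaviour_step(month, warmup=True)
        diet_countdown(month)

    # --- main loop ----------------------------------------------------------
    for month in range(1, config.horizon_months + 1):
        year_idx = (month - 1) // 12
        cal_year = config.start_year + year_idx
        month_in_year = (month - 1) % 12 + 1

        step_network(pop, net, state, rng_net, index)
        behaviour_step(month, warmup=False)

        tee_v = tee_vector(pop, coeffs)
        intake_v = intake_vector(
            pop, cal_year, ef, params.extfactor_matrix(), tee_v,
            behaviour.diet_restriction, behaviour.adherence_prob, rng_energy,
        )
        weight_update_vector(pop, intake_v, tee_v)
        diet_countdown(month)

        pop.age = np.where(pop.alive, pop.age + 1.0 / 12.0, pop.age)
        pop.pal = pal_category(pop.bmi, pop.age)

        demographics_changed = False
        for _ in range(_monthly_quota(config.births_per_year, month_in_year)):
            entrant = sample_entrant(
                cal_year, config.entrant_mean_for_year(cal_year), rng_demo,
                config.profile, agent_id=next_id,
            )
            entrant.pos_x *= net.z / config.profile.map_size
            entrant.pos_y *= net.z / config.profile.map_size
            row = pop.append(entrant)
            next_id += 1
            state.grow(len(pop))
            buffer.grow(len(pop))
            diet_start_weight = np.append(diet_start_weight, 0.0)
            demographics_changed = True
            log({"month": month, "type": "birth", "id": int(pop.id[row])})

        n_deaths = _monthly_quota(config.deaths_per_year, month_in_year)
        if n_deaths > 0:
            alive_idx = np.flatnonzero(pop.alive)
            if len(alive_idx) <= n_deaths:
                raise ExtinctionError("population extinct")
            w = np.exp((pop.age[alive_idx] - 50.0) / 15.0)
            chosen = rng_demo.choice(alive_idx, size=n_deaths, replace=False, p=w / w.sum())
            pop.alive[chosen] = False
            state.drop_agents(chosen)
            demographics_changed = True
            for i in chosen:
                log({"month": month, "type": "death", "id": int(pop.id[i]),
                     "age": float(pop.age[i])})

        if demographics_changed:
            index = CandidateIndex(pop, net.ra)

        if month % 12 == 0:
            year_rows, year_samples = _aggregate_year(pop, cal_year + 1, config.collect_samples)
            rows.extend(year_rows)
            if year_samples is not None:
                samples[cal_year + 1] = year_samples
        if config.collect_metrics_every and month % config.collect_metrics_every == 0:
            metrics.append((month, compute_metrics(pop, state, net.neighbour_weight_min)))

        if pop.n_alive == 0:
            raise ExtinctionError("population extinct")

    reference = pd.DataFrame(rows)
    return SimulationResult(
        reference=reference, metrics=metrics, population=pop, state=state,
        config=config, events=events, samples=samples,
    )


def apply_scenario(base: SimulationConfig, spec: ScenarioSpec) -> SimulationConfig:
    """Attach a scenario to a base config (returns a new config)."""
    return base.model_copy(update={"scenario": spec})


def compare_runs(a: SimulationResult | pd.DataFrame, b: SimulationResult | pd.DataFrame) -> pd.DataFrame:
    """Per-cell percent difference of b relative to a (the reference run).

    Positive values mean b is higher.  Percent-of-reference convention:
    ``100 * (b - a) / a`` with ``a`` the denominator.
    """
    ref_a = a.reference if isinstance(a, SimulationResult) else a
    ref_b = b.reference if isinstance(b, SimulationResult) else b
    keys = ["year", "gender", "age_group"]
    if len(ref_a) != len(ref_b):
        raise ConfigurationError("runs have different aggregate shapes")
    merged = ref_a.merge(ref_b, on=keys, suffixes=("_a", "_b"))
    if len(merged) != len(ref_a):
        raise ConfigurationError("runs cover different (year, gender, age group) cells")
    merged["mean_pct_diff"] = 100.0 * (merged["mean_bmi_b"] - merged["mean_bmi_a"]) / merged["mean_bmi_a"]
    merged["median_pct_diff"] = 100.0 * (merged["median_bmi_b"] - merged["median_bmi_a"]) / merged["median_bmi_a"]
    return merged[keys + ["mean_pct_diff", "median_pct_diff"]]
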