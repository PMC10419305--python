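"""Synthetic populations and population/reference-series I/O.

The simulator does not ship survey micro-data.  Instead this module
generates agent populations whose statistical shape mirrors the national
individual-level records the model was designed around: an adult age
pyramid (16-90), two genders, per-stratum BMI distributions whose means
rise with age, and gender-specific heights.  Generation is stratified over
age-group x gender x BMI-tertile cells so that requested marginals are hit
almost exactly ("balanced for age, gender and BMI"), and every operation is
a pure function of its inputs and seed.

A matching CSV reader/writer covers real population tables with the same
columns, and :func:`make_reference` forward-simulates the full model to
produce a synthetic reference series (mean/median BMI by year x gender x
age group) for calibration exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats

from .errors import ConfigurationError, ParseError
from .groups import AGE_GROUP_LABELS, AGE_GROUP_LOWER, AGE_GROUP_UPPER, MAX_AGE, Gender, age_group_index

__all__ = [
    "Agent",
    "BMI_MAX",
    "BMI_MIN",
    "Population",
    "PopulationProfile",
    "STATE_DIETING",
    "STATE_NORMAL",
    "generate_population",
    "make_reference",
    "pal_category",
    "read_population_csv",
    "read_reference_csv",
    "sample_entrant",
    "write_population_csv",
    "write_reference_csv",
]

#: Hard BMI clamps maintained by the simulation for every agent.
BMI_MIN, BMI_MAX = 10.0, 80.0

STATE_NORMAL, STATE_DIETING = 0, 1

PAL_LABELS = ("low", "medium", "high")

POPULATION_COLUMNS = ["id", "age", "gender", "height_m", "weight_kg", "education", "pal"]
REFERENCE_COLUMNS = ["year", "gender", "age_group", "mean_bmi", "median_bmi"]


class PopulationProfile(BaseModel):
    """Distribution config for synthetic agents.

    Defaults describe a plausible UK-like adult population: the two
    youngest groups jointly make up roughly a quarter of the population,
    BMI means rise with age and flatten after middle age, and heights are
    gender-specific normals.  All values are editable; they are a
    documented stand-in, not survey estimates.
    """

    age_group_weights: list[float] = Field(
        default=[0.08, 0.16, 0.25, 0.24, 0.18, 0.09],
        description="Probability of each of the six age groups, youngest first.",
    )
    female_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    #: rows: male, female; columns: the six age groups.
    bmi_mean: list[list[float]] = Field(
        default=[
            [24.0, 25.5, 27.0, 27.8, 28.0, 27.5],
            [23.5, 25.0, 26.5, 27.3, 27.6, 27.0],
        ]
    )
    bmi_sd: list[list[float]] = Field(
        default=[
            [4.5, 4.2, 4.2, 4.2, 4.0, 3.8],
            [4.8, 4.5, 4.5, 4.5, 4.2, 4.0],
        ]
    )
    height_mean: list[float] = Field(default=[1.75, 1.62])
    height_sd: list[float] = Field(default=[0.07, 0.065])
    education_probs: list[float] = Field(default=[0.10, 0.20, 0.30, 0.25, 0.15])
    entrant_bmi_sd: float = Field(default=3.0, ge=0.0)
    #: Side length of the square map agents are placed on; network presets
    #: use the same value so positions need no rescaling.
    map_size: float = Field(default=25.0, gt=0.0)

    @field_validator("age_group_weights")
    @classmethod
    def _check_age_weights(cls, v):
        if len(v) != len(AGE_GROUP_LABELS):
            raise ValueError(f"need {len(AGE_GROUP_LABELS)} age-group weights")
        if any(w < 0 for w in v):
            raise ValueError("age-group weights must be non-negative")
        if abs(sum(v) - 1.0) > 1e-8:
            raise ValueError("age-group weights must sum to 1")
        return v

    @field_validator("education_probs")
    @classmethod
    def _check_education(cls, v):
        if len(v) != 5:
            raise ValueError("education_probs needs 5 entries (levels 1..5)")
        if any(p < 0 for p in v):
            raise ValueError("education probabilities must be non-negative")
        if abs(sum(v) - 1.0) > 1e-8:
            raise ValueError("education probabilities must sum to 1")
        return v

    @model_validator(mode="after")
    def _check_shapes(self):
        for name in ("bmi_mean", "bmi_sd"):
            m = getattr(self, name)
            if len(m) != 2 or any(len(row) != len(AGE_GROUP_LABELS) for row in m):
                raise ValueError(f"{name} must be 2 x {len(AGE_GROUP_LABELS)} (male row, female row)")
        if any(s <= 0 for row in self.bmi_sd for s in row):
            raise ValueError("bmi_sd entries must be positive")
        if len(self.height_mean) != 2 or len(self.height_sd) != 2:
            raise ValueError("height_mean / height_sd need one entry per gender")
        if any(s <= 0 for s in self.height_sd):
            raise ValueError("height_sd entries must be positive")
        return self


def pal_category(bmi, age):
    """Physical-activity-level class from (BMI, age).

    Three classes; activity declines with age and with high BMI: ``high``
    for young (<30) non-overweight agents, ``low`` for agents aged 60+ or
    with BMI >= 30, ``medium`` otherwise.  Returned as int codes
    0=low, 1=medium, 2=high.
    """
    bmi = np.asarray(bmi, dtype=float)
    age = np.asarray(age, dtype=float)
    out = np.ones(np.broadcast(bmi, age).shape, dtype=np.int8)  # medium
    out[(age < 30) & (bmi < 25)] = 2
    out[(age >= 60) | (bmi >= 30)] = 0
    return out if out.ndim else int(out)


@dataclass
class Agent:
    """One simulated person.

    ``intention``/``behaviour`` are the TPB stock levels, ``pbc`` the
    perceived-behavioural-control value, ``success_score`` the signed net
    weight change (kg lost, positive = successful) over completed diets.
    ``state`` is 0 (NORMAL) or 1 (DIETING); the two are linked through
    ``diet_months_remaining > 0``.
    """

    id: int
    age: float
    gender: Gender
    height: float
    weight: float
    education: int
    pal_category: int
    pos_x: float = 0.0
    pos_y: float = 0.0
    intention: float = 0.0
    behaviour: float = 0.0
    pbc: float = 1.0
    state: int = STATE_NORMAL
    diet_months_remaining: int = 0
    success_score: float = 0.0
    alive: bool = True

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2

    @property
    def age_group(self) -> int:
        return int(age_group_index(self.age))


class Population:
    """Column-oriented container of agents (numpy arrays, one row each).

    Behaves as a sequence of :class:`Agent` snapshots for inspection while
    the simulator operates on the arrays directly.  ``alive`` rows are
    never physically removed during a run, only masked, so ids stay stable.
    """

    _FLOAT_COLS = ("age", "height", "weight", "pos_x", "pos_y", "intention",
                   "behaviour", "pbc", "success_score")
    _INT_COLS = ("id", "gender", "education", "pal", "state", "diet_months")

    def __init__(self, n: int = 0):
        self.id = np.zeros(n, dtype=np.int64)
        self.age = np.zeros(n)
        self.gender = np.zeros(n, dtype=np.int8)
        self.height = np.full(n, 1.7)
        self.weight = np.full(n, 70.0)
        self.education = np.ones(n, dtype=np.int8)
        self.pal = np.ones(n, dtype=np.int8)
        self.pos_x = np.zeros(n)
        self.pos_y = np.zeros(n)
        self.intention = np.zeros(n)
        self.behaviour = np.zeros(n)
        self.pbc = np.ones(n)
        self.state = np.zeros(n, dtype=np.int8)
        self.diet_months = np.zeros(n, dtype=np.int32)
        self.success_score = np.zeros(n)
        self.alive = np.ones(n, dtype=bool)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.id)

    def __iter__(self) -> Iterator[Agent]:
        return (self.agent(i) for i in range(len(self)))

    def __getitem__(self, i: int) -> Agent:
        return self.agent(i)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def bmi(self) -> np.ndarray:
        return self.weight / self.height**2

    @property
    def age_group(self) -> np.ndarray:
        return age_group_index(self.age)

    def agent(self, i: int) -> Agent:
        return Agent(
            id=int(self.id[i]), age=float(self.age[i]), gender=Gender(int(self.gender[i])),
            height=float(self.height[i]), weight=float(self.weight[i]),
            education=int(self.education[i]), pal_category=int(self.pal[i]),
            pos_x=float(self.pos_x[i]), pos_y=float(self.pos_y[i]),
            intention=float(self.intention[i]), behaviour=float(self.behaviour[i]),
            pbc=float(self.pbc[i]), state=int(self.state[i]),
            diet_months_remaining=int(self.diet_months[i]),
            success_score=float(self.success_score[i]), alive=bool(self.alive[i]),
        )

    def agents(self) -> list[Agent]:
        return list(self)

    def copy(self) -> "Population":
        out = Population(0)
        for name in ("id", "age", "gender", "height", "weight", "education", "pal",
                     "pos_x", "pos_y", "intention", "behaviour", "pbc", "state",
                     "diet_months", "success_score", "alive"):
            setattr(out, name, getattr(self, name).copy())
        return out

    def append(self, agent: Agent) -> int:
        """Append one agent; returns its row index."""
        values = {
            "id": agent.id, "age": agent.age, "gender": int(agent.gender),
            "height": agent.height, "weight": agent.weight,
            "education": agent.education, "pal": agent.pal_category,
            "pos_x": agent.pos_x, "pos_y": agent.pos_y,
            "intention": agent.intention, "behaviour": agent.behaviour,
            "pbc": agent.pbc, "state": agent.state,
            "diet_months": agent.diet_months_remaining,
            "success_score": agent.success_score, "alive": agent.alive,
        }
        for name, v in values.items():
            arr = getattr(self, name)
            setattr(self, name, np.append(arr, np.asarray(v, dtype=arr.dtype)))
        return len(self) - 1

    @classmethod
    def from_agents(cls, agents: Sequence[Agent]) -> "Population":
        pop = cls(len(agents))
        for i, a in enumerate(agents):
            pop.id[i] = a.id
            pop.age[i] = a.age
            pop.gender[i] = int(a.gender)
            pop.height[i] = a.height
            pop.weight[i] = a.weight
            pop.education[i] = a.education
            pop.pal[i] = a.pal_category
            pop.pos_x[i] = a.pos_x
            pop.pos_y[i] = a.pos_y
            pop.intention[i] = a.intention
            pop.behaviour[i] = a.behaviour
            pop.pbc[i] = a.pbc
            pop.state[i] = a.state
            pop.diet_months[i] = a.diet_months_remaining
            pop.success_score[i] = a.success_score
            pop.alive[i] = a.alive
        return pop

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.id,
                "age": self.age,
                "gender": [str(Gender(g)) for g in self.gender],
                "height_m": self.height,
                "weight_kg": self.weight,
                "education": self.education,
                "pal": [PAL_LABELS[p] for p in self.pal],
            }
        )


def _allocate(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items over weights."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ConfigurationError("allocation weights must be non-negative and sum > 0")
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _sample_truncnorm_tertile(rng, n, tertile, mean, sd):
    """Sample n values from the given tertile band of Normal(mean, sd)."""
    u = rng.uniform(tertile / 3.0, (tertile + 1) / 3.0, size=n)
    u = np.clip(u, 1e-9, 1 - 1e-9)
    return stats.norm.ppf(u, loc=mean, scale=sd)


def generate_population(
    n: int,
    year: int = 0,
    seed: int | np.random.Generator = 0,
    profile: PopulationProfile | None = None,
) -> Population:
    """Generate ``n`` synthetic agents, stratified for age, gender and BMI.

    Stratification allocates agents to age-group x gender cells by largest
    remainder on the profile weights, then splits each cell's BMI draws
    evenly across the tertiles of that cell's Normal distribution, so the
    realised marginals match the profile almost exactly even at small n.

    Deterministic: the same ``(n, year, seed, profile)`` always produces
    a byte-identical population.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    profile = profile or PopulationProfile()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gw = np.array([1.0 - profile.female_fraction, profile.female_fraction])
    cell_w = np.outer(gw, profile.age_group_weights).ravel()  # 2 x 6 -> 12
    cell_counts = _allocate(n, cell_w).reshape(2, len(AGE_GROUP_LABELS))

    pop = Population(n)
    row = 0
    for g in (0, 1):
        for a, count in enumerate(cell_counts[g]):
            if count == 0:
                continue
            sl = slice(row, row + count)
            lo, hi = AGE_GROUP_LOWER[a], min(AGE_GROUP_UPPER[a], MAX_AGE)
            pop.age[sl] = rng.uniform(lo, hi, count)
            pop.gender[sl] = g
            pop.height[sl] = np.clip(
                rng.normal(profile.height_mean[g], profile.height_sd[g], count), 1.30, 2.10
            )
            tert_counts = _allocate(count, np.ones(3))
            bmis = np.concatenate(
                [
                    _sample_truncnorm_tertile(rng, c, t, profile.bmi_mean[g][a], profile.bmi_sd[g][a])
                    for t, c in enumerate(tert_counts)
                ]
            )
            rng.shuffle(bmis)
            bmis = np.clip(bmis, BMI_MIN + 1.0, BMI_MAX - 5.0)
            pop.weight[sl] = bmis * pop.height[sl] ** 2
            row += count

    pop.id[:] = np.arange(n)
    pop.education[:] = rng.choice(np.arange(1, 6), size=n, p=profile.education_probs)
    pop.pal[:] = pal_category(pop.bmi, pop.age)
    pop.pos_x[:] = rng.uniform(0.0, profile.map_size, n)
    pop.pos_y[:] = rng.uniform(0.0, profile.map_size, n)
    return pop


def sample_entrant(
    year: int,
    entrant_bmi_mean: float,
    seed: int | np.random.Generator,
    profile: PopulationProfile | None = None,
    agent_id: int = 0,
) -> Agent:
    """Sample one 16-year-old entrant joining the simulation.

    BMI is Normal around ``entrant_bmi_mean`` with the profile's entrant
    sd (a zero sd is the degenerate point mass); position is uniform on
    the map; gender follows the profile split.
    """
    if not (12.0 < entrant_bmi_mean < 60.0):
        raise ConfigurationError(f"entrant_bmi_mean {entrant_bmi_mean} outside (12, 60)")
    profile = profile or PopulationProfile()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = int(rng.random() < profile.female_fraction)
    height = float(np.clip(rng.normal(profile.height_mean[g], profile.height_sd[g]), 1.30, 2.10))
    bmi = entrant_bmi_mean + profile.entrant_bmi_sd * float(rng.standard_normal())
    bmi = float(np.clip(bmi, BMI_MIN + 1.0, BMI_MAX - 5.0))
    education = int(rng.choice(np.arange(1, 6), p=profile.education_probs))
    return Agent(
        id=agent_id,
        age=16.0,
        gender=Gender(g),
        height=height,
        weight=bmi * height**2,
        education=education,
        pal_category=int(pal_category(bmi, 16.0)),
        pos_x=float(rng.uniform(0.0, profile.map_size)),
        pos_y=float(rng.uniform(0.0, profile.map_size)),
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_population_csv(agents: Population | Sequence[Agent], path) -> None:
    """Write agents to the population CSV interface (7 columns, header)."""
    pop = agents if isinstance(agents, Population) else Population.from_agents(list(agents))
    pop.to_dataframe().to_csv(path, index=False)


def read_population_csv(path) -> Population:
    """Read a population CSV; validates header and row contents.

    Raises :class:`ParseError` naming the missing column or the 1-based
    data row containing a non-numeric anthropometric value.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file without header")
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    n = len(df)
    pop = Population(n)
    for col, target in (("age", "age"), ("height_m", "height"), ("weight_kg", "weight")):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric {col!r}", row=int(bad[0]) + 1)
        getattr(pop, target)[:] = values.to_numpy(dtype=float)
    ids = pd.to_numeric(df["id"], errors="coerce")
    if ids.isna().any():
        raise ParseError(f"{path}: non-numeric 'id'", row=int(ids.index[ids.isna()][0]) + 1)
    pop.id[:] = ids.to_numpy(dtype=np.int64)
    try:
        pop.gender[:] = [int(Gender.parse(g)) for g in df["gender"]]
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}")
    edu = pd.to_numeric(df["education"], errors="coerce")
    if edu.isna().any() or not edu.isin([1, 2, 3, 4, 5]).all():
        raise ParseError(f"{path}: education must be an integer in 1..5")
    pop.education[:] = edu.to_numpy(dtype=np.int8)
    pal_map = {label: i for i, label in enumerate(PAL_LABELS)}
    try:
        pop.pal[:] = [pal_map[str(p).strip().lower()] for p in df["pal"]]
    except KeyError as exc:
        raise ParseError(f"{path}: unknown PAL category {exc}")
    return pop


def write_reference_csv(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, index=False, columns=REFERENCE_COLUMNS)


def read_reference_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    return df[REFERENCE_COLUMNS]


def make_reference(params, horizon: int, seed: int, n: int = 1000,
                   profile: PopulationProfile | None = None) -> pd.DataFrame:
    """Forward-simulate the full model and aggregate to a reference series.

    A synthetic stand-in for published aggregate BMI tables: simulate
    ``horizon`` years from a fresh synthetic population under ``params``
    (a :class:`~obesnet.params.ParameterSet`) and return the mean/median
    BMI per year x gender x age-group table.  Deterministic given seed.
    """
    from .simulate import SimulationConfig, run

    config = SimulationConfig(
        n_initial=n,
        horizon_months=12 * horizon,
        seed=seed,
        params=params,
        profile=profile or PopulationProfile(),
    )
    return run(config).reference
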