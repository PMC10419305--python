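"""Individual energy expenditure and the intake-minus-expenditure weight engine.

Expenditure follows the standard two-equation scheme: a linear basal
metabolic rate in height and weight with coefficients that vary by gender
and age band (BMR = alpha + beta * height + gamma * weight, kcal/day), and
total energy expenditure TEE = PAL * BMR with a three-level physical
activity multiplier.  The shipped coefficient table follows the
Henry-style weight-and-height equations used in UK dietary reference
work, converted to kcal/day; it is an editable config, not a clinical
instrument.

Intake is anchored at TEE plus a calibratable response to the deviation of
the national Average Per Capita Calorie Consumption (APCCC) from its
baseline year, so a population under baseline conditions is in exact
energy balance.  Dieting agents cut intake by a fractional restriction,
but only in months where they adhere (a Bernoulli draw), reproducing the
cyclical loss/plateau pattern of real-world dieting.

Weight change converts the monthly energy gap at 7700 kcal per kg of body
weight; BMI is clamped to (10, 80).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .groups import Gender, age_group_index
from .population import Agent, BMI_MAX, BMI_MIN, Population, STATE_DIETING

__all__ = [
    "DAYS_PER_MONTH",
    "DEFAULT_THETA_EXTFACTOR",
    "EnergyCoefficients",
    "ExternalFactorSeries",
    "KCAL_PER_KG",
    "bmr",
    "intake",
    "read_coefficients_csv",
    "tee",
    "weight_update",
]

#: Mean month length in days used by the monthly integrator.
DAYS_PER_MONTH = 30.44
#: Energy density of body-weight change, kcal per kg.
KCAL_PER_KG = 7700.0

KCAL_PER_MJ = 239.006

#: External-factor (APCCC) gains per gender x age group; male row first.
DEFAULT_THETA_EXTFACTOR = [
    [0.29, 0.31, 0.24, 0.256, 0.22, 0.22],
    [0.20, 0.22, 0.22, 0.20, 0.21, 0.20],
]

# Henry-style weight+height BMR equations, MJ/day:
# (gender, age_min, age_max, const, height coef, weight coef)
_HENRY_MJ = [
    (0, 0.0, 18.0, 1.25, 1.11, 0.0651),
    (0, 18.0, 30.0, 0.473, 1.31, 0.0600),
    (0, 30.0, 60.0, -0.574, 2.26, 0.0476),
    (0, 60.0, np.inf, -1.070, 2.26, 0.0478),
    (1, 0.0, 18.0, 1.93, 1.04, 0.0393),
    (1, 18.0, 30.0, -1.180, 2.57, 0.0433),
    (1, 30.0, 60.0, -0.0486, 2.10, 0.0342),
    (1, 60.0, np.inf, 0.0448, 1.76, 0.0356),
]

#: PAL multipliers for the low / medium / high activity classes.
DEFAULT_PAL_TABLE = (1.49, 1.63, 1.78)


def _default_coefficient_frame() -> pd.DataFrame:
    rows = [
        {
            "gender": g,
            "age_min": lo,
            "age_max": hi,
            "alpha": const * KCAL_PER_MJ,
            "beta": h * KCAL_PER_MJ,
            "gamma": w * KCAL_PER_MJ,
        }
        for g, lo, hi, const, h, w in _HENRY_MJ
    ]
    return pd.DataFrame(rows)


class EnergyCoefficients:
    """BMR coefficient table keyed by (gender, age band) plus PAL multipliers.

    The table must cover every (gender, age) combination the simulation can
    produce; lookups for an uncovered band raise a configuration error
    naming the band.
    """

    def __init__(self, table: pd.DataFrame | None = None,
                 pal_table: tuple[float, float, float] = DEFAULT_PAL_TABLE):
        self.table = table if table is not None else _default_coefficient_frame()
        required = {"gender", "age_min", "age_max", "alpha", "beta", "gamma"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"coefficient table missing columns: {sorted(missing)}")
        if (self.table["gamma"] <= 0).any():
            raise ConfigurationError("gamma (kcal/day per kg) must be positive")
        if len(pal_table) != 3 or any(not (1.0 <= p <= 2.5) for p in pal_table):
            raise ConfigurationError("pal_table needs 3 multipliers in [1.0, 2.5]")
        if sorted(pal_table) != list(pal_table):
            raise ConfigurationError("PAL multipliers must be non-decreasing low->high")
        self.pal_table = tuple(float(p) for p in pal_table)

    def lookup(self, gender, age) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised (alpha, beta, gamma) lookup for gender/age arrays."""
        gender = np.atleast_1d(np.asarray(gender, dtype=int))
        age = np.atleast_1d(np.asarray(age, dtype=float))
        alpha = np.full(len(age), np.nan)
        beta = np.full(len(age), np.nan)
        gamma = np.full(len(age), np.nan)
        for _, row in self.table.iterrows():
            mask = (gender == int(row["gender"])) & (age >= row["age_min"]) & (age < row["age_max"])
            alpha[mask] = row["alpha"]
            beta[mask] = row["beta"]
            gamma[mask] = row["gamma"]
        if np.isnan(alpha).any():
            i = int(np.flatnonzero(np.isnan(alpha))[0])
            raise ConfigurationError(
                f"no BMR coefficient band for gender={Gender(int(gender[i]))} age={age[i]:.1f}"
            )
        return alpha, beta, gamma

    def pal_multiplier(self, pal_code) -> np.ndarray:
        return np.asarray(self.pal_table)[np.asarray(pal_code, dtype=int)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pal_table=DEFAULT_PAL_TABLE) -> "EnergyCoefficients":
        return cls(pd.read_csv(path, comment="#"), pal_table)


def read_coefficients_csv(path) -> EnergyCoefficients:
    return EnergyCoefficients.from_csv(path)


class ExternalFactorSeries(BaseModel):
    """Per-year APCCC series (kcal/person/day) with a baseline year.

    The intake model responds to the deviation of the current year from
    the baseline year, so baseline conditions mean exact energy balance.
    """

    values: dict[int, float]
    baseline_year: int

    @model_validator(mode="after")
    def _check(self):
        if not self.values:
            raise ValueError("external-factor series is empty")
        years = sorted(self.values)
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError("external-factor series must be contiguous in year")
        for y, v in self.values.items():
            if not (1000.0 < v < 5000.0):
                raise ValueError(f"APCCC {v} kcal/day for {y} outside the plausible (1000, 5000)")
        if self.baseline_year not in self.values:
            raise ValueError("baseline_year must be part of the series")
        return self

    @classmethod
    def constant(cls, value: float, start_year: int, n_years: int) -> "ExternalFactorSeries":
        return cls(values={start_year + k: value for k in range(n_years)}, baseline_year=start_year)

    def apccc(self, year: int) -> float:
        if year not in self.values:
            raise KeyError(f"year {year} outside external-factor series "
                           f"({min(self.values)}..{max(self.values)})")
        return self.values[year]

    def deviation(self, year: int) -> float:
        return self.apccc(year) - self.values[self.baseline_year]

    def to_csv(self, path) -> None:
        pd.DataFrame({"year": sorted(self.values), "kcal_per_day": [self.values[y] for y in sorted(self.values)]}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, baseline_year: int | None = None) -> "ExternalFactorSeries":
        df = pd.read_csv(path)
        values = {int(r.year): float(r.kcal_per_day) for r in df.itertuples()}
        return cls(values=values, baseline_year=baseline_year if baseline_year is not None else min(values))


# ---------------------------------------------------------------------------
# per-agent operations
# ---------------------------------------------------------------------------

def bmr(p: Agent, coeffs: EnergyCoefficients) -> float:
    """Basal metabolic rate, kcal/day: alpha + beta * height + gamma * weight."""
    alpha, beta, gamma = coeffs.lookup(int(p.gender), p.age)
    return float(alpha[0] + beta[0] * p.height + gamma[0] * p.weight)


def tee(p: Agent, coeffs: EnergyCoefficients) -> float:
    """Total energy expenditure, kcal/day: PAL multiplier x BMR."""
    return float(coeffs.pal_multiplier(p.pal_category)) * bmr(p, coeffs)


def intake(p: Agent, year: int, ef: ExternalFactorSeries,
           theta_extfactor, state: int | None = None,
           rng: np.random.Generator | None = None,
           coeffs: EnergyCoefficients | None = None,
           diet_restriction: float = 0.15,
           adherence_prob: float = 0.8) -> float:
    """Calorie intake, kcal/day, for one agent in one month.

    NORMAL intake = TEE + theta_extfactor[gender, age group] * (APCCC(year)
    - APCCC(baseline)).  While DIETING, the restriction applies only with
    probability ``adherence_prob`` (a lapse month reverts to NORMAL intake).
    """
    coeffs = coeffs or EnergyCoefficients()
    theta = np.asarray(theta_extfactor, dtype=float)
    gain = theta[int(p.gender), p.age_group]
    base = tee(p, coeffs) + gain * ef.deviation(year)
    state = p.state if state is None else state
    if state == STATE_DIETING:
        rng = rng or np.random.default_rng()
        if rng.random() < adherence_prob:
            return base * (1.0 - diet_restriction)
    return base


def weight_update(p: Agent, intake_kcal_day: float, tee_kcal_day: float,
                  dt: float = 1.0) -> Agent:
    """Apply one month of energy (im)balance to an agent's weight.

    delta = (intake - TEE) * 30.44 / 7700 kg; the result is clamped so
    BMI stays inside (10, 80).
    """
    delta = (intake_kcal_day - tee_kcal_day) * DAYS_PER_MONTH * dt / KCAL_PER_KG
    weight = p.weight + delta
    h2 = p.height**2
    weight = float(np.clip(weight, BMI_MIN * h2, BMI_MAX * h2))
    out = Agent(**{**p.__dict__})
    out.weight = weight
    return out


# ---------------------------------------------------------------------------
# vectorised engine path
# ---------------------------------------------------------------------------

def tee_vector(pop: Population, coeffs: EnergyCoefficients) -> np.ndarray:
    alpha, beta, gamma = coeffs.lookup(pop.gender, pop.age)
    bmr_v = alpha + beta * pop.height + gamma * pop.weight
    return coeffs.pal_multiplier(pop.pal) * bmr_v


def intake_vector(pop: Population, year: int, ef: ExternalFactorSeries,
                  theta_extfactor, tee_v: np.ndarray,
                  diet_restriction: float, adherence_prob: float,
                  rng: np.random.Generator) -> np.ndarray:
    theta = np.asarray(theta_extfactor, dtype=float)
    gains = theta[pop.gender, pop.age_group]
    base = tee_v + gains * ef.deviation(year)
    dieting = pop.alive & (pop.state == STATE_DIETING)
    adhere = dieting & (rng.random(len(pop)) < adherence_prob)
    return np.where(adhere, base * (1.0 - diet_restriction), base)


def weight_update_vector(pop: Population, intake_v: np.ndarray,
                         tee_v: np.ndarray, dt: float = 1.0) -> None:
    delta = (intake_v - tee_v) * DAYS_PER_MONTH * dt / KCAL_PER_KG
    h2 = pop.height**2
    new_weight = np.clip(pop.weight + delta, BMI_MIN * h2, BMI_MAX * h2)
    pop.weight = np.where(pop.alive, new_weight, pop.weight)
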