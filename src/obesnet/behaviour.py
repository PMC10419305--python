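"""Per-agent Theory-of-Planned-Behaviour stock-flow dynamics.

Each agent carries two stocks, Intention and Behaviour.  Intention is fed
by three flows — attitudes (moderated by education and degree of
overweight), subjective norms (the gap between own BMI and the same-gender
network-neighbourhood mean, gated by a satisficing threshold that grows
with own BMI) and perceived behavioural control (a default value modified
by past dieting success).  A constant fraction of Intention flows out as
"activation", reaches the Behaviour stock after a configurable lag, and
both stocks decay each month.  Once Behaviour crosses its threshold *and*
the agent perceives itself significantly overweight relative to its
contacts, it transitions from NORMAL to DIETING for a stochastic number of
months.

All flows are per month; the integrator is explicit Euler with a fixed
one-month step, matching the simulation clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .groups import AGE_GROUP_LABELS, age_group_index
from .population import Agent, Population, STATE_DIETING, STATE_NORMAL
from .network import NetworkState

__all__ = [
    "ActivationBuffer",
    "BehaviourParams",
    "StockState",
    "attitudes_inflow",
    "maybe_transition",
    "neighbour_mean_bmi",
    "norms_inflow",
    "pbc_inflow",
    "pbc_value",
    "satisficing_value",
    "update_stocks",
]

#: Table of norms-flow gains, male row then female row, six age groups each.
DEFAULT_THETA_NORMS = [
    [1.95, 1.87, 4.91, 2.99, 3.69, 1.52],
    [2.84, 3.85, 1.02, 4.99, 0.87, 3.725],
]


#: Splittable SD gains: scalar config values are broadcast to the full
#: gender x age-group grid, which is what the calibration cascade splits.
GainValue = float | list


def _as_gain_matrix(value) -> list[list[float]]:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full((2, len(AGE_GROUP_LABELS)), float(arr))
    if arr.shape != (2, len(AGE_GROUP_LABELS)):
        raise ValueError(f"gain must be a scalar or 2 x {len(AGE_GROUP_LABELS)} grid")
    if np.any(arr < 0):
        raise ValueError("gains must be non-negative")
    return arr.tolist()


class BehaviourParams(BaseModel):
    """Parameters of the TPB component.

    The flow gains (``theta_norms``, ``theta_pbc``, ``theta_attitude``),
    the satisficing scale ``theta_sv`` and the mean diet time
    ``theta_diet_time`` may each be a single global value or a full
    gender x age-group grid; scalars are broadcast on validation.  Decays
    are per-month fractional losses; the defaults for decay rates and the
    behaviour threshold are free choices documented in the methods note.
    """

    theta_norms: GainValue = Field(default_factory=lambda: [r[:] for r in DEFAULT_THETA_NORMS])
    theta_pbc: GainValue = 0.5
    theta_attitude: GainValue = 0.5
    theta_sv: GainValue = 1.0
    theta_lag: int = Field(default=3, ge=0, description="activation lag (months)")
    theta_diet_time: GainValue = Field(default=3.0, description="mean diet duration (months)")
    intention_decay: float = Field(default=0.2, ge=0.0, lt=1.0)
    behaviour_decay: float = Field(default=0.3, ge=0.0, lt=1.0)
    behaviour_threshold: float = Field(default=20.0, gt=0.0)
    pbc_default: float = Field(default=1.0, ge=0.0)
    activation_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    diet_restriction: float = Field(default=0.10, gt=0.0, lt=1.0)
    adherence_prob: float = Field(default=0.7, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _normalise_gains(self):
        for name in ("theta_norms", "theta_pbc", "theta_attitude", "theta_sv", "theta_diet_time"):
            object.__setattr__(self, name, _as_gain_matrix(getattr(self, name)))
        if np.any(np.asarray(self.theta_diet_time) <= 0):
            raise ValueError("theta_diet_time must be positive")
        return self

    def gain(self, name: str) -> np.ndarray:
        """Gender x age-group matrix for a splittable gain."""
        return np.asarray(getattr(self, name), dtype=float)

    def norms_matrix(self) -> np.ndarray:
        return self.gain("theta_norms")


def satisficing_value(bmi, theta_sv: float = 1.0):
    """Minimum BMI discrepancy an agent must perceive before reacting.

    ``sv(b) = theta_sv * max(0, (b - 20) / 10) ** 2`` — zero at BMI 20,
    one at BMI 30 and four at BMI 40 for the default scale, so heavier
    individuals require a larger gap before the norms flow triggers.
    """
    b = np.asarray(bmi, dtype=float)
    if np.any(b <= 0):
        raise ConfigurationError("bmi must be positive")
    out = theta_sv * np.maximum(0.0, (b - 20.0) / 10.0) ** 2
    return float(out) if out.ndim == 0 else out


def _age_weights(focal_age: float, ages: np.ndarray) -> np.ndarray:
    """Age-proximity weights: contributions fade with age distance."""
    return 1.0 / (1.0 + np.abs(focal_age - ages) / 10.0)


def norms_inflow(p: Agent, neighbours: Sequence[Agent], params: BehaviourParams) -> float:
    """Subjective-norms flow into Intention for one agent.

    Uses the age-proximity-weighted mean BMI of *same-gender* network
    neighbours; the flow is zero unless the agent's own BMI exceeds that
    mean by more than its satisficing value.
    """
    same = [q for q in neighbours if q.gender == p.gender and q.alive]
    if not same:
        return 0.0
    ages = np.array([q.age for q in same])
    bmis = np.array([q.bmi for q in same])
    w = _age_weights(p.age, ages)
    m = float(np.sum(w * bmis) / np.sum(w))
    d = p.bmi - m
    g, a = int(p.gender), p.age_group
    if d <= satisficing_value(p.bmi, params.gain("theta_sv")[g, a]):
        return 0.0
    return float(params.norms_matrix()[g, a] * d)


def attitudes_inflow(p: Agent, params: BehaviourParams) -> float:
    """Attitudes flow: education-moderated reaction to being overweight."""
    if not 1 <= p.education <= 5:
        raise ConfigurationError(f"education must be in 1..5, got {p.education}")
    overweight = min(1.0, max(0.0, (p.bmi - 25.0) / 5.0))
    gain = params.gain("theta_attitude")[int(p.gender), p.age_group]
    return gain * (p.education / 5.0) * overweight


def pbc_value(success_score, pbc_default: float):
    """Perceived behavioural control: default scaled by past success.

    Bounded via tanh so extreme histories saturate at 0 and 2x default.
    """
    return pbc_default * (1.0 + np.tanh(np.asarray(success_score, dtype=float) / 5.0))


def pbc_inflow(p: Agent, params: BehaviourParams) -> float:
    gain = params.gain("theta_pbc")[int(p.gender), p.age_group]
    return float(gain * pbc_value(p.success_score, params.pbc_default))


@dataclass
class StockState:
    """Intention/Behaviour stocks plus the activation lag buffer.

    The buffer is a FIFO of length ``theta_lag``: activation leaving
    Intention at month t reaches Behaviour at month t + lag.
    """

    intention: float = 0.0
    behaviour: float = 0.0
    buffer: list[float] = field(default_factory=list)


def update_stocks(s: StockState, inflows: tuple[float, float, float],
                  params: BehaviourParams, dt: float = 1.0) -> StockState:
    """One Euler month-step of the stock-flow system.

    intention <- intention * (1 - decay) + sum(inflows) - activation;
    the activation amount (a fixed fraction of pre-update Intention)
    enters the lag buffer and the element delayed by ``theta_lag`` months
    is added to the decayed Behaviour stock.  Stocks are floored at zero.
    """
    if dt != 1.0:
        raise ConfigurationError("the integrator uses a fixed 1-month step")
    lag = params.theta_lag
    buffer = list(s.buffer)
    if len(buffer) != lag:
        buffer = ([0.0] * lag + buffer)[-lag:] if lag > 0 else []
    activation = params.activation_fraction * s.intention
    intention = max(0.0, s.intention * (1.0 - params.intention_decay) + sum(inflows) - activation)
    if lag == 0:
        delivered = activation
    else:
        buffer.append(activation)
        delivered = buffer.pop(0)
    behaviour = max(0.0, s.behaviour * (1.0 - params.behaviour_decay) + delivered)
    return StockState(intention=intention, behaviour=behaviour, buffer=buffer)


def _diet_duration(success_score, theta_diet_time: float, rng: np.random.Generator):
    """Geometric diet duration (months, >= 1) with success-modified mean."""
    mean = theta_diet_time * (1.0 + np.tanh(np.asarray(success_score, dtype=float) / 5.0))
    p = 1.0 / np.maximum(mean, 1.0)
    return rng.geometric(p)


def maybe_transition(p: Agent, neighbours: Sequence[Agent], params: BehaviourParams,
                     rng: np.random.Generator) -> Agent:
    """NORMAL -> DIETING transition check for one agent.

    Requires both the Behaviour stock at threshold and a perceived BMI
    excess over the same-gender neighbourhood mean larger than the
    satisficing value.  On transition the diet duration is drawn from a
    geometric distribution and the Behaviour stock resets.
    """
    if p.state != STATE_NORMAL:
        return p
    if p.behaviour < params.behaviour_threshold:
        return p
    same = [q for q in neighbours if q.gender == p.gender and q.alive]
    if not same:
        return p
    ages = np.array([q.age for q in same])
    bmis = np.array([q.bmi for q in same])
    w = _age_weights(p.age, ages)
    m = float(np.sum(w * bmis) / np.sum(w))
    g, a = int(p.gender), p.age_group
    if p.bmi - m <= satisficing_value(p.bmi, params.gain("theta_sv")[g, a]):
        return p
    duration = int(_diet_duration(p.success_score, params.gain("theta_diet_time")[g, a], rng))
    out = Agent(**{**p.__dict__})
    out.state = STATE_DIETING
    out.diet_months_remaining = max(1, duration)
    out.behaviour = 0.0
    return out


# ---------------------------------------------------------------------------
# vectorised engine path
# ---------------------------------------------------------------------------

class ActivationBuffer:
    """Ring buffer of pending activation for the whole population."""

    def __init__(self, lag: int, n: int):
        self.lag = lag
        self.data = np.zeros((max(lag, 1), n)) if lag > 0 else np.zeros((0, n))
        self.pos = 0

    def grow(self, new_n: int) -> None:
        if self.lag > 0 and new_n > self.data.shape[1]:
            pad = np.zeros((self.data.shape[0], new_n - self.data.shape[1]))
            self.data = np.hstack([self.data, pad])

    def push_pop(self, activation: np.ndarray) -> np.ndarray:
        """Insert this month's activation; return the lag-delayed amount."""
        if self.lag == 0:
            return activation
        out = self.data[self.pos].copy()
        self.data[self.pos] = activation
        self.pos = (self.pos + 1) % self.lag
        return out


def neighbour_mean_bmi(pop: Population, state: NetworkState,
                       weight_min: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Same-gender, age-proximity-weighted neighbourhood mean BMI.

    Returns ``(mean, has_neighbours)`` arrays over the whole population;
    agents without living same-gender neighbours get mean 0 and flag
    False.  Vectorised over the edge list of the derived graph.
    """
    n = len(pop)
    alive_idx = np.flatnonzero(pop.alive)
    threshold = weight_min * state.memory_window
    sub = state.counts[np.ix_(alive_idx, alive_idx)]
    ii, jj = np.nonzero(np.triu(sub, k=1) > threshold)
    src = np.concatenate([alive_idx[ii], alive_idx[jj]])
    dst = np.concatenate([alive_idx[jj], alive_idx[ii]])
    same = pop.gender[src] == pop.gender[dst]
    src, dst = src[same], dst[same]
    w = 1.0 / (1.0 + np.abs(pop.age[src] - pop.age[dst]) / 10.0)
    num = np.zeros(n)
    den = np.zeros(n)
    np.add.at(num, src, w * pop.bmi[dst])
    np.add.at(den, src, w)
    has = den > 0
    mean = np.where(has, num / np.where(has, den, 1.0), 0.0)
    return mean, has


def inflows_vector(pop: Population, params: BehaviourParams,
                   nb_mean: np.ndarray, nb_has: np.ndarray,
                   network_effect: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(attitudes, norms, pbc) flow arrays for the whole population."""
    bmi = pop.bmi
    g, a = pop.gender, pop.age_group
    overweight = np.clip((bmi - 25.0) / 5.0, 0.0, 1.0)
    attitudes = params.gain("theta_attitude")[g, a] * (pop.education / 5.0) * overweight
    if network_effect:
        d = bmi - nb_mean
        gate = nb_has & (d > satisficing_value(bmi, params.gain("theta_sv")[g, a]))
        norms = np.where(gate, params.norms_matrix()[g, a] * d, 0.0)
    else:
        norms = np.zeros(len(pop))
    pbc = params.gain("theta_pbc")[g, a] * pbc_value(pop.success_score, params.pbc_default)
    return attitudes, norms, pbc


def update_stocks_vector(pop: Population, buffer: ActivationBuffer,
                         total_inflow: np.ndarray, params: BehaviourParams) -> None:
    """Vectorised stock update in place (living agents only)."""
    alive = pop.alive
    activation = params.activation_fraction * pop.intention
    pop.intention = np.where(
        alive,
        np.maximum(0.0, pop.intention * (1.0 - params.intention_decay) + total_inflow - activation),
        pop.intention,
    )
    delivered = buffer.push_pop(np.where(alive, activation, 0.0))
    pop.behaviour = np.where(
        alive,
        np.maximum(0.0, pop.behaviour * (1.0 - params.behaviour_decay) + delivered),
        pop.behaviour,
    )


def transitions_vector(pop: Population, params: BehaviourParams,
                       nb_mean: np.ndarray, nb_has: np.ndarray,
                       rng: np.random.Generator,
                       network_effect: bool = True) -> np.ndarray:
    """Apply NORMAL -> DIETING transitions in place; returns the indices
    of agents starting a diet this month."""
    eligible = pop.alive & (pop.state == STATE_NORMAL) & (pop.behaviour >= params.behaviour_threshold)
    if network_effect:
        d = pop.bmi - nb_mean
        sv = satisficing_value(pop.bmi, 1.0) * params.gain("theta_sv")[pop.gender, pop.age_group]
        eligible &= nb_has & (d > sv)
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return idx
    diet_time = params.gain("theta_diet_time")[pop.gender[idx], pop.age_group[idx]]
    durations = _diet_duration(pop.success_score[idx], diet_time, rng)
    pop.state[idx] = STATE_DIETING
    pop.diet_months[idx] = np.maximum(1, durations)
    pop.behaviour[idx] = 0.0
    return idx
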