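"""SPSA calibration of the simulation parameter vector.

Simultaneous perturbation stochastic approximation: at iteration k every
parameter is perturbed at once by +/- c_k along a random +/-1 vector, the
loss (sum of squared errors between simulated and reference mean/median
BMI per year x gender x age group) is evaluated at the two perturbed
points, and the gradient estimate

    g_hat = (L+ - L-) / (2 c_k) * Delta^{-1}   (elementwise inverse)

drives the update theta <- theta - a_k g_hat with decaying gains
a_k = a / (A + k + 1)^alpha and c_k = c / (k + 1)^gamma.  Defaults follow
standard practice for this optimiser: a = 0.16, A = 100, c = 0.1,
alpha = 0.602, gamma = 0.101, 3000 iterations, with the final estimate
taken as the elementwise median of the last 100 iterates to damp the
stochastic jitter of individual steps.

Bounded parameters are optimised through a logit transform so perturbed
evaluations always stay feasible.  By default the two perturbed
evaluations of one iteration share the simulation seed (common random
numbers), which markedly reduces gradient-estimator variance; a flag
disables it.

Parameter-splitting (the manual refinement cascade) is provided as an
operation on the vector layout: a global gain can be split by gender, age
group or both, each child initialised to the parent value so the loss is
unchanged at the moment of the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .groups import AGE_GROUP_LABELS, Gender
from .params import ParameterSet
from .simulate import SimulationConfig, SimulationResult, run

__all__ = [
    "ParameterVector",
    "ReplicatedResult",
    "SPSAConfig",
    "gain_sequences",
    "homophily_ablation",
    "loss",
    "replicated_test",
    "split_parameter",
    "spsa_run",
    "spsa_step",
]

N_GROUPS = len(AGE_GROUP_LABELS)

#: Parameters the cascade may split by gender / age group / both.
SPLITTABLE = (
    "theta_norms",
    "theta_pbc",
    "theta_attitude",
    "theta_sv",
    "theta_diet_time",
    "theta_extfactor",
)
#: Global-only parameters (structural or already pair-resolved).
GLOBAL_ONLY = ("theta_lag", "theta_trigger", "theta_mem", "theta_range")

GENDER_PAIR_LABELS = ("male->male", "male->female", "female->female", "female->male")

#: Optimisation bounds per parameter name (natural scale).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "theta_norms": (0.0, 10.0),
    "theta_pbc": (0.0, 5.0),
    "theta_attitude": (0.0, 5.0),
    "theta_sv": (0.0, 5.0),
    "theta_diet_time": (0.5, 24.0),
    "theta_extfactor": (0.0, 1.0),
    "theta_lag": (0.0, 12.0),
    "theta_trigger": (0.05, 20.0),
    "theta_bmiadj": (0.0, 10.0),
    "theta_mem": (0.0, 5.0),
    "theta_range": (0.1, 30.0),
}

#: Default split layout: the two gains shipped as full grids are split by
#: both axes, everything else starts global.
DEFAULT_SPLITS: dict[str, str | None] = {
    "theta_norms": "both",
    "theta_pbc": None,
    "theta_attitude": None,
    "theta_extfactor": "both",
    "theta_sv": None,
    "theta_lag": None,
    "theta_diet_time": None,
    "theta_trigger": None,
    "theta_bmiadj": "gender_pair",
    "theta_mem": None,
    "theta_range": None,
}

_AXIS_SIZE = {None: 1, "gender": 2, "age_group": N_GROUPS, "both": 2 * N_GROUPS, "gender_pair": 4}


class SPSAConfig(BaseModel):
    a: float = Field(default=0.16, gt=0.0, description="gain numerator")
    A: float = Field(default=100.0, ge=0.0, description="stability constant")
    c: float = Field(default=0.1, gt=0.0, description="perturbation numerator")
    alpha_gain: float = Field(default=0.602, gt=0.0, le=1.0)
    gamma_gain: float = Field(default=0.101, gt=0.0, le=1.0)
    iterations: int = Field(default=3000, ge=1)
    tail: int = Field(default=100, ge=1, description="finalisation window")
    seed: int = 0
    common_random_numbers: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.iterations < self.tail:
            raise ValueError("iterations must be >= tail")
        return self


def gain_sequences(k: int, cfg: SPSAConfig) -> tuple[float, float]:
    """(a_k, c_k) = (a / (A + k + 1)^alpha, c / (k + 1)^gamma)."""
    a_k = cfg.a / (cfg.A + k + 1) ** cfg.alpha_gain
    c_k = cfg.c / (k + 1) ** cfg.gamma_gain
    return a_k, c_k


# ---------------------------------------------------------------------------
# flat bounded parameter vector
# ---------------------------------------------------------------------------

@dataclass
class _Entry:
    name: str
    axis: str | None

    @property
    def size(self) -> int:
        return _AXIS_SIZE[self.axis]

    def labels(self) -> list[str]:
        if self.axis is None:
            return [self.name]
        if self.axis == "gender":
            return [f"{self.name}[{g}]" for g in ("male", "female")]
        if self.axis == "age_group":
            return [f"{self.name}[{a}]" for a in AGE_GROUP_LABELS]
        if self.axis == "both":
            return [f"{self.name}[{g},{a}]" for g in ("male", "female") for a in AGE_GROUP_LABELS]
        return [f"{self.name}[{p}]" for p in GENDER_PAIR_LABELS]


def _aggregate(matrix: np.ndarray, axis: str | None) -> np.ndarray:
    """Collapse a 2 x 6 grid to the entry's category values (by mean)."""
    if axis is None:
        return np.array([matrix.mean()])
    if axis == "gender":
        return matrix.mean(axis=1)
    if axis == "age_group":
        return matrix.mean(axis=0)
    return matrix.ravel()


def _broadcast(values: np.ndarray, axis: str | None) -> np.ndarray:
    """Expand entry values back to the 2 x 6 grid."""
    if axis is None:
        return np.full((2, N_GROUPS), values[0])
    if axis == "gender":
        return np.repeat(values[:, None], N_GROUPS, axis=1)
    if axis == "age_group":
        return np.repeat(values[None, :], 2, axis=0)
    return values.reshape(2, N_GROUPS)


class ParameterVector:
    """Flat, bounded, named view of a :class:`ParameterSet`.

    Holds the natural-scale values plus per-element bounds and the logit
    transform between the bounded and unbounded optimisation spaces.
    ``base`` keeps the structural (non-calibrated) fields needed to
    reconstruct a full parameter set.
    """

    def __init__(self, entries: list[_Entry], values: np.ndarray, base: ParameterSet):
        self.entries = entries
        self.values = np.asarray(values, dtype=float)
        self.base = base
        lo, hi = [], []
        for e in entries:
            b = DEFAULT_BOUNDS[e.name]
            lo += [b[0]] * e.size
            hi += [b[1]] * e.size
        self.lower = np.array(lo)
        self.upper = np.array(hi)
        if len(self.values) != len(self.lower):
            raise ConfigurationError("value/layout size mismatch")

    # -- construction --------------------------------------------------------
    @classmethod
    def from_parameter_set(cls, params: ParameterSet,
                           splits: dict[str, str | None] | None = None) -> "ParameterVector":
        splits = {**DEFAULT_SPLITS, **(splits or {})}
        entries, chunks = [], []
        for name, axis in splits.items():
            if name in GLOBAL_ONLY and axis is not None:
                raise ConfigurationError(f"{name} cannot be split")
            entries.append(_Entry(name, axis))
            chunks.append(_aggregate(_get_matrix(params, name), axis)
                          if name in SPLITTABLE else _get_global(params, name))
        return cls(entries, np.concatenate(chunks), params)

    def copy(self) -> "ParameterVector":
        return ParameterVector(list(self.entries), self.values.copy(), self.base)

    # -- layout helpers ------------------------------------------------------
    def labels(self) -> list[str]:
        return [label for e in self.entries for label in e.labels()]

    def _slices(self) -> dict[str, slice]:
        out, pos = {}, 0
        for e in self.entries:
            out[e.name] = slice(pos, pos + e.size)
            pos += e.size
        return out

    def entry_values(self, name: str) -> np.ndarray:
        return self.values[self._slices()[name]]

    # -- transforms ----------------------------------------------------------
    def transformed(self) -> np.ndarray:
        """Map natural values to unbounded space via a logit."""
        frac = np.clip((self.values - self.lower) / (self.upper - self.lower), 1e-9, 1 - 1e-9)
        return np.log(frac / (1.0 - frac))

    def with_transformed(self, z: np.ndarray) -> "ParameterVector":
        frac = 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))
        values = self.lower + (self.upper - self.lower) * frac
        return ParameterVector(list(self.entries), values, self.base)

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(list(self.entries), np.asarray(values, dtype=float), self.base)

    # -- pack/unpack ---------------------------------------------------------
    def to_parameter_set(self) -> ParameterSet:
        behaviour_updates: dict = {}
        network_updates: dict = {}
        extfactor = None
        for e, sl in zip(self.entries, self._slices().values()):
            v = self.values[sl]
            if e.name in SPLITTABLE:
                grid = _broadcast(v, e.axis).tolist()
                if e.name == "theta_extfactor":
                    extfactor = grid
                else:
                    behaviour_updates[e.name] = grid
            elif e.name == "theta_lag":
                behaviour_updates["theta_lag"] = int(round(max(0.0, v[0])))
            elif e.name == "theta_trigger":
                network_updates["theta_trigger"] = float(v[0])
            elif e.name == "theta_bmiadj":
                network_updates["theta_bmiadj"] = [float(x) for x in v]
            elif e.name == "theta_mem":
                network_updates["theta_mem"] = float(v[0])
            elif e.name == "theta_range":
                network_updates["ra"] = float(v[0])
            else:
                raise ConfigurationError(f"unknown parameter {e.name}")
        return self.base.clone(
            network=self.base.network.model_copy(update=network_updates),
            behaviour=self.base.behaviour.model_copy(update=behaviour_updates),
            **({"theta_extfactor": extfactor} if extfactor is not None else {}),
        )


def _get_matrix(params: ParameterSet, name: str) -> np.ndarray:
    if name == "theta_extfactor":
        return params.extfactor_matrix()
    return params.behaviour.gain(name)


def _get_global(params: ParameterSet, name: str) -> np.ndarray:
    net = params.network
    values = {
        "theta_lag": [float(params.behaviour.theta_lag)],
        "theta_trigger": [net.theta_trigger],
        "theta_bmiadj": list(net.theta_bmiadj),
        "theta_mem": [net.theta_mem],
        "theta_range": [net.ra],
    }
    return np.asarray(values[name], dtype=float)


def split_parameter(pv: ParameterVector, name: str,
                    axis: str) -> ParameterVector:
    """Split a calibratable gain by gender, age group or both.

    Children are initialised to the parent value, so model behaviour (and
    therefore the loss) is unchanged immediately after the split.
    """
    if axis not in ("gender", "age_group", "both"):
        raise ConfigurationError(f"unknown split axis {axis!r}")
    if name not in SPLITTABLE:
        raise ConfigurationError(f"{name} cannot be split (structural or pairwise parameter)")
    entries, chunks = [], []
    found = False
    for e, sl in zip(pv.entries, pv._slices().values()):
        v = pv.values[sl]
        if e.name != name:
            entries.append(e)
            chunks.append(v)
            continue
        found = True
        old, new = e.axis, axis
        if old == "both":
            raise ConfigurationError(f"{name} is already fully split")
        if old == new:
            raise ConfigurationError(f"{name} is already split by {old}")
        # splitting a gender-split entry by age group (or vice versa)
        # yields the full grid
        target = new if old is None else "both"
        grid = _broadcast(v, old)
        entries.append(_Entry(name, target))
        chunks.append(_aggregate(grid, target))
    if not found:
        raise ConfigurationError(f"no parameter named {name!r} in the vector")
    return ParameterVector(entries, np.concatenate(chunks), pv.base)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def loss(candidate: ParameterSet, reference: pd.DataFrame,
         sim_config: SimulationConfig, seed: int) -> float:
    """Sum of squared errors of simulated vs reference mean and median BMI
    over every (year, gender, age group) cell."""
    config = sim_config.model_copy(update={
        "params": candidate, "seed": seed,
        "collect_metrics_every": 0, "collect_event_log": False,
        "collect_samples": False,
    })
    simulated = run(config).reference
    return series_sse(simulated, reference)


def series_sse(simulated: pd.DataFrame, reference: pd.DataFrame) -> float:
    keys = ["year", "gender", "age_group"]
    merged = simulated.merge(reference, on=keys, suffixes=("_sim", "_ref"))
    if len(merged) != len(reference) or len(simulated) < len(reference):
        raise ConfigurationError("simulated and reference series shapes differ")
    ok = merged[["mean_bmi_sim", "mean_bmi_ref", "median_bmi_sim", "median_bmi_ref"]].notna().all(axis=1)
    m = merged[ok]
    return float(
        ((m["mean_bmi_sim"] - m["mean_bmi_ref"]) ** 2).sum()
        + ((m["median_bmi_sim"] - m["median_bmi_ref"]) ** 2).sum()
    )


# ---------------------------------------------------------------------------
# SPSA iteration
# ---------------------------------------------------------------------------

@dataclass
class StepInfo:
    k: int
    loss_plus: float
    loss_minus: float
    rejected: bool = False

    @property
    def loss(self) -> float:
        return 0.5 * (self.loss_plus + self.loss_minus)


def spsa_step(theta_hat: ParameterVector, k: int, loss_fn, cfg: SPSAConfig,
              rng: np.random.Generator) -> tuple[ParameterVector, StepInfo]:
    """One SPSA iteration in the unbounded (transformed) space.

    ``loss_fn(params: ParameterSet, seed: int) -> float``.  The
    perturbation vector has i.i.d. +/-1 components; with common random
    numbers both perturbed evaluations use the same simulation seed.
    A non-finite loss rejects the step (theta unchanged).
    """
    a_k, c_k = gain_sequences(k, cfg)
    z = theta_hat.transformed()
    delta = rng.choice([-1.0, 1.0], size=len(z))
    seed_plus = int(rng.integers(2**31 - 1))
    seed_minus = seed_plus if cfg.common_random_numbers else int(rng.integers(2**31 - 1))
    loss_plus = loss_fn(theta_hat.with_transformed(z + c_k * delta).to_parameter_set(), seed_plus)
    loss_minus = loss_fn(theta_hat.with_transformed(z - c_k * delta).to_parameter_set(), seed_minus)
    info = StepInfo(k=k, loss_plus=float(loss_plus), loss_minus=float(loss_minus))
    if not (np.isfinite(loss_plus) and np.isfinite(loss_minus)):
        info.rejected = True
        return theta_hat, info
    g_hat = (loss_plus - loss_minus) / (2.0 * c_k) * (1.0 / delta)
    return theta_hat.with_transformed(z - a_k * g_hat), info


def spsa_run(theta0: ParameterVector, loss_fn, cfg: SPSAConfig) -> tuple[pd.DataFrame, ParameterVector]:
    """Full SPSA descent.

    Returns the trajectory (iteration, loss, every parameter value on the
    natural scale) and the finalised vector: the elementwise median of the
    last ``cfg.tail`` iterates.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = theta0.copy()
    labels = theta0.labels()
    records = []
    iterates = []
    for k in range(cfg.iterations):
        theta, info = spsa_step(theta, k, loss_fn, cfg, rng)
        records.append({"k": k, "loss": info.loss, "rejected": info.rejected,
                        **dict(zip(labels, theta.values))})
        iterates.append(theta.values)
    tail = np.asarray(iterates[-cfg.tail:])
    final = theta0.with_values(np.median(tail, axis=0))
    return pd.DataFrame(records), final


# ---------------------------------------------------------------------------
# replicated testing and the homophily ablation harness
# ---------------------------------------------------------------------------

@dataclass
class ReplicatedResult:
    """Combined output of replicated test runs.

    ``combined_series`` pools the raw per-agent BMI values of all
    replicates per (year, gender, age group) cell before taking mean and
    median; ``combined_loss`` is the median of the per-replicate losses.
    """

    combined_series: pd.DataFrame
    losses: list[float]
    combined_loss: float


def replicated_test(final_params: ParameterSet, n_reps: int,
                    sim_config: SimulationConfig, reference: pd.DataFrame,
                    seed: int = 0) -> ReplicatedResult:
    """Re-test a calibrated parameter set over fresh random populations."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    losses = []
    pooled: dict[int, list[pd.DataFrame]] = {}
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31 - 1)
    for rep in range(n_reps):
        config = sim_config.model_copy(update={
            "params": final_params, "seed": int(seeds[rep]),
            "initial_population": None, "collect_samples": True,
            "collect_metrics_every": 0, "collect_event_log": False,
        })
        result = run(config)
        losses.append(series_sse(result.reference, reference))
        for year, frame in result.samples.items():
            pooled.setdefault(year, []).append(frame)
    rows = []
    for year in sorted(pooled):
        frame = pd.concat(pooled[year], ignore_index=True)
        for g in (0, 1):
            for a in range(N_GROUPS):
                cell = frame.loc[(frame.gender == g) & (frame.age_group == a), "bmi"]
                rows.append({
                    "year": year, "gender": str(Gender(g)), "age_group": AGE_GROUP_LABELS[a],
                    "mean_bmi": float(cell.mean()) if len(cell) else float("nan"),
                    "median_bmi": float(cell.median()) if len(cell) else float("nan"),
                    "n": int(len(cell)),
                })
    return ReplicatedResult(
        combined_series=pd.DataFrame(rows),
        losses=losses,
        combined_loss=float(np.median(losses)),
    )


def homophily_ablation(sim_config: SimulationConfig, reference: pd.DataFrame,
                       n_reps: int = 3, seed: int = 0) -> dict[str, float]:
    """Paired comparison of the model with and without BMI homophily.

    The two tracks share every parameter except the four gender-pair BMI
    weights, which the "no homophily" track pins to zero (the indicator
    then passes every candidate pair).  Returns the paired combined loss
    scores, lower = closer to the reference series.
    """
    with_h = sim_config.params
    without_h = with_h.clone(
        network=with_h.network.model_copy(update={"theta_bmiadj": [0.0, 0.0, 0.0, 0.0]})
    )
    res_h = replicated_test(with_h, n_reps, sim_config, reference, seed=seed)
    res_n = replicated_test(without_h, n_reps, sim_config, reference, seed=seed)
    return {
        "loss_homophily": res_h.combined_loss,
        "loss_no_homophily": res_n.combined_loss,
    }
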