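"""Model / results facade.

:class:`ObesityModel` bundles a population, an optional reference BMI
series and a simulation configuration, in the familiar build-model /
fit / inspect-results idiom: ``simulate`` produces projections,
``fit`` calibrates the parameter vector with SPSA and returns a
:class:`CalibrationResult` carrying the estimates, their tail dispersion
(a robust spread of the final iterates, reported as an uncertainty proxy),
the full descent trajectory and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .calibrate import ParameterVector, SPSAConfig, loss as _loss, spsa_run
from .errors import ConfigurationError
from .params import ParameterSet
from .population import Population, PopulationProfile, generate_population
from .simulate import ScenarioSpec, SimulationConfig, SimulationResult, run

__all__ = ["CalibrationResult", "ObesityModel"]


class ObesityModel:
    """Hybrid network + behaviour + energy-balance model bound to data.

    Parameters
    ----------
    population:
        Initial agents.  If omitted, a synthetic population of
        ``config.n_initial`` agents is generated per run from the profile.
    reference:
        Reference series (year x gender x age group mean/median BMI) used
        as the calibration target; required for ``fit`` and ``loss``.
    config:
        Base :class:`SimulationConfig`; its ``params`` are the model's
        current parameter set.
    """

    def __init__(self, population: Population | None = None,
                 reference: pd.DataFrame | None = None,
                 config: SimulationConfig | None = None):
        self.config = config or SimulationConfig()
        if population is not None:
            self.config = self.config.model_copy(update={
                "initial_population": population, "n_initial": len(population),
            })
        self.reference = reference

    @classmethod
    def from_profile(cls, n: int = 1000, profile: PopulationProfile | None = None,
                     seed: int = 0, reference: pd.DataFrame | None = None,
                     **config_updates) -> "ObesityModel":
        """Build a model over a freshly generated synthetic population."""
        profile = profile or PopulationProfile()
        pop = generate_population(n, seed=seed, profile=profile)
        config = SimulationConfig(profile=profile, **config_updates)
        return cls(population=pop, reference=reference, config=config)

    @property
    def params(self) -> ParameterSet:
        return self.config.params

    def simulate(self, params: ParameterSet | None = None, seed: int | None = None,
                 scenario: ScenarioSpec | None = None) -> SimulationResult:
        updates: dict = {}
        if params is not None:
            updates["params"] = params
        if seed is not None:
            updates["seed"] = seed
        if scenario is not None:
            updates["scenario"] = scenario
        return run(self.config.model_copy(update=updates) if updates else self.config)

    def loss(self, params: ParameterSet | None = None, seed: int = 0) -> float:
        if self.reference is None:
            raise ConfigurationError("model has no reference series to score against")
        return _loss(params or self.params, self.reference, self.config, seed)

    def fit(self, start_params: ParameterSet | None = None,
            splits: dict[str, str | None] | None = None,
            spsa: SPSAConfig | None = None, seed: int | None = None,
            **spsa_updates) -> "CalibrationResult":
        """Calibrate with SPSA against the reference series.

        ``spsa_updates`` (e.g. ``iterations=300, tail=50``) override the
        default :class:`SPSAConfig`; ``seed`` seeds the whole descent.
        """
        if self.reference is None:
            raise ConfigurationError("model has no reference series to fit against")
        cfg = spsa or SPSAConfig()
        if seed is not None:
            spsa_updates["seed"] = seed
        if spsa_updates:
            cfg = cfg.model_copy(update=spsa_updates)
        theta0 = ParameterVector.from_parameter_set(start_params or self.params, splits)

        def loss_fn(candidate: ParameterSet, eval_seed: int) -> float:
            return _loss(candidate, self.reference, self.config, eval_seed)

        trajectory, final = spsa_run(theta0, loss_fn, cfg)
        return CalibrationResult(self, theta0, final, trajectory, cfg)


class CalibrationResult:
    """Estimates and diagnostics of one SPSA calibration."""

    def __init__(self, model: ObesityModel, start: ParameterVector,
                 final: ParameterVector, trajectory: pd.DataFrame, spsa: SPSAConfig):
        self.model = model
        self.start = start
        self.final_vector = final
        self.trajectory = trajectory
        self.spsa = spsa

    @property
    def params(self) -> ParameterSet:
        """The calibrated parameter set (tail-median estimates)."""
        return self.final_vector.to_parameter_set()

    @property
    def labels(self) -> list[str]:
        return self.final_vector.labels()

    def tail_frame(self) -> pd.DataFrame:
        return self.trajectory.iloc[-self.spsa.tail:]

    @property
    def tail_loss(self) -> float:
        """Median loss over the finalisation window."""
        return float(self.tail_frame()["loss"].median())

    def tail_spread(self) -> pd.Series:
        """Robust spread (half the central 50% range) of the final iterates,
        a proxy for how settled each estimate is."""
        tail = self.tail_frame()[self.labels]
        return (tail.quantile(0.75) - tail.quantile(0.25)) / 2.0

    def summary(self) -> pd.DataFrame:
        """Estimate table: start value, estimate, tail spread, bounds."""
        spread = self.tail_spread()
        return pd.DataFrame(
            {
                "start": self.start.values,
                "estimate": self.final_vector.values,
                "tail_spread": [spread[label] for label in self.labels],
                "lower": self.final_vector.lower,
                "upper": self.final_vector.upper,
            },
            index=self.labels,
        )

    def plot_loss(self, ax=None, window: int = 25):
        """Loss-vs-iteration descent curve with a rolling median overlay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        traj = self.trajectory
        ax.plot(traj["k"], traj["loss"], lw=0.6, alpha=0.5, label="per-iteration loss")
        ax.plot(traj["k"], traj["loss"].rolling(window, min_periods=1).median(),
                lw=1.8, label=f"rolling median ({window})")
        ax.set_xlabel("iteration")
        ax.set_ylabel("loss (sum of squared errors)")
        ax.legend(frameon=False)
        return ax

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<CalibrationResult: {len(self.labels)} parameters, "
                f"{self.spsa.iterations} iterations, tail loss {self.tail_loss:.4g}>")
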