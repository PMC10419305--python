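"""The full calibratable parameter set.

Bundles the network parameters, the TPB behaviour parameters and the
external-factor (APCCC) response gains into one structured object that the
simulator consumes and the SPSA calibrator packs into a flat bounded
vector.  Defaults reproduce the shipped gender x age-group gain tables for
the norms flow and the external-factor response.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .behaviour import BehaviourParams, _as_gain_matrix
from .energy import DEFAULT_THETA_EXTFACTOR
from .network import NetworkParams

__all__ = ["ParameterSet"]


class ParameterSet(BaseModel):
    """Network + behaviour + energy-gain parameters for one model run.

    ``theta_extfactor`` is the per (gender x age group) response of
    individual intake to deviations of the national APCCC series from its
    baseline year (kcal intake per kcal of APCCC deviation); like the
    behavioural gains it may be given as a scalar and is broadcast to the
    2 x 6 grid.
    """

    network: NetworkParams = Field(default_factory=NetworkParams)
    behaviour: BehaviourParams = Field(default_factory=BehaviourParams)
    theta_extfactor: float | list = Field(
        default_factory=lambda: [row[:] for row in DEFAULT_THETA_EXTFACTOR]
    )

    @model_validator(mode="after")
    def _normalise(self):
        object.__setattr__(self, "theta_extfactor", _as_gain_matrix(self.theta_extfactor))
        return self

    def extfactor_matrix(self) -> np.ndarray:
        return np.asarray(self.theta_extfactor, dtype=float)

    def clone(self, **updates) -> "ParameterSet":
        data = self.model_dump()
        data.update(updates)
        return ParameterSet(**data)
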