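"""Reading and writing model configurations, observations and trajectories.

Model configs are YAML: species names, reactions with net stoichiometry,
a declarative kinetic-law spec, Gamma prior hyperparameters and the true
theta used for simulation.  Observations and trajectories travel as CSV
with a ``time`` column plus one column per species (trajectories add an
``event`` column).  Round-trips are lossless for declarative kinetic laws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .model import KineticLaw, PMJPModel, Reaction
from .simulate import ObservationSet, Trajectory

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "save_observations",
    "load_observations",
    "save_trajectory",
]


def model_to_dict(model: PMJPModel, initial_state=None) -> dict:
    d = {
        "species": list(model.species),
        "reactions": [
            {
                "name": r.name,
                "delta": list(r.delta),
                "law": r.rho.spec(),
                "theta": float(model.theta[i]),
                "prior": {
                    "shape": float(model.priors[i, 0]),
                    "rate": float(model.priors[i, 1]),
                },
            }
            for i, r in enumerate(model.reactions)
        ],
    }
    if initial_state is not None:
        d["initial_state"] = [int(x) for x in initial_state]
    return d


def model_from_dict(d: dict):
    reactions, theta, priors = [], [], []
    for r in d["reactions"]:
        reactions.append(Reaction(r["name"], tuple(r["delta"]), KineticLaw.from_spec(r["law"])))
        theta.append(float(r["theta"]))
        priors.append((float(r["prior"]["shape"]), float(r["prior"]["rate"])))
    model = PMJPModel(d["species"], reactions, theta, priors)
    s0 = np.asarray(d["initial_state"], np.int64) if "initial_state" in d else None
    return model, s0


def save_model(model: PMJPModel, path, initial_state=None):
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model, initial_state), fh, sort_keys=False)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_observations(obs: ObservationSet, path, species=None):
    obs.to_dataframe(species).to_csv(path, index=False)


def load_observations(path) -> ObservationSet:
    return ObservationSet.from_dataframe(pd.read_csv(path))


def save_trajectory(traj: Trajectory, path, model: PMJPModel | None = None):
    traj.to_dataframe(model).to_csv(path, index=False)
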