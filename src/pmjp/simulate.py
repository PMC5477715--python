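"""Exact stochastic simulation of pMJPs and observation handling.

Trajectories are piecewise-constant, right-continuous (cadlag) paths: the
state at time ``t`` is the state entered at the largest jump time ``<= t``.
Observations read the path at a set of times; by default they are noiseless
(indicator emissions in the samplers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PMJPModel, VIRTUAL, infer_reaction

__all__ = ["Trajectory", "ObservationSet", "gillespie_simulate", "observe_at_times"]


@dataclass
class Trajectory:
    """A piecewise-constant path: states ``s_0..s_K`` entered at ``t_0..t_K``."""

    states: np.ndarray  # (K+1, M) int
    times: np.ndarray  # (K+1,) float, strictly increasing, times[0] = start
    t_end: float
    absorbed: bool = False

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.states.ndim != 2 or len(self.states) != len(self.times):
            raise ValueError("states and times must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if self.t_end < self.times[-1]:
            raise ValueError("t_end before last jump")

    @property
    def n_jumps(self) -> int:
        return len(self.times) - 1

    def state_at(self, t: float) -> np.ndarray:
        """State at time ``t`` (right-continuous)."""
        k = int(np.searchsorted(self.times, t, side="right")) - 1
        if k < 0:
            raise ValueError(f"time {t} precedes trajectory start")
        return self.states[k]

    def states_at(self, ts: np.ndarray) -> np.ndarray:
        ks = np.searchsorted(self.times, np.asarray(ts, float), side="right") - 1
        if np.any(ks < 0):
            raise ValueError("time precedes trajectory start")
        return self.states[ks]

    def holding_intervals(self):
        """Yield (state, dt) pairs covering [times[0], t_end]."""
        bounds = np.append(self.times, self.t_end)
        for k in range(len(self.states)):
            dt = bounds[k + 1] - bounds[k]
            if dt > 0 or k == len(self.states) - 1:
                yield self.states[k], dt

    def to_dataframe(self, model: PMJPModel | None = None, species=None) -> pd.DataFrame:
        names = (
            list(model.species)
            if model is not None
            else list(species)
            if species is not None
            else [f"species_{j + 1}" for j in range(self.states.shape[1])]
        )
        df = pd.DataFrame(self.states, columns=names)
        df.insert(0, "time", self.times)
        events = ["init"]
        for k in range(1, len(self.states)):
            if model is not None:
                u = infer_reaction(model, self.states[k - 1], self.states[k])
                events.append(VIRTUAL if u == VIRTUAL else model.reactions[u].name)
            else:
                events.append("jump")
        df["event"] = events
        return df


@dataclass
class ObservationSet:
    """Time-ordered observations ``(t_i, y_i)`` of the process state.

    ``mask`` marks which species are observed (default: all, i.e. full
    noiseless state observations).  A per-observation emission vector over a
    state space can be produced with :meth:`emission_vector`.
    """

    times: np.ndarray
    values: np.ndarray  # (N, M) int
    mask: np.ndarray | None = None  # (M,) bool; False = species unobserved

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or len(self.values) != len(self.times):
            raise ValueError("times and values must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("observed counts must be nonnegative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    def emission_vector(self, i: int, space) -> np.ndarray:
        """Likelihood of observation ``i`` under each state of ``space``."""
        states = space.states
        if self.mask is None:
            return np.all(states == self.values[i], axis=1).astype(float)
        cols = np.nonzero(self.mask)[0]
        return np.all(states[:, cols] == self.values[i][cols], axis=1).astype(float)

    def max_values(self) -> np.ndarray:
        """Per-dimension maximum observed count (the y* of box truncations)."""
        return self.values.max(axis=0)

    def to_dataframe(self, species=None) -> pd.DataFrame:
        names = (
            list(species)
            if species is not None
            else [f"species_{j + 1}" for j in range(self.values.shape[1])]
        )
        df = pd.DataFrame(self.values, columns=names)
        df.insert(0, "time", self.times)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservationSet":
        cols = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(), df[cols].to_numpy())


def gillespie_simulate(
    model: PMJPModel,
    s0,
    t_end: float,
    seed,
    theta=None,
) -> Trajectory:
    """Exact stochastic simulation (Gillespie's direct method).

    Holding times are exponential with rate ``r(s) = sum_i theta_i rho_i(s)``
    and the next reaction is ``i`` with probability ``theta_i rho_i(s)/r(s)``.
    Stops at ``t_end`` or on absorption (``r(s) = 0``).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = model.theta if theta is None else np.asarray(theta, float)
    s = np.asarray(s0, np.int64).copy()
    if np.any(s < 0):
        raise ValueError("initial state must be nonnegative")
    t = 0.0
    states = [s.copy()]
    times = [0.0]
    absorbed = False
    deltas = model.deltas
    while True:
        props = model.propensities_fast(s, theta)
        total = props.sum()
        if total <= 0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        i = int(np.searchsorted(np.cumsum(props), rng.random() * total, side="right"))
        i = min(i, model.n_reactions - 1)
        s = s + deltas[i]
        states.append(s.copy())
        times.append(t)
    return Trajectory(np.array(states), np.array(times), t_end=t_end, absorbed=absorbed)


def observe_at_times(traj: Trajectory, times) -> ObservationSet:
    """Read the trajectory at the given times (right-continuous convention)."""
    times = np.asarray(times, dtype=float)
    if times.size and times.max() > traj.t_end:
        raise ValueError("observation time beyond trajectory end")
    if times.size == 0:
        return ObservationSet(times, np.empty((0, traj.states.shape[1]), np.int64))
    return ObservationSet(times, traj.states_at(times))
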