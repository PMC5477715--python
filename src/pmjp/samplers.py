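"""The three posterior samplers.

* :func:`run_gibbs_finite` — auxiliary-variable Gibbs sampling on a fixed
  finite state space, alternating exact FFBS trajectory draws with exact
  conjugate Gamma updates of the kinetic parameters.
* :func:`run_algorithm1` — pseudo-marginal Metropolis–Hastings on theta,
  replacing the intractable likelihood with the nonnegative unbiased
  Russian-Roulette estimate; the estimate at the current state is retained,
  never recomputed, so the chain targets the exact parameter posterior.
* :func:`run_algorithm2` — Metropolized truncation Gibbs: each sweep draws
  theta conjugately, a random box truncation, and a trajectory on that box,
  then accepts or rejects with a ratio of conditional path probabilities
  under the new and old truncations.

The conjugacy rests on the trajectory likelihood

    L(theta) = prod_k theta_{u_k} rho_{u_k}(s_k) exp(-dt_k r_k),

so Gamma(a_i, b_i) priors give Gamma(a_i + N_i, b_i + sum_k dt_k rho_i(s_k))
conditionals, with N_i the number of firings of reaction i in the path.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ffbs import (
    ZeroLikelihoodError,
    paths_conditional_probabilities,
    sample_posterior_path,
)
from .model import PMJPModel, StateSpace, VIRTUAL, enumerate_box, infer_reaction
from .simulate import ObservationSet, Trajectory
from .transient import TruncationScheme, likelihood_estimate, sample_num_terms

__all__ = [
    "SufficientStats",
    "ChainOutput",
    "TruncationDraw",
    "sufficient_statistics",
    "gibbs_theta_update",
    "run_gibbs_finite",
    "run_algorithm1",
    "algorithm2_step",
    "run_algorithm2",
    "initial_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass
class SufficientStats:
    """Reaction counts N_i and integrated propensity factors along a path."""

    counts: np.ndarray  # (R,) int
    integrals: np.ndarray  # (R,) float: sum_k dt_k rho_i(s_k)


@dataclass
class ChainOutput:
    """Per-iteration output of a sampler run."""

    theta: np.ndarray  # (n_iter, R)
    accepted: np.ndarray  # (n_iter,) bool
    extras: dict = field(default_factory=dict)  # name -> (n_iter,) array
    config: dict = field(default_factory=dict)
    seed: object = None
    trajectories: list | None = None

    @property
    def n_iter(self) -> int:
        return len(self.theta)

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.theta, columns=[f"theta_{i + 1}" for i in range(self.theta.shape[1])]
        )
        df.insert(0, "iteration", np.arange(self.n_iter))
        df["accepted"] = self.accepted.astype(int)
        for name, arr in self.extras.items():
            df[name] = arr
        return df

    def save(self, path):
        """Write the chain as CSV with a JSON config sidecar."""
        path = str(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {"seed": self.seed, "config": _jsonable(self.config)}
        with open(path + ".config.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "ChainOutput":
        path = str(path)
        df = pd.read_csv(path)
        theta_cols = [c for c in df.columns if c.startswith("theta_")]
        extras = {
            c: df[c].to_numpy()
            for c in df.columns
            if c not in theta_cols and c not in ("iteration", "accepted")
        }
        try:
            with open(path + ".config.json") as fh:
                sidecar = json.load(fh)
        except FileNotFoundError:
            sidecar = {"seed": None, "config": {}}
        return cls(
            df[theta_cols].to_numpy(),
            df["accepted"].to_numpy().astype(bool),
            extras,
            sidecar["config"],
            sidecar["seed"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class TruncationDraw:
    """A sampled box truncation {x : x_d <= y*_d + m*}."""

    m_star: int
    y_star: np.ndarray
    space: StateSpace


# ---------------------------------------------------------------------------
# sufficient statistics and conjugate updates


def sufficient_statistics(path: Trajectory, model: PMJPModel) -> SufficientStats:
    """Counts and integrated rate factors of a trajectory.

    Virtual self-jumps contribute to the integrals (through the holding
    times) but never to the counts, so inserting or removing them leaves
    the statistics unchanged.
    """
    R = model.n_reactions
    counts = np.zeros(R, dtype=np.int64)
    for k in range(path.n_jumps):
        u = infer_reaction(model, path.states[k], path.states[k + 1])
        if u is not VIRTUAL:
            counts[u] += 1
    ones = np.ones(R)
    rho = model.propensities(path.states, theta=ones)  # (K+1, R)
    bounds = np.append(path.times, path.t_end)
    dts = np.diff(bounds)
    integrals = dts @ rho
    return SufficientStats(counts, integrals)


def gibbs_theta_update(stats: SufficientStats, priors, seed) -> np.ndarray:
    """Draw theta from its exact Gamma conditional given a trajectory."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    priors = np.asarray(priors, float).reshape(-1, 2)
    if np.any(priors <= 0):
        raise ValueError("prior shapes and rates must be positive")
    shape = priors[:, 0] + stats.counts
    rate = priors[:, 1] + stats.integrals
    return rng.gamma(shape, 1.0 / rate)


def _draw_prior_theta(model: PMJPModel, rng) -> np.ndarray:
    return rng.gamma(model.priors[:, 0], 1.0 / model.priors[:, 1])


# ---------------------------------------------------------------------------
# finite-space Gibbs


def run_gibbs_finite(
    model: PMJPModel,
    obs: ObservationSet,
    space: StateSpace,
    n_iter: int,
    seed,
    theta_init=None,
    multiplier: float = 2.0,
    update_theta: bool = True,
    t_end: float | None = None,
    keep_paths: bool = False,
) -> ChainOutput:
    """Gibbs sampling of (theta, trajectory) on a fixed finite space."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = (
        np.asarray(theta_init, float) if theta_init is not None else _draw_prior_theta(model, rng)
    )
    # Seed the auxiliary-variable kernel with a deterministic feasible path;
    # a fresh-grid draw can be infeasible when the initial theta is small.
    path = initial_trajectory(model, obs, space, t_end=t_end)
    thetas = np.empty((n_iter, model.n_reactions))
    paths = [] if keep_paths else None
    for it in range(n_iter):
        path = sample_posterior_path(
            model, theta, obs, space, path, rng, multiplier=multiplier, t_end=t_end
        )
        if update_theta:
            stats = sufficient_statistics(path, model)
            theta = gibbs_theta_update(stats, model.priors, rng)
        thetas[it] = theta
        if keep_paths:
            paths.append(path)
    return ChainOutput(
        thetas,
        np.ones(n_iter, dtype=bool),
        config={"algorithm": "gibbs", "n_iter": n_iter, "multiplier": multiplier},
        seed=_seed_repr(seed),
        trajectories=paths,
    )


def _seed_repr(seed):
    return None if isinstance(seed, np.random.Generator) else seed


# ---------------------------------------------------------------------------
# Algorithm 1: pseudo-marginal Metropolis-Hastings


def _log_prior(theta: np.ndarray, priors: np.ndarray) -> float:
    """Gamma log-prior up to an additive constant."""
    with np.errstate(divide="ignore"):
        return float(np.sum((priors[:, 0] - 1) * np.log(theta) - priors[:, 1] * theta))


def mh_log_acceptance(
    log_est_new: float,
    log_est_cur: float,
    theta_new: np.ndarray,
    theta_cur: np.ndarray,
    priors: np.ndarray,
    log_scale: bool = True,
) -> float:
    """Log pseudo-marginal M-H acceptance ratio.

    With a Gaussian random walk on log(theta), the proposal is symmetric in
    log space and the Jacobian contributes prod(theta_new/theta_cur).
    """
    la = log_est_new - log_est_cur
    la += _log_prior(theta_new, priors) - _log_prior(theta_cur, priors)
    if log_scale:
        la += float(np.sum(np.log(theta_new) - np.log(theta_cur)))
    return la


def run_algorithm1(
    model: PMJPModel,
    obs: ObservationSet,
    scheme: TruncationScheme,
    n_iter: int,
    seed,
    step_sizes=0.3,
    theta_init=None,
    log_scale: bool = True,
    sticking_window: int = 50,
) -> ChainOutput:
    """Pseudo-marginal M-H with the Russian-Roulette likelihood estimate.

    Proposals are a Gaussian random walk on log(theta) (positivity for
    free).  The likelihood estimate attached to the current state is kept
    until a proposal is accepted — recomputing it would target only an
    approximate posterior.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = model.n_reactions
    step = np.broadcast_to(np.asarray(step_sizes, float), (R,))
    theta = (
        np.asarray(theta_init, float) if theta_init is not None else _draw_prior_theta(model, rng)
    )
    cur_log_est = likelihood_estimate(model, theta, obs, scheme, rng).log_value

    thetas = np.empty((n_iter, R))
    accepted = np.zeros(n_iter, dtype=bool)
    log_ests = np.empty(n_iter)
    recent_zero = deque(maxlen=sticking_window)
    warned = False
    for it in range(n_iter):
        if log_scale:
            prop = theta * np.exp(step * rng.standard_normal(R))
        else:
            prop = theta + step * rng.standard_normal(R)
        if np.all(prop > 0):
            prop_log_est = likelihood_estimate(model, prop, obs, scheme, rng).log_value
            recent_zero.append(not np.isfinite(prop_log_est))
            la = mh_log_acceptance(
                prop_log_est, cur_log_est, prop, theta, model.priors, log_scale
            )
            if np.log(rng.random()) < la:
                theta, cur_log_est = prop, prop_log_est
                accepted[it] = True
        thetas[it] = theta
        log_ests[it] = cur_log_est
        if (
            not warned
            and len(recent_zero) == sticking_window
            and all(recent_zero)
        ):
            warned = True
            warnings.warn(
                f"all of the last {sticking_window} proposals had zero likelihood "
                "estimates; the chain may be sticking (consider a larger "
                "truncation parameter a)",
                RuntimeWarning,
            )
    return ChainOutput(
        thetas,
        accepted,
        extras={"log_estimate": log_ests},
        config={
            "algorithm": "alg1",
            "n_iter": n_iter,
            "a": scheme.a,
            "step_sizes": list(np.asarray(step)),
            "log_scale": log_scale,
        },
        seed=_seed_repr(seed),
    )


# ---------------------------------------------------------------------------
# Algorithm 2: Metropolized truncation Gibbs


def _truncation_space(y_star: np.ndarray, m: int) -> StateSpace:
    upper = np.asarray(y_star, np.int64) + int(m)
    return enumerate_box(np.zeros_like(upper), upper)


def initial_trajectory(
    model: PMJPModel,
    obs: ObservationSet,
    space: StateSpace,
    t_end: float | None = None,
) -> Trajectory:
    """Deterministic minimal-event path through the observations.

    Each inter-observation segment follows a shortest reaction sequence
    (breadth-first search over the space under the stoichiometries) with
    jumps spaced uniformly inside the segment.  Used to initialise
    Algorithm 2; any feasible path would do, a deterministic one keeps runs
    reproducible.
    """
    if t_end is None:
        t_end = float(obs.times[-1])
    start = _match_state(obs, 0, space)
    states = [space.states[start]]
    times = [0.0]
    cur = start
    prev_t = 0.0
    for i in range(len(obs)):
        t_i = obs.times[i]
        target_mask = obs.emission_vector(i, space) > 0
        seq = _bfs_path(model, space, cur, target_mask)
        if seq is None:
            raise ValueError(
                f"observation {i} unreachable from previous state under the stoichiometry"
            )
        if len(seq) > 1:
            lo = max(prev_t, times[-1])
            if t_i <= lo:
                raise ValueError("zero-length segment cannot host connecting jumps")
            inner = np.linspace(lo, t_i, len(seq) + 1)[1:-1]
            for j, k in enumerate(seq[1:]):
                states.append(space.states[k])
                times.append(inner[j])
        cur = seq[-1]
        prev_t = t_i
    return Trajectory(np.array(states), np.array(times), t_end=t_end)


def _match_state(obs: ObservationSet, i: int, space: StateSpace) -> int:
    e = obs.emission_vector(i, space)
    idx = np.nonzero(e)[0]
    if len(idx) == 0:
        raise ZeroLikelihoodError(f"observation {i} matches no state in the space")
    return int(idx[0])


def _bfs_path(model, space, start: int, target_mask: np.ndarray):
    """Shortest sequence of states (as indices) from start into the target set."""
    if target_mask[start]:
        return [start]
    prev = {start: None}
    frontier = [start]
    while frontier:
        nxt_frontier = []
        for k in frontier:
            s = space.states[k]
            for i in range(model.n_reactions):
                if model.reactions[i].rho(s) <= 0:
                    continue
                t = s + model.deltas[i]
                if np.any(t < 0):
                    continue
                j = space.locate_many(t[None, :])[0]
                if j < 0 or j in prev:
                    continue
                prev[j] = k
                if target_mask[j]:
                    seq = [int(j)]
                    while prev[seq[0]] is not None:
                        seq.insert(0, prev[seq[0]])
                    return seq
                nxt_frontier.append(int(j))
        frontier = nxt_frontier
    return None


@dataclass
class Alg2State:
    theta: np.ndarray
    path: Trajectory
    m: int
    space: StateSpace


def algorithm2_step(
    state: Alg2State,
    model: PMJPModel,
    obs: ObservationSet,
    scheme: TruncationScheme,
    seed,
    y_star: np.ndarray | None = None,
    offset: int = -1,
    multiplier: float = 2.0,
    fix_truncation: int | None = None,
    t_end: float | None = None,
):
    """One sweep of the Metropolized truncation Gibbs sampler.

    1. theta* ~ exact Gamma conditional given the current trajectory.
    2. Draw a truncation m* (roulette term count + offset) defining the box
       {x : x_d <= y*_d + m*}, then a trajectory S* by FFBS on that box
       (via the auxiliary-variable kernel when the box is unchanged, from a
       fresh Poisson grid otherwise).
    3. Evaluate the conditional probabilities of S* and the current S_t
       under both the new and old truncations, on the shared grid formed by
       the union of their jump times.
    4. Accept (theta*, S*, m*) with probability min(alpha, 1) where
       alpha = [p_new(S*) p_new(S_t)] / [p_old(S_t) p_old(S*)]; on
       rejection the whole sweep — including theta* — is discarded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t_end is None:
        t_end = float(obs.times[-1])
    if y_star is None:
        y_star = obs.max_values()

    # 1. conjugate parameter draw
    stats = sufficient_statistics(state.path, model)
    theta_star = gibbs_theta_update(stats, model.priors, rng)

    # 2. truncation and trajectory proposal
    if fix_truncation is not None:
        m_star = int(fix_truncation)
    else:
        m_star = max(sample_num_terms(scheme, rng) + offset, 0)
    new_space = state.space if m_star == state.m else _truncation_space(y_star, m_star)
    upper = np.asarray(y_star, np.int64) + m_star
    if np.any(state.path.states > upper):
        # The current trajectory leaves the proposed (smaller) box, so its
        # conditional probability under the new truncation is zero and the
        # acceptance ratio vanishes: reject without drawing S*.
        return state, {
            "log_alpha": -np.inf,
            "accepted": False,
            "m_star": m_star,
            "theta_star": theta_star,
        }
    # The current path lives on the new space, so the auxiliary-variable
    # kernel (candidate times resampled around it) draws S* there.
    path_star = sample_posterior_path(
        model,
        theta_star,
        obs,
        new_space,
        state.path,
        rng,
        multiplier=multiplier,
        t_end=t_end,
    )

    # 3. four conditional path probabilities on the union grid
    grid = np.unique(np.concatenate([state.path.times[1:], path_star.times[1:]]))
    lp_new_star, lp_new_cur = paths_conditional_probabilities(
        [path_star, state.path], model, theta_star, obs, new_space, grid,
        multiplier=multiplier,
    )
    lp_old_star, lp_old_cur = paths_conditional_probabilities(
        [path_star, state.path], model, theta_star, obs, state.space, grid,
        multiplier=multiplier,
    )

    # 4. accept/reject
    log_num = lp_new_star + lp_new_cur
    log_den = lp_old_cur + lp_old_star
    if not np.isfinite(log_num):
        log_alpha = -np.inf  # covers the doubly-degenerate case: reject
    elif not np.isfinite(log_den):
        log_alpha = np.inf
    else:
        log_alpha = log_num - log_den
    accept = np.log(rng.random()) < log_alpha
    info = {
        "log_alpha": log_alpha,
        "accepted": bool(accept),
        "m_star": m_star,
        "theta_star": theta_star,
    }
    if accept:
        return Alg2State(theta_star, path_star, m_star, new_space), info
    return state, info


def run_algorithm2(
    model: PMJPModel,
    obs: ObservationSet,
    scheme: TruncationScheme,
    n_iter: int,
    seed,
    theta_init=None,
    offset: int = -1,
    multiplier: float = 2.0,
    fix_truncation: int | None = None,
    y_star: np.ndarray | None = None,
    t_end: float | None = None,
    keep_paths: bool = False,
) -> ChainOutput:
    """Run Algorithm 2 from a prior-drawn theta and a minimal-event path."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if y_star is None:
        y_star = obs.max_values()
    theta = (
        np.asarray(theta_init, float) if theta_init is not None else _draw_prior_theta(model, rng)
    )
    if fix_truncation is not None:
        m0 = int(fix_truncation)
    else:
        m0 = max(sample_num_terms(scheme, rng) + offset, 0)
    space0 = _truncation_space(y_star, m0)
    path0 = initial_trajectory(model, obs, space0, t_end=t_end)
    state = Alg2State(theta, path0, m0, space0)

    R = model.n_reactions
    thetas = np.empty((n_iter, R))
    accepted = np.zeros(n_iter, dtype=bool)
    m_stars = np.empty(n_iter, dtype=np.int64)
    log_alphas = np.empty(n_iter)
    paths = [] if keep_paths else None
    for it in range(n_iter):
        state, info = algorithm2_step(
            state, model, obs, scheme, rng,
            y_star=y_star, offset=offset, multiplier=multiplier,
            fix_truncation=fix_truncation, t_end=t_end,
        )
        thetas[it] = state.theta
        accepted[it] = info["accepted"]
        m_stars[it] = info["m_star"]
        log_alphas[it] = info["log_alpha"]
        if keep_paths:
            paths.append(state.path)
    return ChainOutput(
        thetas,
        accepted,
        extras={"m_star": m_stars, "log_alpha": log_alphas},
        config={
            "algorithm": "alg2",
            "n_iter": n_iter,
            "a": scheme.a,
            "offset": offset,
            "multiplier": multiplier,
        },
        seed=_seed_repr(seed),
        trajectories=paths,
    )
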