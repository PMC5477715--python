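"""Uniformisation and forward filtering-backward sampling (FFBS) of paths.

Uniformisation embeds a finite-state MJP with generator ``A`` into a
discrete-time chain with common exit rate ``gamma`` and transition matrix
``B = A/gamma + I``; self-jumps (virtual jumps) keep the time-marginals of
the two processes identical.  Conditioning on observations then reduces to
a hidden-Markov-model smoothing problem on a random grid of candidate jump
times: forward filtering followed by backward sampling draws a state
sequence from its exact conditional law, and removing self-jumps yields a
posterior trajectory of the original continuous-time process.

The same machinery, run in evaluation mode, returns the conditional
probability of a *given* trajectory — the quantity entering the acceptance
ratio of the Metropolized truncation Gibbs sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .model import GeneratorMatrix, PMJPModel, StateSpace, build_generator
from .simulate import ObservationSet, Trajectory

__all__ = [
    "UniformisedChain",
    "MessageSet",
    "ZeroLikelihoodError",
    "uniformise",
    "sample_posterior_path",
    "path_conditional_probability",
    "paths_conditional_probabilities",
    "compute_messages",
]

GAMMA_FLOOR = 1e-9


class ZeroLikelihoodError(ValueError):
    """Observations have probability zero on the given state space."""


@dataclass
class UniformisedChain:
    """Discrete-time embedding: exit rate ``gamma``, stochastic matrix ``B``.

    ``B`` is dense for small spaces and CSR sparse for large ones (it has
    only ~R+1 nonzeros per row, so sparse propagation is far cheaper).
    """

    gamma: float
    B: object  # (n, n) ndarray or CSR matrix
    space: StateSpace
    exit_rates: np.ndarray  # per-state total off-diagonal rate of A

    def column(self, j: int) -> np.ndarray:
        if sparse.issparse(self.B):
            return self.B.getcol(j).toarray().ravel()
        return self.B[:, j]

    def step_probs(self, z: np.ndarray) -> np.ndarray:
        """B[z_g, z_{g+1}] along a state-index sequence."""
        if len(z) < 2:
            return np.ones(0)
        if sparse.issparse(self.B):
            return np.asarray(self.B[z[:-1], z[1:]]).ravel()
        return self.B[z[:-1], z[1:]]


@dataclass
class MessageSet:
    """Normalized forward/backward messages and per-step log-normalizers."""

    forward: np.ndarray  # (G+1, n)
    backward: np.ndarray  # (G+1, n)
    log_normalizers: np.ndarray  # (G+1,); sum = log p(observations)

    @property
    def log_evidence(self) -> float:
        return float(self.log_normalizers.sum())


def uniformise(gen: GeneratorMatrix, multiplier: float = 2.0) -> UniformisedChain:
    """Build the uniformised chain of a closed-mode generator.

    ``gamma = multiplier * max exit rate`` (multiplier > 1 keeps positive
    self-loop mass everywhere, which the auxiliary-variable path sampler
    needs to resample jump times ergodically).
    """
    if gen.mode != "closed":
        raise ValueError("uniformisation requires a closed-mode generator")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    exit_rates = gen.exit_rates()
    gamma = multiplier * float(exit_rates.max())
    if gamma <= 0:
        gamma = GAMMA_FLOOR
    if sparse.issparse(gen.rates):
        B = (gen.rates / gamma + sparse.identity(gen.n, format="csr")).tocsr()
    else:
        B = gen.rates / gamma + np.eye(gen.n)
    return UniformisedChain(gamma, B, gen.space, exit_rates)


# ---------------------------------------------------------------------------
# candidate-time grids


def _fresh_grid(rng: np.random.Generator, gamma: float, t_end: float) -> np.ndarray:
    """Homogeneous Poisson(gamma) candidate times on (0, t_end)."""
    n = rng.poisson(gamma * t_end)
    return np.sort(rng.uniform(0.0, t_end, size=n))


def _resampled_grid(
    rng: np.random.Generator,
    chain: UniformisedChain,
    path: Trajectory,
) -> np.ndarray:
    """Auxiliary candidate times given the current path (Rao-Teh move).

    On each holding interval of the path in state ``s``, extra candidate
    times arrive as a Poisson process with rate ``gamma - exit(s)``; the
    union with the path's actual jump times is the new grid.
    """
    times = [path.times[1:]]
    bounds = np.append(path.times, path.t_end)
    for k, s in enumerate(path.states):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            continue
        rate = chain.gamma - chain.exit_rates[chain.space.locate(s)]
        n = rng.poisson(max(rate, 0.0) * (hi - lo))
        if n:
            times.append(rng.uniform(lo, hi, size=n))
    grid = np.concatenate(times) if times else np.empty(0)
    return np.unique(grid)


def _emission_schedule(obs: ObservationSet, space: StateSpace, grid: np.ndarray):
    """Attach each observation's emission vector to its grid index.

    An observation at time t reads the chain state at the last grid time
    <= t (right-continuous paths).  Returns {grid index: emission vector}.
    """
    full = np.concatenate([[0.0], grid])
    sched: dict[int, np.ndarray] = {}
    for i in range(len(obs)):
        g = int(np.searchsorted(full, obs.times[i], side="right")) - 1
        e = obs.emission_vector(i, space)
        if not np.any(e):
            raise ZeroLikelihoodError(
                f"observation {i} at t={obs.times[i]} matches no state in the space"
            )
        sched[g] = sched[g] * e if g in sched else e
    return sched


def _forward_filter(B: np.ndarray, p0: np.ndarray, sched, n_steps: int):
    """Normalized forward messages over grid indices 0..n_steps."""
    n = B.shape[0]
    fwd = np.empty((n_steps + 1, n))
    lognorm = np.empty(n_steps + 1)
    a = p0 * sched[0] if 0 in sched else p0.copy()
    for g in range(n_steps + 1):
        if g > 0:
            a = a @ B
            if g in sched:
                a = a * sched[g]
        z = a.sum()
        if z <= 0:
            raise ZeroLikelihoodError("observations jointly impossible on this space")
        a /= z
        fwd[g] = a
        lognorm[g] = np.log(z)
        a = a.copy()
    return fwd, lognorm


def _backward_messages(B: np.ndarray, sched, n_steps: int) -> np.ndarray:
    """Normalized backward messages b^(g) ∝ p(future obs | state at g)."""
    n = B.shape[0]
    bwd = np.empty((n_steps + 1, n))
    b = np.ones(n)
    for g in range(n_steps, -1, -1):
        if g in sched and g != 0:
            b = b * sched[g]
        bwd[g] = b / b.sum()
        if g > 0:
            b = B @ bwd[g]
    return bwd


def _backward_sample(B, fwd: np.ndarray, rng: np.random.Generator):
    G = fwd.shape[0] - 1
    z = np.empty(G + 1, dtype=np.int64)
    z[G] = _categorical(fwd[G], rng)
    if sparse.issparse(B):
        BT = B.T.tocsr()
        for g in range(G - 1, -1, -1):
            lo, hi = BT.indptr[z[g + 1]], BT.indptr[z[g + 1] + 1]
            idx = BT.indices[lo:hi]
            w = fwd[g][idx] * BT.data[lo:hi]
            c = np.cumsum(w)
            z[g] = idx[int(np.searchsorted(c, rng.random() * c[-1], side="right"))]
        return z
    for g in range(G - 1, -1, -1):
        w = fwd[g] * B[:, z[g + 1]]
        z[g] = _categorical(w, rng)
    return z


def _categorical(w: np.ndarray, rng: np.random.Generator) -> int:
    c = np.cumsum(w)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


# ---------------------------------------------------------------------------
# public operations


def _default_p0(space: StateSpace) -> np.ndarray:
    return np.full(len(space), 1.0 / len(space))


def sample_posterior_path(
    model: PMJPModel,
    theta,
    obs: ObservationSet,
    space: StateSpace,
    current_path: Trajectory | None,
    seed,
    multiplier: float = 2.0,
    t_end: float | None = None,
    p0: np.ndarray | None = None,
) -> Trajectory:
    """Draw a trajectory from the conditional posterior over paths.

    Candidate jump times come from the auxiliary-variable construction:
    resampled around ``current_path`` when one exists on this space, or a
    fresh homogeneous Poisson(gamma) grid otherwise (e.g. after a change of
    truncation).  FFBS then draws the state sequence on the grid and
    self-jumps are removed.  With noiseless observations the returned path
    passes through every observed state at its time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t_end is None:
        t_end = float(obs.times[-1])
    gen = build_generator(model, space, theta, mode="closed")
    chain = uniformise(gen, multiplier)
    p0 = _default_p0(space) if p0 is None else np.asarray(p0, float)
    # Check observation feasibility once (independent of the grid).
    for i in range(len(obs)):
        if not np.any(obs.emission_vector(i, space)):
            raise ZeroLikelihoodError(
                f"observation {i} at t={obs.times[i]} matches no state in the space"
            )
    max_tries = 1 if current_path is not None else 500
    for attempt in range(max_tries):
        if current_path is not None:
            grid = _resampled_grid(rng, chain, current_path)
        else:
            grid = _fresh_grid(rng, chain.gamma, t_end)
        grid = grid[(grid > 0) & (grid < t_end)]
        sched = _emission_schedule(obs, space, grid)
        try:
            fwd, _ = _forward_filter(chain.B, p0, sched, len(grid))
        except ZeroLikelihoodError:
            # A fresh Poisson grid may have too few candidate times to
            # connect the observations; redraw.  A grid resampled around a
            # consistent current path always supports it, so failure there
            # means the observations really are impossible.
            if current_path is None and attempt < max_tries - 1:
                continue
            raise
        break
    z = _backward_sample(chain.B, fwd, rng)
    full_times = np.concatenate([[0.0], grid])
    keep = np.concatenate([[True], z[1:] != z[:-1]])
    return Trajectory(
        chain.space.states[z[keep]], full_times[keep], t_end=t_end
    )


def compute_messages(
    model: PMJPModel,
    theta,
    obs: ObservationSet,
    space: StateSpace,
    grid: np.ndarray,
    multiplier: float = 2.0,
    p0: np.ndarray | None = None,
) -> MessageSet:
    """Forward then backward messages of the uniformised chain on a grid."""
    gen = build_generator(model, space, theta, mode="closed")
    chain = uniformise(gen, multiplier)
    sched = _emission_schedule(obs, space, grid)
    p0 = _default_p0(space) if p0 is None else np.asarray(p0, float)
    fwd, lognorm = _forward_filter(chain.B, p0, sched, len(grid))
    bwd = _backward_messages(chain.B, sched, len(grid))
    return MessageSet(fwd, bwd, lognorm)


def path_conditional_probability(
    path: Trajectory,
    model: PMJPModel,
    theta,
    obs: ObservationSet,
    space: StateSpace,
    grid: np.ndarray | None = None,
    multiplier: float = 2.0,
    p0: np.ndarray | None = None,
) -> float:
    """Log conditional probability of ``path`` given observations and theta.

    The path is discretized on ``grid`` (default: its own jump times); the
    probability is the chain's joint weight of that state sequence divided
    by the evidence, obtained from a forward pass first (the backward
    messages are by-products available via :func:`compute_messages`).
    Returns ``-inf`` when the path leaves the space or contradicts a
    noiseless observation.
    """
    if grid is None:
        grid = path.times[1:]
    return paths_conditional_probabilities(
        [path], model, theta, obs, space, grid, multiplier=multiplier, p0=p0
    )[0]


def paths_conditional_probabilities(
    paths,
    model: PMJPModel,
    theta,
    obs: ObservationSet,
    space: StateSpace,
    grid: np.ndarray,
    multiplier: float = 2.0,
    p0: np.ndarray | None = None,
) -> list[float]:
    """Log conditional probabilities of several paths on one shared grid.

    The uniformised chain and the evidence (forward-filter normalizer) are
    computed once; each path then contributes only its own joint weight.
    ``grid`` must contain every jump time of every path so the discretized
    sequences represent the paths faithfully.
    """
    t_end = paths[0].t_end
    grid = np.asarray(grid, float)
    grid = grid[(grid > 0) & (grid < t_end)]
    gen = build_generator(model, space, theta, mode="closed")
    chain = uniformise(gen, multiplier)
    p0 = _default_p0(space) if p0 is None else np.asarray(p0, float)
    try:
        sched = _emission_schedule(obs, space, grid)
        fwd, lognorm = _forward_filter(chain.B, p0, sched, len(grid))
    except ZeroLikelihoodError:
        # no path on this grid is consistent with the observations
        return [-np.inf] * len(paths)
    log_evidence = float(lognorm.sum())
    full_times = np.concatenate([[0.0], grid])

    out = []
    for path in paths:
        z = space.locate_many(path.states_at(full_times))
        if np.any(z < 0):
            out.append(-np.inf)
            continue
        with np.errstate(divide="ignore"):
            lognum = np.log(p0[z[0]])
            if 0 in sched:
                lognum += np.log(sched[0][z[0]])
            if len(z) > 1:
                lognum += np.log(chain.step_probs(z)).sum()
            for g, e in sched.items():
                if g > 0:
                    lognum += np.log(e[z[g]])
        out.append(float(lognum - log_evidence) if np.isfinite(lognum) else -np.inf)
    return out
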