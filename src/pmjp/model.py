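"""Population Markov jump process (pMJP) models, state spaces and generators.

A pMJP tracks integer counts of ``M`` species evolving through ``R``
reaction channels.  Reaction ``i`` fires from state ``s`` at rate
``theta_i * rho_i(s)`` where ``rho_i`` is a fixed function of the state and
``theta_i`` is the (typically unknown) kinetic parameter — one parameter per
reaction.  On a finite state space the jump rates assemble into a generator
matrix ``A`` whose transient solution is ``p(t) = p(0) exp(A t)``.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "VIRTUAL",
    "KineticLaw",
    "Reaction",
    "PMJPModel",
    "StateSpace",
    "GeneratorMatrix",
    "propensity",
    "infer_reaction",
    "enumerate_box",
    "enumerate_reachable",
    "build_generator",
]

#: Sentinel returned by :func:`infer_reaction` for self-jumps (virtual jumps
#: introduced by uniformisation).
VIRTUAL = "virtual"

# Generators on spaces larger than this are stored sparse (CSR).
DENSE_LIMIT = 500


def _falling_factorial(n: np.ndarray, c: int) -> np.ndarray:
    """n (n-1) ... (n-c+1), elementwise; 0 where n < c, 1 where c == 0."""
    out = np.ones_like(n, dtype=float)
    for j in range(c):
        out *= np.maximum(n - j, 0.0)
    return out


class KineticLaw:
    """The state-dependent factor rho(s) of a kinetic law theta * rho(s).

    The declarative form covers every law used by the benchmark systems::

        rho(s) = prod_j ff(s_j, c_j) * prod_(j,v) [s_j == v] * prod_(j,r) exp(r s_j)

    where ``ff`` is the falling factorial (mass action), indicator factors
    gate a reaction on an exact species level (e.g. a gene being on), and
    exponential factors express repression rates such as ``theta * exp(r P)``.
    An arbitrary callable may be supplied instead; such laws cannot be
    serialized to config files.
    """

    def __init__(
        self,
        mass_action: Sequence[int] | None = None,
        indicators: Sequence[tuple[int, int]] = (),
        exponentials: Sequence[tuple[int, float]] = (),
        func: Callable[[np.ndarray], float] | None = None,
    ):
        if func is not None and (mass_action is not None or indicators or exponentials):
            raise ValueError("a custom callable law cannot be combined with declarative factors")
        self.mass_action = None if mass_action is None else tuple(int(c) for c in mass_action)
        self.indicators = tuple((int(j), int(v)) for j, v in indicators)
        self.exponentials = tuple((int(j), float(r)) for j, r in exponentials)
        self.func = func

    def __call__(self, s: np.ndarray) -> np.ndarray | float:
        """Evaluate rho at a single state ``(M,)`` or a batch ``(n, M)``."""
        s = np.asarray(s)
        if self.func is not None:
            if s.ndim == 1:
                return float(self.func(s))
            return np.array([float(self.func(row)) for row in s])
        batch = s.ndim == 2
        arr = s if batch else s[None, :]
        out = np.ones(arr.shape[0])
        if self.mass_action is not None:
            for j, c in enumerate(self.mass_action):
                if c:
                    out *= _falling_factorial(arr[:, j].astype(float), c)
        for j, v in self.indicators:
            out *= arr[:, j] == v
        for j, r in self.exponentials:
            out *= np.exp(r * arr[:, j].astype(float))
        return out if batch else float(out[0])

    def spec(self) -> dict:
        """Declarative description for config round-trips."""
        if self.func is not None:
            raise ValueError("custom callable kinetic laws are not serializable")
        d: dict = {}
        if self.mass_action is not None:
            d["mass_action"] = list(self.mass_action)
        if self.indicators:
            d["indicators"] = [[j, v] for j, v in self.indicators]
        if self.exponentials:
            d["exponentials"] = [[j, r] for j, r in self.exponentials]
        return d

    @classmethod
    def from_spec(cls, d: dict) -> "KineticLaw":
        return cls(
            mass_action=d.get("mass_action"),
            indicators=[tuple(p) for p in d.get("indicators", ())],
            exponentials=[tuple(p) for p in d.get("exponentials", ())],
        )

    def scalar(self, s) -> float:
        """Pure-Python evaluation at one state (fast path for simulation)."""
        if self.func is not None:
            return float(self.func(np.asarray(s)))
        out = 1.0
        if self.mass_action is not None:
            for j, c in enumerate(self.mass_action):
                n = s[j]
                for k in range(c):
                    out *= n - k if n >= k + 1 else 0.0
        for j, v in self.indicators:
            if s[j] != v:
                return 0.0
        from math import exp

        for j, r in self.exponentials:
            out *= exp(r * s[j])
        return float(out)


@dataclass(frozen=True)
class Reaction:
    """A reaction channel: net stoichiometry ``delta`` and law factor ``rho``."""

    name: str
    delta: tuple
    rho: KineticLaw
    param_index: int | None = None

    def __post_init__(self):
        delta = tuple(int(d) for d in self.delta)
        object.__setattr__(self, "delta", delta)
        if not any(delta):
            raise ValueError(f"reaction {self.name!r} has zero net stoichiometry")


class PMJPModel:
    """A pMJP: species, reactions, kinetic parameters theta and Gamma priors.

    Parameters
    ----------
    species : sequence of str
        Species names; the state vector has one count per species.
    reactions : sequence of Reaction
        Reaction channels.  Net stoichiometry vectors must be pairwise
        distinct so that the reaction fired between two states can be read
        off their difference.
    theta : sequence of float
        Kinetic parameters, one per reaction, all positive.
    priors : sequence of (shape, rate)
        Gamma prior hyperparameters for each theta_i.
    """

    def __init__(self, species, reactions, theta, priors):
        self.species = tuple(str(s) for s in species)
        self.reactions = tuple(reactions)
        self.theta = np.asarray(theta, dtype=float)
        self.priors = np.asarray(priors, dtype=float).reshape(-1, 2)
        self._validate()
        self._deltas = np.array([r.delta for r in self.reactions], dtype=np.int64)
        self._delta_lookup = {r.delta: i for i, r in enumerate(self.reactions)}
        # dims with negative stoichiometry, per reaction (orthant guard)
        self._guards = [
            [(j, -d) for j, d in enumerate(r.delta) if d < 0] for r in self.reactions
        ]

    def _validate(self):
        M, R = len(self.species), len(self.reactions)
        if R < 1:
            raise ValueError("a model needs at least one reaction")
        for r in self.reactions:
            if len(r.delta) != M:
                raise ValueError(f"reaction {r.name!r} delta has wrong length")
        if self.theta.shape != (R,) or np.any(self.theta <= 0):
            raise ValueError("theta must be positive with one entry per reaction")
        if self.priors.shape != (R, 2) or np.any(self.priors <= 0):
            raise ValueError("priors must be positive (shape, rate) pairs, one per reaction")
        deltas = [r.delta for r in self.reactions]
        if len(set(deltas)) != len(deltas):
            raise ValueError(
                "duplicate net stoichiometry vectors: reactions would not be "
                "identifiable from state differences"
            )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def deltas(self) -> np.ndarray:
        """(R, M) integer array of net stoichiometries."""
        return self._deltas

    def propensities(self, s: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        """All R propensities at state ``s`` (rows of a batch are states)."""
        theta = self.theta if theta is None else np.asarray(theta, dtype=float)
        s = np.asarray(s)
        if s.ndim == 1:
            return np.array(
                [propensity(self, i, s, theta) for i in range(self.n_reactions)]
            )
        return np.stack(
            [self._batch_propensity(i, s, theta) for i in range(self.n_reactions)], axis=1
        )

    def _batch_propensity(self, i: int, states: np.ndarray, theta: np.ndarray) -> np.ndarray:
        rxn = self.reactions[i]
        rho = np.asarray(rxn.rho(states), dtype=float)
        feasible = np.all(states + self._deltas[i] >= 0, axis=1)
        return theta[i] * rho * feasible

    def propensities_fast(self, s, theta: np.ndarray) -> np.ndarray:
        """Unvalidated scalar propensities (hot path of the simulator)."""
        out = np.empty(len(self.reactions))
        for i, rxn in enumerate(self.reactions):
            for j, need in self._guards[i]:
                if s[j] < need:
                    out[i] = 0.0
                    break
            else:
                out[i] = theta[i] * rxn.rho.scalar(s)
        return out

    def with_theta(self, theta) -> "PMJPModel":
        return PMJPModel(self.species, self.reactions, theta, self.priors)


def propensity(
    model: PMJPModel, i: int, s, theta: np.ndarray | None = None
) -> float:
    """Rate ``theta_i * rho_i(s)`` of reaction ``i`` at state ``s``.

    Returns 0 when firing the reaction would drive any count negative.
    """
    if not 0 <= i < model.n_reactions:
        raise IndexError(f"invalid reaction index {i}")
    s = np.asarray(s, dtype=np.int64)
    if s.shape != (model.n_species,):
        raise ValueError("state vector has wrong length")
    if np.any(s < 0):
        raise ValueError("negative state entry")
    if np.any(s + model.deltas[i] < 0):
        return 0.0
    theta = model.theta if theta is None else theta
    return float(theta[i]) * float(model.reactions[i].rho(s))


def infer_reaction(model: PMJPModel, s_k, s_next):
    """Identify the reaction fired between consecutive states.

    Returns the reaction index whose stoichiometry equals ``s_next - s_k``,
    or :data:`VIRTUAL` for a self-jump.  Raises ``ValueError`` when no
    reaction matches (a corrupted trajectory).
    """
    diff = tuple(int(d) for d in (np.asarray(s_next) - np.asarray(s_k)))
    if not any(diff):
        return VIRTUAL
    try:
        return model._delta_lookup[diff]
    except KeyError:
        raise ValueError(f"no reaction with net stoichiometry {diff}") from None


class StateSpace:
    """An ordered finite set of nonnegative integer state vectors.

    States are held in lexicographic order; ``locate`` maps a state back to
    its position.  Box-shaped spaces remember their bounds so lookups and
    generator assembly can use index arithmetic.
    """

    def __init__(self, states: np.ndarray, box: tuple[np.ndarray, np.ndarray] | None = None):
        states = np.asarray(states, dtype=np.int64)
        if states.ndim != 2:
            raise ValueError("states must be a (n, M) array")
        if np.any(states < 0):
            raise ValueError("states must be nonnegative")
        self.states = states
        self._box = None
        if box is not None:
            self._box = (np.asarray(box[0], np.int64), np.asarray(box[1], np.int64))
            self._index = None
        else:
            self._index = {tuple(s): k for k, s in enumerate(states)}
            if len(self._index) != len(states):
                raise ValueError("duplicate states")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_species(self) -> int:
        return self.states.shape[1]

    @property
    def is_box(self) -> bool:
        return self._box is not None

    @property
    def box_bounds(self):
        return self._box

    def __contains__(self, s) -> bool:
        return self.locate_many(np.asarray(s, np.int64)[None, :])[0] >= 0

    def locate(self, s) -> int:
        """Position of state ``s``; raises ``KeyError`` if absent."""
        k = self.locate_many(np.asarray(s, np.int64)[None, :])[0]
        if k < 0:
            raise KeyError(f"state {tuple(np.asarray(s))} not in space")
        return int(k)

    def locate_many(self, states: np.ndarray) -> np.ndarray:
        """Positions of a batch of states; -1 for states outside the space."""
        states = np.asarray(states, np.int64)
        if self._box is not None:
            lower, upper = self._box
            dims = upper - lower + 1
            inside = np.all((states >= lower) & (states <= upper), axis=1)
            shifted = np.clip(states - lower, 0, dims - 1)
            idx = np.ravel_multi_index(shifted.T, dims)
            return np.where(inside, idx, -1)
        return np.array([self._index.get(tuple(s), -1) for s in states], dtype=np.int64)


_BOX_CACHE: dict = {}
_BOX_CACHE_MAX = 256


def enumerate_box(lower, upper) -> StateSpace:
    """All integer vectors with ``lower <= x <= upper``, lexicographically.

    Repeated calls with the same bounds return the same object, so
    downstream caches keyed on the space (generator templates) stay warm.
    """
    lower = np.asarray(lower, np.int64)
    upper = np.asarray(upper, np.int64)
    if lower.shape != upper.shape or lower.ndim != 1:
        raise ValueError("bounds must be 1-d vectors of equal length")
    if np.any(lower < 0) or np.any(lower > upper):
        raise ValueError("require 0 <= lower <= upper componentwise")
    key = (tuple(lower), tuple(upper))
    cached = _BOX_CACHE.get(key)
    if cached is not None:
        return cached
    grids = [np.arange(lo, hi + 1) for lo, hi in zip(lower, upper)]
    states = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, len(lower))
    space = StateSpace(states, box=(lower, upper))
    if len(_BOX_CACHE) >= _BOX_CACHE_MAX:
        _BOX_CACHE.pop(next(iter(_BOX_CACHE)))
    _BOX_CACHE[key] = space
    return space


def enumerate_reachable(
    model: PMJPModel,
    s0,
    bound=None,
    max_states: int = 1_000_000,
) -> StateSpace:
    """Breadth-first closure of ``s0`` under the reaction stoichiometries.

    A reaction contributes an edge from ``s`` only where its rate factor
    ``rho(s)`` is positive and the successor stays in the nonnegative
    orthant (and under ``bound``, a per-dimension cap, when given).  The
    resulting states are sorted lexicographically.
    """
    s0 = np.asarray(s0, np.int64)
    if np.any(s0 < 0):
        raise ValueError("initial state must be nonnegative")
    bound = None if bound is None else np.asarray(bound, np.int64)
    seen = {tuple(s0)}
    queue = deque([s0])
    while queue:
        s = queue.popleft()
        for i, rxn in enumerate(model.reactions):
            if rxn.rho(s) <= 0:
                continue
            nxt = s + model.deltas[i]
            if np.any(nxt < 0):
                continue
            if bound is not None and np.any(nxt > bound):
                continue
            key = tuple(nxt)
            if key not in seen:
                seen.add(key)
                if len(seen) > max_states:
                    raise RuntimeError(
                        f"reachable closure exceeds safety limit of {max_states} states"
                    )
                queue.append(nxt)
    states = np.array(sorted(seen), dtype=np.int64)
    return StateSpace(states)


@dataclass
class GeneratorMatrix:
    """Generator ``A`` of a pMJP restricted to a finite state space.

    ``mode='closed'`` drops reactions that would leave the space entirely
    (rows sum to zero: a reflecting/static truncation).  In
    ``mode='substochastic'`` those rates are charged to the diagonal, so row
    sums are <= 0 and probability mass exits the space along trajectories
    that escape it — exactly the semantics needed for the bounded transient
    probabilities f^(N).
    """

    space: StateSpace
    rates: object  # (n, n) ndarray or scipy sparse CSR
    mode: str

    @property
    def n(self) -> int:
        return len(self.space)

    def as_dense(self) -> np.ndarray:
        if sparse.issparse(self.rates):
            return self.rates.toarray()
        return np.asarray(self.rates)

    def row_sums(self) -> np.ndarray:
        if sparse.issparse(self.rates):
            return np.asarray(self.rates.sum(axis=1)).ravel()
        return self.rates.sum(axis=1)

    def exit_rates(self) -> np.ndarray:
        """Total off-diagonal rate per state (|diagonal| in closed mode)."""
        d = self.rates.diagonal()
        return self.row_sums() - d


class _GeneratorTemplate:
    """theta-independent skeleton of a generator on a fixed space.

    The generator is linear in the kinetic parameters,
    ``A(theta) = sum_r theta_r A_r``, so the sparsity pattern and the
    rho-factors are computed once per (model, space, mode) and each
    assembly only rescales values — the samplers re-evaluate A at a fresh
    theta every sweep.
    """

    def __init__(self, model: PMJPModel, space: StateSpace, mode: str):
        n = len(space)
        states = space.states
        rows, cols, vals, ids = [], [], [], []
        for i in range(model.n_reactions):
            unit = model._batch_propensity(i, states, np.ones(model.n_reactions))
            active = unit > 0
            if not np.any(active):
                continue
            src = np.nonzero(active)[0]
            tgt = space.locate_many(states[src] + model.deltas[i])
            inside = tgt >= 0
            # off-diagonal jump rates
            rows.append(src[inside])
            cols.append(tgt[inside])
            vals.append(unit[src[inside]])
            ids.append(np.full(inside.sum(), i))
            # diagonal: closed mode only charges in-space jumps, the
            # substochastic mode charges every feasible firing
            dsrc = src if mode == "substochastic" else src[inside]
            dval = unit[dsrc]
            rows.append(dsrc)
            cols.append(dsrc)
            vals.append(-dval)
            ids.append(np.full(len(dsrc), i))
        if rows:
            self.rows = np.concatenate(rows)
            self.cols = np.concatenate(cols)
            self.unit_vals = np.concatenate(vals)
            self.ids = np.concatenate(ids)
        else:
            self.rows = self.cols = np.empty(0, np.int64)
            self.unit_vals = np.empty(0)
            self.ids = np.empty(0, np.int64)
        self.n = n

    def assemble(self, theta: np.ndarray, dense: bool):
        vals = self.unit_vals * theta[self.ids]
        A = sparse.coo_matrix(
            (vals, (self.rows, self.cols)), shape=(self.n, self.n)
        ).tocsr()
        return A.toarray() if dense else A


_TEMPLATE_CACHE: dict = {}
_TEMPLATE_CACHE_MAX = 128


def _generator_template(model, space, mode) -> _GeneratorTemplate:
    key = (id(model), id(space), mode)
    hit = _TEMPLATE_CACHE.get(key)
    if hit is not None:
        return hit[0]
    tpl = _GeneratorTemplate(model, space, mode)
    if len(_TEMPLATE_CACHE) >= _TEMPLATE_CACHE_MAX:
        _TEMPLATE_CACHE.pop(next(iter(_TEMPLATE_CACHE)))
    # keep model/space alive so their ids cannot be recycled
    _TEMPLATE_CACHE[key] = (tpl, model, space)
    return tpl


def build_generator(
    model: PMJPModel,
    space: StateSpace,
    theta=None,
    mode: str = "closed",
    dense_limit: int = DENSE_LIMIT,
) -> GeneratorMatrix:
    """Assemble the generator of ``model`` on ``space``.

    Off-diagonal entry ``a_ij`` sums ``theta_r * rho_r(s_i)`` over reactions
    carrying ``s_i`` to ``s_j``.  See :class:`GeneratorMatrix` for the two
    diagonal conventions.
    """
    if mode not in ("closed", "substochastic"):
        raise ValueError("mode must be 'closed' or 'substochastic'")
    theta = model.theta if theta is None else np.asarray(theta, dtype=float)
    if theta.shape != (model.n_reactions,):
        raise ValueError("theta length mismatch")
    if len(space) == 0:
        raise ValueError("empty state space")
    tpl = _generator_template(model, space, mode)
    rates = tpl.assemble(theta, dense=len(space) <= dense_limit)
    return GeneratorMatrix(space, rates, mode)
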