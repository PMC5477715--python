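"""Transient probabilities, the nested series expansion of the transition
likelihood, and the Russian-Roulette unbiased estimator.

For an interval between noiseless observations ``s -> s'`` of duration
``dt``, the transition probability expands as an infinite series over the
"dispersal" ``N``::

    p(s' | s) = sum_N p^(N),   p^(N) = f^(N) - f^(N-1),   p^(0) = f^(0)

where ``f^(N)`` is the probability that the process reaches ``s'`` at time
``dt`` without ever exceeding ``s_upper + N`` in any dimension
(``s_upper = max(s, s')`` componentwise).  Each ``f^(N)`` is a transient
probability of a finite, substochastic system and each ``p^(N)`` is itself a
probability, hence nonnegative.  Randomly truncating the series with
geometric continuation probabilities and reweighting retained terms by
their inclusion probabilities yields a nonnegative unbiased estimator of
the exact (infinite-state-space) likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import expm
from scipy.sparse.linalg import expm_multiply

from .model import GeneratorMatrix, PMJPModel, build_generator, enumerate_box
from .simulate import ObservationSet

__all__ = [
    "TruncationScheme",
    "IntervalSpec",
    "LikelihoodEstimate",
    "transient_probability",
    "bounded_transient_f",
    "series_term_p",
    "sample_num_terms",
    "expected_terms",
    "roulette_interval_estimate",
    "likelihood_estimate",
]

logger = logging.getLogger(__name__)

# p^(N) obtained by subtraction is clamped to 0 when within this of 0.
NEG_CLAMP = 1e-12

# Safety cap on the box built for a single f^(N) evaluation.
MAX_BOX_STATES = 200_000


@dataclass(frozen=True)
class TruncationScheme:
    """Geometric Russian-Roulette truncation.

    Term 0 is always taken; after term ``n-1`` the sum continues to term
    ``n`` with probability ``q̄_n = a**n``.  Term ``N`` is therefore
    included with probability ``p_N = prod_{j<=N} a**j = a**(N(N+1)/2)``,
    which is also the weight restoring unbiasedness.
    """

    a: float

    def __post_init__(self):
        if not 0 < self.a < 1:
            raise ValueError("continuation parameter a must lie in (0, 1)")

    def continuation_probability(self, n: int) -> float:
        """q̄_n: probability of continuing past term n-1 to term n."""
        return self.a**n if n >= 1 else 1.0

    def inclusion_probability(self, N: int) -> float:
        """p_N = a^(N(N+1)/2): probability that term N is included."""
        return self.a ** (N * (N + 1) / 2)


def sample_num_terms(scheme: TruncationScheme, seed) -> int:
    """Draw the number of series terms retained (always >= 1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 1
    while rng.random() < scheme.a**n:
        n += 1
    return n


def expected_terms(scheme: TruncationScheme, tol: float = 1e-12) -> float:
    """Analytic expected number of retained terms: 1 + sum_n a^(n(n+1)/2)."""
    total = 1.0
    n = 1
    while True:
        term = scheme.inclusion_probability(n)
        total += term
        if term < tol:
            return total
        n += 1


@dataclass(frozen=True)
class IntervalSpec:
    """One inter-observation interval: start state, end state, duration."""

    s: tuple
    s_prime: tuple
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "s", tuple(int(x) for x in self.s))
        object.__setattr__(self, "s_prime", tuple(int(x) for x in self.s_prime))
        if self.dt <= 0:
            raise ValueError("interval duration must be positive")
        if any(x < 0 for x in self.s) or any(x < 0 for x in self.s_prime):
            raise ValueError("states must be nonnegative")

    @property
    def s_upper(self) -> np.ndarray:
        return np.maximum(self.s, self.s_prime)


@dataclass
class LikelihoodEstimate:
    """A Russian-Roulette likelihood estimate over an observation set."""

    value: float
    log_value: float
    terms_used: list
    weights: list
    flagged_zero: bool = False


def transient_probability(gen: GeneratorMatrix, p0, t: float):
    """``p0 @ expm(A t)`` via a scaling-based matrix-exponential action.

    In substochastic mode the result may sum to less than one; the missing
    mass belongs to trajectories that left the space.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (gen.n,):
        raise ValueError("initial distribution has wrong dimension")
    if t < 0:
        raise ValueError("time must be nonnegative")
    if t == 0:
        return p0.copy()
    A = gen.rates
    if sparse.issparse(A):
        return expm_multiply((A.T * t).tocsc(), p0)
    if gen.n <= 120:
        return p0 @ expm(A * t)
    return expm_multiply(A.T * t, p0)


def _f_box_upper(interval: IntervalSpec, N: int) -> np.ndarray:
    return interval.s_upper + N


def bounded_transient_f(
    model: PMJPModel, theta, interval: IntervalSpec, N: int
) -> float:
    """f^(N): probability of ending at ``s'`` after ``dt`` while never
    exceeding ``s_upper + N`` in any dimension.

    Computed as the ``(s -> s')`` entry of ``expm(A_N dt)`` with ``A_N`` the
    substochastic generator on the box ``[0, s_upper + N]``: outflow from
    the box is dropped, so the retained mass is exactly the probability of
    staying inside.
    """
    if N < 0:
        raise ValueError("N must be nonnegative")
    upper = _f_box_upper(interval, N)
    n_states = int(np.prod(upper + 1))
    if n_states > MAX_BOX_STATES:
        raise RuntimeError(f"f^({N}) box would have {n_states} states")
    space = enumerate_box(np.zeros_like(upper), upper)
    gen = build_generator(model, space, theta, mode="substochastic")
    p0 = np.zeros(len(space))
    p0[space.locate(interval.s)] = 1.0
    p = transient_probability(gen, p0, interval.dt)
    return float(p[space.locate(interval.s_prime)])


def series_term_p(model: PMJPModel, theta, interval: IntervalSpec, N: int) -> float:
    """p^(N) = f^(N) - f^(N-1) (p^(0) = f^(0)), clamped at 0 near round-off."""
    fN = bounded_transient_f(model, theta, interval, N)
    if N == 0:
        return fN
    fNm1 = bounded_transient_f(model, theta, interval, N - 1)
    diff = fN - fNm1
    if diff < 0:
        if diff < -NEG_CLAMP:
            logger.warning("p^(%d) = %.3e below clamp tolerance", N, diff)
        return 0.0
    return diff


class _IntervalKernel:
    """Computes and caches the f^(N) sequence for one interval at fixed theta.

    ``partial_sum(k)`` returns sum_{N<k} p^(N)/p_N, reusing previously
    computed terms — the estimator for a roulette draw of ``k`` terms.
    """

    def __init__(self, model, theta, interval: IntervalSpec, scheme: TruncationScheme):
        self.model = model
        self.theta = np.asarray(theta, float)
        self.interval = interval
        self.scheme = scheme
        self._f: list[float] = []
        self._partial: list[float] = [0.0]  # partial[k] = sum over N < k

    def _extend(self, k: int):
        while len(self._f) < k:
            N = len(self._f)
            fN = bounded_transient_f(self.model, self.theta, self.interval, N)
            pN = fN if N == 0 else max(fN - self._f[N - 1], 0.0)
            self._f.append(fN)
            self._partial.append(
                self._partial[-1] + pN / self.scheme.inclusion_probability(N)
            )

    def partial_sum(self, k: int) -> float:
        self._extend(k)
        return self._partial[k]


def roulette_interval_estimate(
    model: PMJPModel,
    theta,
    interval: IntervalSpec,
    scheme: TruncationScheme,
    seed,
    kernel: _IntervalKernel | None = None,
) -> float:
    """One Russian-Roulette draw of the interval transition probability.

    Draws the number of retained terms, then returns
    ``sum_{N<k} p^(N) / a^(N(N+1)/2)``.  Nonnegative by construction and
    unbiased for the exact (untruncated) transition probability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = sample_num_terms(scheme, rng)
    if kernel is None:
        kernel = _IntervalKernel(model, theta, interval, scheme)
    return kernel.partial_sum(k)


def intervals_from_observations(obs: ObservationSet) -> list[IntervalSpec]:
    """Consecutive observation pairs as interval specifications."""
    if len(obs) < 2:
        raise ValueError("need at least two observation times")
    return [
        IntervalSpec(tuple(obs.values[i]), tuple(obs.values[i + 1]),
                     obs.times[i + 1] - obs.times[i])
        for i in range(len(obs) - 1)
    ]


def likelihood_estimate(
    model: PMJPModel,
    theta,
    obs: ObservationSet,
    scheme: TruncationScheme,
    seed,
    kernels: dict | None = None,
) -> LikelihoodEstimate:
    """Unbiased estimate of the observation likelihood.

    Independent roulette estimates of the transition probability of each
    consecutive observation pair are multiplied (accumulated in the log
    domain).  ``kernels`` may carry a reusable per-interval f^(N) cache for
    repeated evaluation at the same theta.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_value = 0.0
    terms_used, weights = [], []
    flagged = False
    for interval in intervals_from_observations(obs):
        kernel = None
        if kernels is not None:
            key = (interval.s, interval.s_prime, round(interval.dt, 12))
            kernel = kernels.get(key)
            if kernel is None:
                kernel = kernels[key] = _IntervalKernel(model, theta, interval, scheme)
        k = sample_num_terms(scheme, rng)
        if kernel is None:
            kernel = _IntervalKernel(model, theta, interval, scheme)
        est = kernel.partial_sum(k)
        terms_used.append(k)
        weights.append([scheme.inclusion_probability(N) for N in range(k)])
        if est <= 0:
            flagged = True
            log_value = -np.inf
        elif np.isfinite(log_value):
            log_value += np.log(est)
    value = float(np.exp(log_value)) if np.isfinite(log_value) else 0.0
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "roulette likelihood: log=%.6g terms_per_interval=%s", log_value, terms_used
        )
    return LikelihoodEstimate(value, float(log_value), terms_used, weights, flagged)
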