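"""Convergence and efficiency diagnostics for sampler output.

Implements the effective sample size (ESS) with Geyer's initial monotone
sequence truncation and the classic Gelman–Rubin potential scale reduction
factor (PSRF) computed on the second halves of the chains, with PSRF < 1.1
as the conventional convergence yardstick.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from statsmodels.tsa.stattools import acovf

__all__ = [
    "DiagnosticsReport",
    "effective_sample_size",
    "psrf",
    "convergence_iteration",
    "relative_error",
    "summarize_chains",
    "NOT_CONVERGED",
]

#: Sentinel returned by :func:`convergence_iteration` when no prefix converges.
NOT_CONVERGED = -1


def effective_sample_size(samples) -> float:
    """ESS = n / (1 + 2 sum_k rho_k), Geyer initial-monotone truncation.

    Autocorrelations are summed in adjacent pairs Gamma_m = rho_2m +
    rho_2m+1 for as long as the pairs stay positive, then forced
    nonincreasing — the standard reversible-chain estimator.  A constant
    series has no information and reports ESS 0 with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need a 1-d series of length >= 10")
    n = len(x)
    if np.ptp(x) == 0:
        warnings.warn("constant series: ESS undefined, reporting 0", RuntimeWarning)
        return 0.0
    gamma = acovf(x, fft=True, demean=True)
    rho = gamma / gamma[0]
    pair_sums = []
    m = 0
    while 2 * m + 1 < n:
        g = rho[2 * m] + rho[2 * m + 1]
        if g <= 0:
            break
        pair_sums.append(g)
        m += 1
    pair_sums = np.minimum.accumulate(pair_sums) if pair_sums else np.array([1.0])
    tau = max(2.0 * float(np.sum(pair_sums)) - 1.0, 1.0 / n)
    return float(min(n / tau, n))


def psrf(chains) -> float:
    """Gelman–Rubin statistic on the second halves of >= 2 equal-length chains."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    halves = arr[:, arr.shape[1] // 2 :]
    m, n = halves.shape
    if n < 2:
        raise ValueError("chains too short")
    means = halves.mean(axis=1)
    W = float(np.mean(np.var(halves, axis=1, ddof=1)))
    B = n * float(np.var(means, ddof=1))
    if W == 0:
        warnings.warn("zero within-chain variance: PSRF reported as 1.0", RuntimeWarning)
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def convergence_iteration(chains, threshold: float = 1.1, n_checkpoints: int = 20):
    """Smallest checkpointed prefix length with PSRF below ``threshold``.

    ``chains`` is (m, n) for one parameter or (m, n, R); with several
    parameters every one must pass.  Returns :data:`NOT_CONVERGED` when no
    prefix qualifies.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    _, n, R = arr.shape
    checkpoints = np.unique(np.linspace(max(4, n // n_checkpoints), n, n_checkpoints).astype(int))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for c in checkpoints:
            if all(psrf(arr[:, :c, r]) < threshold for r in range(R)):
                return int(c)
    return NOT_CONVERGED


def relative_error(posterior_means, true_theta) -> float:
    """Mean relative error of posterior-mean point estimates, in percent."""
    means = np.asarray(posterior_means, dtype=float)
    true = np.asarray(true_theta, dtype=float)
    if means.shape != true.shape:
        raise ValueError("dimension mismatch")
    if np.any(true <= 0):
        raise ValueError("true parameters must be positive")
    return float(np.mean(np.abs(means - true) / true) * 100.0)


@dataclass
class DiagnosticsReport:
    """Per-parameter summary of a multi-chain run."""

    ess: list
    psrf: list
    iterations_to_convergence: int
    posterior_mean: list
    posterior_q05: list
    posterior_q95: list
    mean_relative_error: float | None = None
    psrf_threshold: float = 1.1

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticsReport":
        return cls(**json.loads(text))


def summarize_chains(
    chains, true_theta=None, psrf_threshold: float = 1.1
) -> DiagnosticsReport:
    """Build a :class:`DiagnosticsReport` from (m, n, R) theta samples."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    m, n, R = arr.shape
    pooled = arr.reshape(m * n, R)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ess = [float(np.sum([effective_sample_size(arr[c, :, r]) for c in range(m)]))
               for r in range(R)]
        psrfs = [psrf(arr[:, :, r]) if m >= 2 else float("nan") for r in range(R)]
        conv = convergence_iteration(arr, threshold=psrf_threshold) if m >= 2 else NOT_CONVERGED
    mre = None
    if true_theta is not None:
        mre = relative_error(pooled.mean(axis=0), true_theta)
    return DiagnosticsReport(
        ess=ess,
        psrf=psrfs,
        iterations_to_convergence=conv,
        posterior_mean=pooled.mean(axis=0).tolist(),
        posterior_q05=np.quantile(pooled, 0.05, axis=0).tolist(),
        posterior_q95=np.quantile(pooled, 0.95, axis=0).tolist(),
        mean_relative_error=mre,
        psrf_threshold=psrf_threshold,
    )
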