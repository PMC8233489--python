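"""Discrete power-law fitting for degree distributions.

Maximum-likelihood estimation of the exponent of a discrete power law
P(X = x) = x^(-alpha) / zeta(alpha, xmin), with the lower cutoff xmin chosen
by Kolmogorov-Smirnov minimization and plausibility judged by a
semiparametric bootstrap — the standard procedure for testing whether a
network's degree distribution is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = [
    "PowerlawFit",
    "sample_discrete_powerlaw",
    "fit_alpha",
    "ks_statistic",
    "fit_discrete_powerlaw",
    "bootstrap_pvalue",
]


@dataclass
class PowerlawFit:
    alpha: float
    xmin: int
    ks: float
    n_tail: int
    p_value: float | None = None

    @property
    def goodness(self) -> str:
        """'plausible' when the bootstrap p-value is at least 0.1."""
        if self.p_value is None:
            return "untested"
        return "plausible" if self.p_value >= 0.1 else "implausible"


def sample_discrete_powerlaw(
    alpha: float, xmin: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact sampling by inverse-CDF bisection on the integer support."""
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if xmin < 1:
        raise ValueError("xmin must be >= 1")
    u = rng.random(size)
    z0 = zeta(alpha, xmin)
    # P(X >= x) = zeta(alpha, x) / zeta(alpha, xmin); return the largest x
    # with P(X >= x) > u, by doubling then bisection on the survival.
    lo = np.full(size, xmin, dtype=np.int64)
    hi = np.full(size, xmin, dtype=np.int64)
    while True:
        surv = zeta(alpha, hi + 1) / z0
        grow = surv > u  # the answer lies above hi
        if not np.any(grow):
            break
        lo[grow] = hi[grow] + 1
        hi[grow] *= 2
    while np.any(hi > lo):
        mid = (lo + hi) // 2
        surv = zeta(alpha, mid + 1) / z0
        take = surv > u  # the answer is at least mid+1
        lo = np.where(take, mid + 1, lo)
        hi = np.where(take, hi, mid)
    return lo


def fit_alpha(data: np.ndarray, xmin: int) -> float:
    """MLE of the exponent for the tail ``data >= xmin``."""
    tail = data[data >= xmin]
    n = len(tail)
    if n == 0:
        raise ValueError("no data at or above xmin")
    slog = np.sum(np.log(tail))

    def nll(a: float) -> float:
        return n * np.log(zeta(a, xmin)) + a * slog

    res = minimize_scalar(nll, bounds=(1.0001, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def ks_statistic(data: np.ndarray, alpha: float, xmin: int) -> float:
    """KS distance between the tail's empirical CDF and the fitted model."""
    tail = np.sort(data[data >= xmin])
    n = len(tail)
    values = np.unique(tail)
    z0 = zeta(alpha, xmin)
    # both CDFs are right-continuous step functions with jumps only at the
    # observed atoms, so the sup-distance is attained at an atom
    model_cdf = 1.0 - zeta(alpha, values + 1) / z0
    emp_cdf = np.searchsorted(tail, values, side="right") / n
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def fit_discrete_powerlaw(
    data: np.ndarray, max_xmin_candidates: int = 60
) -> PowerlawFit:
    """Fit alpha and xmin by MLE + KS minimization over candidate cutoffs.

    Zero values (isolated nodes) are excluded; candidate xmin values are the
    distinct observed values (thinned evenly to at most
    ``max_xmin_candidates``), keeping at least 10 tail observations.
    """
    data = np.asarray(data, dtype=np.int64)
    data = data[data >= 1]
    if len(data) < 10:
        raise ValueError("need at least 10 positive observations")
    values = np.unique(data)
    # keep cutoffs leaving a usable tail
    tail_sizes = len(data) - np.searchsorted(np.sort(data), values, side="left")
    values = values[tail_sizes >= 10]
    if len(values) == 0:
        values = np.unique(data)[:1]
    if len(values) > max_xmin_candidates:
        idx = np.linspace(0, len(values) - 1, max_xmin_candidates).astype(int)
        values = values[np.unique(idx)]
    best: PowerlawFit | None = None
    for xmin in values:
        a = fit_alpha(data, int(xmin))
        ks = ks_statistic(data, a, int(xmin))
        if best is None or ks < best.ks:
            best = PowerlawFit(alpha=a, xmin=int(xmin), ks=ks,
                               n_tail=int(np.sum(data >= xmin)))
    assert best is not None
    return best


def bootstrap_pvalue(
    data: np.ndarray,
    fit: PowerlawFit,
    n_bootstrap: int = 100,
    seed: int = 0,
    max_xmin_candidates: int = 60,
) -> float:
    """Semiparametric bootstrap p-value for power-law plausibility.

    Each replicate draws, per observation, from the fitted tail model with
    probability n_tail/n and otherwise resamples the observed body; the full
    fitting procedure is re-run on the replicate and the p-value is the
    fraction of replicate KS distances at least as large as the observed one.
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(data, dtype=np.int64)
    data = data[data >= 1]
    n = len(data)
    body = data[data < fit.xmin]
    p_tail = fit.n_tail / n
    exceed = 0
    for _ in range(n_bootstrap):
        from_tail = rng.random(n) < p_tail
        k = int(np.sum(from_tail))
        rep = np.empty(n, dtype=np.int64)
        if k:
            rep[:k] = sample_discrete_powerlaw(fit.alpha, fit.xmin, k, rng)
        if n - k:
            rep[k:] = rng.choice(body if len(body) else data, size=n - k)
        rep_fit = fit_discrete_powerlaw(rep, max_xmin_candidates)
        if rep_fit.ks >= fit.ks:
            exceed += 1
    return exceed / n_bootstrap
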