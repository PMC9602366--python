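"""Mismatch distributions and sudden-expansion model fitting.

The expected distribution of pairwise differences under an instantaneous
change of the scaled mutation parameter from theta0 to theta1 at mutational
time tau before present (Li 1977; Rogers & Harpending 1992) is::

    F_j = Fhat_j(theta1)
          + exp(-tau * (theta1 + 1) / theta1)
            * sum_{i=0}^{j} tau^i / i! * (Fhat_{j-i}(theta0) - Fhat_{j-i}(theta1))

with the equilibrium distribution ``Fhat_j(theta) = theta^j / (theta+1)^(j+1)``
(geometric).  Parameters are estimated by least squares between the observed
relative mismatch frequencies and F_j, via multi-start local optimization.

The fitted tau converts to calendar time through ``tau = 2*u*t`` with the
per-sequence rate ``u = L * r``; the default rate convention uses the
published sequence *divergence* rate per site per year directly as ``r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .differentiation import DistanceMatrix

__all__ = [
    "MismatchDistribution",
    "ExpansionFit",
    "ExpansionTime",
    "observed_mismatch",
    "expected_mismatch",
    "fit_expansion",
    "expansion_time",
    "DEFAULT_BOUNDS",
]

# (tau, theta0, theta1) box constraints; theta1 additionally >= theta0.
DEFAULT_BOUNDS = ((0.0, 50.0), (1e-6, 50.0), (1e-6, 20000.0))


@dataclass(frozen=True)
class MismatchDistribution:
    counts: tuple[int, ...]  # index j = number of pairwise differences
    population: str = ""

    @property
    def n_pairs(self) -> int:
        return sum(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_pairs

    @property
    def mean(self) -> float:
        j = np.arange(len(self.counts))
        return float((j * np.asarray(self.counts)).sum() / self.n_pairs)


@dataclass(frozen=True)
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    converged: bool
    bounds_hit: tuple[bool, bool, bool]


@dataclass(frozen=True)
class ExpansionTime:
    t_years: float
    tau: float
    L: int
    rate_per_site_per_year: float

    @property
    def u(self) -> float:
        return self.L * self.rate_per_site_per_year


def observed_mismatch(
    dm: DistanceMatrix, members: Sequence[str], population: str = ""
) -> MismatchDistribution:
    """Histogram of pairwise difference counts within a sample subset."""
    if len(members) < 2:
        raise ValueError("mismatch distribution requires >= 2 members")
    sub = dm.submatrix(list(members))
    m = len(members)
    iu = np.triu_indices(m, k=1)
    diffs = sub.d[iu].astype(int)
    counts = np.bincount(diffs)
    return MismatchDistribution(tuple(int(c) for c in counts), population)


def _equilibrium(theta: float, j_max: int) -> np.ndarray:
    """Fhat_j(theta) = theta^j / (theta+1)^(j+1) for j = 0..j_max."""
    j = np.arange(j_max + 1)
    return np.exp(j * math.log(theta) - (j + 1) * math.log(theta + 1.0)) \
        if theta > 0 else np.where(j == 0, 1.0, 0.0)


def expected_mismatch(
    tau: float, theta0: float, theta1: float, j_max: int
) -> np.ndarray:
    """Expected pairwise-difference probabilities F_0..F_{j_max}.

    Nonnegative; the full series over j = 0..inf sums to 1, so
    ``1 - sum(result)`` is the truncation mass beyond j_max.
    """
    if theta0 < 0 or theta1 <= 0:
        raise ValueError("theta parameters must be positive")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    f0 = _equilibrium(theta0, j_max)
    f1 = _equilibrium(theta1, j_max)
    diff = f0 - f1
    # log-space Poisson weights; tau = 0 leaves only the i = 0 term
    i = np.arange(j_max + 1)
    if tau == 0:
        w = np.where(i == 0, 1.0, 0.0)
    else:
        w = np.exp(i * math.log(tau) - [math.lgamma(x + 1) for x in i])
    conv = np.convolve(w, diff)[: j_max + 1]
    F = f1 + math.exp(-tau * (theta1 + 1.0) / theta1) * conv
    return np.maximum(F, 0.0)


def _ssd(params: np.ndarray, obs_freq: np.ndarray) -> float:
    tau, theta0, theta1 = params
    if theta1 < theta0:  # enforce ordering softly inside the optimizer
        return 1e6 + (theta0 - theta1)
    exp_f = expected_mismatch(tau, theta0, theta1, len(obs_freq) - 1)
    return float(((obs_freq - exp_f) ** 2).sum())


def fit_expansion(
    mm: MismatchDistribution,
    bounds: tuple = DEFAULT_BOUNDS,
    n_starts: int = 20,
    seed: int = 0,
) -> ExpansionFit:
    """Least-squares fit of (tau, theta0, theta1) to a mismatch histogram.

    Multi-start Nelder-Mead within box bounds over a coarse grid of starting
    points plus seeded jitter; deterministic given the seed.  Ties are broken
    by lowest SSD then lowest tau.  ``bounds_hit`` flags parameters that
    ended within 0.1% of a box edge.
    """
    obs = mm.frequencies
    # pad the histogram a little so the fit sees the right tail
    pad = max(5, len(obs) // 2)
    obs = np.concatenate([obs, np.zeros(pad)])
    mean_d = max(mm.mean, 0.05)

    rng = np.random.default_rng(seed)
    (t_lo, t_hi), (q0_lo, q0_hi), (q1_lo, q1_hi) = bounds
    base_starts = [
        (min(max(mean_d, t_lo), t_hi), q0_lo * 10, min(10.0 * mean_d + 1, q1_hi)),
        (min(mean_d / 2 + 0.1, t_hi), 0.5, min(100.0, q1_hi)),
        (min(mean_d, t_hi), 1.0, min(q1_hi, 1000.0)),
        (t_lo + 0.1, q0_lo * 10, min(mean_d + 1, q1_hi)),
    ]
    starts = list(base_starts)
    while len(starts) < n_starts:
        starts.append(
            (
                rng.uniform(t_lo, min(t_hi, 3 * mean_d + 1)),
                math.exp(rng.uniform(math.log(q0_lo), math.log(q0_hi))),
                math.exp(rng.uniform(math.log(max(q1_lo, 1e-3)), math.log(q1_hi))),
            )
        )

    best: tuple[float, float, np.ndarray] | None = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            _ssd,
            np.asarray(x0, dtype=float),
            args=(obs,),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
        )
        any_converged = any_converged or bool(res.success)
        key = (res.fun, res.x[0])
        if best is None or key < (best[0], best[1]):
            best = (res.fun, res.x[0], res.x)
    assert best is not None
    x = best[2]
    rel = 1e-3
    hits = (
        x[0] <= t_lo + rel * (t_hi - t_lo) or x[0] >= t_hi - rel * (t_hi - t_lo),
        x[1] <= q0_lo * (1 + rel) or x[1] >= q0_hi * (1 - rel),
        x[2] <= q1_lo * (1 + rel) or x[2] >= q1_hi * (1 - rel),
    )
    return ExpansionFit(
        tau=float(x[0]),
        theta0=float(x[1]),
        theta1=float(x[2]),
        ssd=float(best[0]),
        converged=any_converged,
        bounds_hit=hits,
    )


def expansion_time(
    tau: float, L: int, rate_per_site_per_year: float
) -> ExpansionTime:
    """Calendar years since expansion: ``t = tau / (2 * L * r)``."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if rate_per_site_per_year <= 0:
        raise ValueError("rate must be positive")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    u = L * rate_per_site_per_year
    return ExpansionTime(
        t_years=tau / (2.0 * u),
        tau=tau,
        L=L,
        rate_per_site_per_year=rate_per_site_per_year,
    )
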