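"""Neutrality tests: Tajima's D and Fu's Fs.

Tajima's D follows Tajima (1989): D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1))
with the a1..e2 constants depending only on the sample size.

Fu's Fs follows Fu (1997): with theta estimated by the mean pairwise
difference k_hat, S' is the probability of observing at least the observed
number of distinct haplotypes under the Ewens sampling formula, and
Fs = ln(S' / (1 - S')).  The Ewens probabilities are computed in log space
through the unsigned-Stirling-number recurrence, which is stable for the
sample sizes mtDNA studies use (n <= a few hundred).

Significance for both statistics is simulated under a constant-size neutral
coalescent (lower tail, since both tests flag negative values).  Fs is
conventionally called significant at p < 0.02, D at p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diversity import (
    UndefinedStatisticError,
    count_site_types,
    mean_pairwise_differences,
)
from .seqio import Alignment

__all__ = [
    "TajimaD",
    "FuFs",
    "tajima_constants",
    "tajimas_d",
    "ewens_pmf",
    "fus_fs",
    "neutrality_significance",
]

D_ALPHA = 0.05
FS_ALPHA = 0.02


@dataclass(frozen=True)
class TajimaD:
    n: int
    S: int
    k_hat: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float
    p_value: float | None
    significant: bool | None


@dataclass(frozen=True)
class FuFs:
    n: int
    k0: int
    theta_hat: float
    s_prime: float
    fs: float
    p_value: float | None
    significant: bool | None


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989), functions of n only."""
    if n < 4:
        raise UndefinedStatisticError("Tajima's D requires n >= 4")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _tajimas_d_value(n: int, S: int, k_hat: float) -> tuple[float, dict]:
    c = tajima_constants(n)
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k_hat - S / c["a1"]) / math.sqrt(var), c


def tajimas_d(
    aln: Alignment,
    n_sims: int = 1000,
    seed: int = 0,
    compute_p: bool = True,
) -> TajimaD:
    """Tajima's D for a (masked) alignment, with simulated p-value."""
    S, _, _ = count_site_types(aln)
    k_hat = mean_pairwise_differences(aln)
    D, c = _tajimas_d_value(aln.n, S, k_hat)
    p = sig = None
    if compute_p:
        p = neutrality_significance(
            "D", D, aln.n, S=S, n_sims=n_sims, seed=seed
        )
        sig = p < D_ALPHA
    return TajimaD(
        n=aln.n, S=S, k_hat=k_hat, D=D, p_value=p, significant=sig, **c
    )


# ---------------------------------------------------------------------------
# Ewens sampling formula and Fu's Fs


def _log_stirling_row(n: int) -> np.ndarray:
    """log |S1(n, k)| for k = 0..n via the standard recurrence.

    |S1(n,k)| = |S1(n-1,k-1)| + (n-1)*|S1(n-1,k)|, computed in log space to
    stay finite for large n.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S1(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = row[0:m]
        with np.errstate(divide="ignore"):
            shifted = row + math.log(m - 1) if m > 1 else np.full(n + 1, -np.inf)
        new = np.logaddexp(new, shifted)
        row = new
    return row


def ewens_pmf(n: int, theta: float) -> np.ndarray:
    """Pr(K = k) for k = 1..n under the Ewens sampling formula.

    Pr(K = k) = |S1(n,k)| * theta^k / (theta * (theta+1) * ... * (theta+n-1)).
    Returned as a length-n vector (index 0 is k=1); sums to 1 within 1e-12.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_stir = _log_stirling_row(n)[1:]  # k = 1..n
    log_theta_rising = sum(math.log(theta + i) for i in range(n))
    k = np.arange(1, n + 1)
    logp = log_stir + k * math.log(theta) - log_theta_rising
    p = np.exp(logp)
    return p / p.sum()  # renormalize away last-ulp drift


def _fs_value(n: int, k0: int, theta: float) -> tuple[float, float]:
    pmf = ewens_pmf(n, theta)
    s_prime = float(pmf[k0 - 1 :].sum())
    s_prime = min(max(s_prime, 1e-300), 1.0 - 1e-16)
    return math.log(s_prime / (1.0 - s_prime)), s_prime


def fus_fs(
    aln: Alignment,
    n_sims: int = 1000,
    seed: int = 0,
    compute_p: bool = True,
) -> FuFs:
    """Fu's Fs for a (masked) alignment, with simulated p-value."""
    if aln.n < 2:
        raise UndefinedStatisticError("Fu's Fs requires n >= 2")
    k_hat = mean_pairwise_differences(aln)
    if k_hat <= 0:
        raise UndefinedStatisticError("Fu's Fs undefined for monomorphic data")
    k0 = len(set(aln.sequences))
    if k0 < 2:
        # k_hat > 0 forces at least two distinct sequences
        raise UndefinedStatisticError("inconsistent haplotype count")
    fs, s_prime = _fs_value(aln.n, k0, k_hat)
    p = sig = None
    if compute_p:
        p = neutrality_significance(
            "Fs", fs, aln.n, theta=k_hat, n_sims=n_sims, seed=seed
        )
        sig = p < FS_ALPHA
    return FuFs(
        n=aln.n,
        k0=k0,
        theta_hat=k_hat,
        s_prime=s_prime,
        fs=fs,
        p_value=p,
        significant=sig,
    )


# ---------------------------------------------------------------------------
# Null distribution by neutral coalescent simulation


def _simulate_neutral_stats(
    n: int, theta: float, rng: np.random.Generator
) -> tuple[int, float, int]:
    """One constant-size coalescent replicate with infinite-sites mutation.

    Returns (S, k_hat, k0) for a sample of n lineages with scaled mutation
    parameter theta (mutations on a branch of coalescent length t are
    Poisson(t * theta / 2)).
    """
    # Kingman coalescent: record, per mutation, the set of descendant tips.
    lineages = [frozenset([i]) for i in range(n)]
    muts: list[frozenset[int]] = []
    k = n
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        # mutations fall uniformly on the k active branches during time t
        n_mut = rng.poisson(k * t * theta / 2.0)
        for _ in range(n_mut):
            muts.append(lineages[rng.integers(k)])
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1
    seg = [m for m in muts if 0 < len(m) < n]
    S = len(seg)
    genotypes = [frozenset(mi for mi, m in enumerate(seg) if t in m) for t in range(n)]
    total = 0
    for a in range(n):
        for b in range(a + 1, n):
            total += len(genotypes[a] ^ genotypes[b])
    k_hat = total / (n * (n - 1) / 2.0)
    k0 = len(set(genotypes))
    return S, k_hat, k0


def neutrality_significance(
    stat: str,
    observed: float,
    n: int,
    *,
    theta: float | None = None,
    S: int | None = None,
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Lower-tail p-value for Tajima's D or Fu's Fs by neutral simulation.

    The null is a constant-size coalescent sample of size ``n``; its scaled
    mutation parameter is ``theta`` if given, otherwise the Watterson
    estimate ``S / a1``.  p is the fraction of simulated statistics <= the
    observed value, among replicates where the statistic is defined, with
    the (hits+1)/(m+1) correction.
    """
    if stat not in {"D", "Fs"}:
        raise ValueError("stat must be 'D' or 'Fs'")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if theta is None:
        if S is None:
            raise ValueError("provide theta or S")
        theta = S / tajima_constants(n)["a1"]
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    hits = defined = 0
    for _ in range(n_sims):
        S_sim, k_hat_sim, k0_sim = _simulate_neutral_stats(n, theta, rng)
        if stat == "D":
            if S_sim < 1:
                continue
            value, _ = _tajimas_d_value(n, S_sim, k_hat_sim)
        else:
            if k_hat_sim <= 0:
                continue
            value, _ = _fs_value(n, k0_sim, k_hat_sim)
        defined += 1
        if value <= observed + 1e-12:
            hits += 1
    if defined == 0:
        return 1.0
    return (hits + 1) / (defined + 1)
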