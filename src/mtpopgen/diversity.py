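"""Per-population molecular diversity indices.

Implements the classical unbiased estimators:

* haplotype (gene) diversity ``h = n/(n-1) * (1 - sum p_i^2)`` with its
  sampling variance (Nei 1987, eq. 8.12),
* nucleotide diversity ``pi`` as the mean pairwise proportion of differing
  sites, with the total (stochastic + sampling) variance of Nei 1987,
  eq. 10.7,
* segregating-site counts split into transition and transversion site types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .seqio import Alignment, HaplotypeTable, PopulationMap

__all__ = [
    "DiversityStats",
    "haplotype_diversity",
    "nucleotide_diversity",
    "count_site_types",
    "population_diversity",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class UndefinedStatisticError(ValueError):
    """Statistic undefined for the given sample (e.g. n < 2)."""


@dataclass(frozen=True)
class DiversityStats:
    population: str
    n: int
    nh: int
    h: float
    se_h: float
    pi: float
    se_pi: float
    S: int
    k_hat: float
    ti: int
    tv: int


def haplotype_diversity(counts: Sequence[int], n: int) -> tuple[float, float]:
    """Nei's haplotype diversity and its standard error.

    ``h = n/(n-1) * (1 - sum p_i^2)`` with variance (Nei 1987, eq. 8.12)::

        V(h) = 2/(n(n-1)) * { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
                              + sum p_i^2 - (sum p_i^2)^2 }
    """
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity requires n >= 2")
    if sum(counts) != n:
        raise ValueError("haplotype counts must sum to n")
    p = [c / n for c in counts if c > 0]
    sum_p2 = sum(x * x for x in p)
    sum_p3 = sum(x**3 for x in p)
    h = n / (n - 1) * (1.0 - sum_p2)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2)
    )
    return h, math.sqrt(max(var, 0.0))


def mean_pairwise_differences(aln: Alignment) -> float:
    """Mean number of differing sites over all C(n,2) sequence pairs."""
    if aln.n < 2:
        raise UndefinedStatisticError("need at least two sequences")
    total = 0
    for a, b in combinations(aln.sequences, 2):
        total += sum(x != y for x, y in zip(a, b))
    return total / math.comb(aln.n, 2)


def nucleotide_diversity(aln: Alignment) -> tuple[float, float, float]:
    """Nucleotide diversity per site, its standard error, and k_hat.

    ``pi = k_hat / L`` where ``k_hat`` is the mean pairwise difference
    count.  The standard error uses the total variance of Nei 1987,
    eq. 10.7::

        V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2
    """
    n, L = aln.n, aln.length
    k_hat = mean_pairwise_differences(aln)
    pi = k_hat / L
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi
    return pi, math.sqrt(max(var, 0.0)), k_hat


def classify_pair(a: str, b: str) -> str:
    """'ti' for purine-purine or pyrimidine-pyrimidine, else 'tv'."""
    if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
        return "ti"
    return "tv"


def count_site_types(aln: Alignment) -> tuple[int, int, int]:
    """Segregating sites and transition/transversion site-pair counts.

    Each polymorphic column contributes one count per unordered pair of
    observed states, so a biallelic column adds exactly one transition or
    transversion and a triallelic column adds up to three.
    """
    S = ti = tv = 0
    for j in range(aln.length):
        states = sorted(set(aln.column(j)))
        if len(states) < 2:
            continue
        S += 1
        for a, b in combinations(states, 2):
            if classify_pair(a, b) == "ti":
                ti += 1
            else:
                tv += 1
    return S, ti, tv


def population_diversity(
    aln: Alignment, pm: PopulationMap, population: str
) -> DiversityStats:
    """All diversity indices for one population (base label or grouping)."""
    sub = aln.subset(pm.members(population))
    ht = _hap_counts(sub)
    h, se_h = haplotype_diversity(ht, sub.n)
    pi, se_pi, k_hat = nucleotide_diversity(sub)
    S, ti, tv = count_site_types(sub)
    return DiversityStats(
        population=population,
        n=sub.n,
        nh=len(ht),
        h=h,
        se_h=se_h,
        pi=pi,
        se_pi=se_pi,
        S=S,
        k_hat=k_hat,
        ti=ti,
        tv=tv,
    )


def _hap_counts(aln: Alignment) -> list[int]:
    counts: dict[str, int] = {}
    for s in aln.sequences:
        counts[s] = counts.get(s, 0) + 1
    return list(counts.values())
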