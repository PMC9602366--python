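"""AMOVA variance decomposition, pairwise Phi_ST, and gene flow.

The fixation index computed here is the distance-based Phi_ST of the AMOVA
framework (Excoffier, Smouse & Quattro 1992) with pairwise nucleotide
difference counts used as squared Euclidean distances — the standard choice
for haploid sequence data.  Significance is assessed by permuting
individuals among populations with population sizes held fixed.

Negative variance components are retained, so Phi_ST may be slightly
negative for unstructured data; reports do not clamp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import Alignment, PopulationMap

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "FstMatrix",
    "GeneFlow",
    "pairwise_differences",
    "amova_two_level",
    "pairwise_phist",
    "fst_matrix",
    "gene_flow",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, counts of differing sites

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.d[np.ix_(idx, idx)])


@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    ssd_total: float
    sigma2_a: float
    sigma2_w: float
    pct_among: float
    pct_within: float
    fst: float
    p_value: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class FstMatrix:
    populations: tuple[str, ...]
    fst: np.ndarray
    p: np.ndarray


@dataclass(frozen=True)
class GeneFlow:
    nm: float
    category: str  # high (>=1.0), medium (0.250-0.99), low (0.0-0.249)


def pairwise_differences(aln: Alignment) -> DistanceMatrix:
    """Hamming distances between all sequence pairs on analyzed sites."""
    arr = np.frombuffer(
        "".join(aln.sequences).encode(), dtype="S1"
    ).reshape(aln.n, aln.length)
    d = np.zeros((aln.n, aln.n), dtype=float)
    for i in range(aln.n):
        d[i] = (arr != arr[i]).sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.sample_ids, d)


def _amova_components(
    d: np.ndarray, groups: np.ndarray, n_pops: int
) -> tuple[float, float, float, float, float]:
    """Variance components from squared distances and integer group labels.

    Returns (ssd_among, ssd_within, sigma2_a, sigma2_w, fst).
    SSD_total = sum_{i<j} d_ij / N ; SSD_within = sum over populations of
    within-population pair sums divided by the population size.
    """
    N = len(groups)
    triu = np.triu_indices(N, k=1)
    ssd_total = d[triu].sum() / N
    ssd_within = 0.0
    sizes = np.zeros(n_pops, dtype=float)
    for g in range(n_pops):
        idx = np.flatnonzero(groups == g)
        sizes[g] = len(idx)
        sub = d[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    P = n_pops
    sigma2_w = ssd_within / (N - P)
    n_bar = (N - (sizes**2).sum() / N) / (P - 1)
    sigma2_a = (ssd_among / (P - 1) - sigma2_w) / n_bar
    denom = sigma2_a + sigma2_w
    fst = sigma2_a / denom if denom > 0 else 0.0
    return ssd_among, ssd_within, sigma2_a, sigma2_w, fst


def amova_two_level(
    dm: DistanceMatrix,
    pm: PopulationMap,
    n_perm: int = 10_000,
    seed: int = 0,
    populations: Sequence[str] | None = None,
) -> AmovaResult:
    """Two-level AMOVA (among/within populations) with permutation test.

    The p-value uses the ``(hits + 1)/(n_perm + 1)`` estimator with the
    conservative ``>= observed`` tie rule.  Permutations shuffle individuals
    among populations with sizes held fixed; the RNG is seeded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pops = tuple(populations) if populations is not None else pm.populations
    if len(pops) < 2:
        raise ValueError("AMOVA requires at least two populations")
    label_order: list[str] = []
    groups_list: list[int] = []
    for g, p in enumerate(pops):
        members = pm.members(p)
        if len(members) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
        for s in members:
            label_order.append(s)
            groups_list.append(g)
    sub = dm.submatrix(label_order)
    groups = np.asarray(groups_list)
    N, P = len(groups), len(pops)

    ssd_a, ssd_w, s2a, s2w, fst = _amova_components(sub.d, groups, P)
    monomorphic = sub.d.max() == 0
    if monomorphic:
        fst = 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        *_, fst_p = _amova_components(sub.d, perm, P)
        if fst_p >= fst - 1e-12:
            hits += 1
    p_value = (hits + 1) / (n_perm + 1)

    denom = s2a + s2w
    pct_among = 100.0 * s2a / denom if denom > 0 else 0.0
    return AmovaResult(
        df_among=P - 1,
        df_within=N - P,
        ssd_among=ssd_a,
        ssd_within=ssd_w,
        ssd_total=ssd_a + ssd_w,
        sigma2_a=s2a,
        sigma2_w=s2w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        fst=fst,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
    )


def pairwise_phist(
    dm: DistanceMatrix,
    pm: PopulationMap,
    pair: tuple[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Phi_ST and permutation p-value for one population pair."""
    res = amova_two_level(dm, pm, n_perm=n_perm, seed=seed, populations=pair)
    return res.fst, res.p_value


def fst_matrix(
    dm: DistanceMatrix,
    pm: PopulationMap,
    populations: Sequence[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> FstMatrix:
    """All pairwise Phi_ST values with permutation p-values."""
    pops = tuple(populations) if populations is not None else pm.populations
    k = len(pops)
    fst = np.zeros((k, k))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f, pv = pairwise_phist(
                dm, pm, (pops[i], pops[j]), n_perm=n_perm,
                seed=seed + 1000 * i + j,
            )
            fst[i, j] = fst[j, i] = f
            p[i, j] = p[j, i] = pv
    return FstMatrix(pops, fst, p)


def gene_flow(fst: float) -> GeneFlow:
    """Wright's transformation ``Nm = (1/Fst - 1)/2`` with categorization.

    Categories: high for Nm >= 1.0, medium for 0.250 <= Nm < 1.0, low for
    Nm < 0.250.
    """
    if fst <= 0:
        raise ValueError("gene flow undefined (infinite) for Fst <= 0")
    if fst > 1:
        raise ValueError("Fst cannot exceed 1")
    nm = (1.0 / fst - 1.0) / 2.0
    if nm >= 1.0:
        category = "high"
    elif nm >= 0.250:
        category = "medium"
    else:
        category = "low"
    return GeneFlow(nm=nm, category=category)
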