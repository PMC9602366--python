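"""Independent brute-force reference implementations used only by tests.

Each function here recomputes a statistic from first principles, sharing no
code with the package, so that package results can be checked against a
second, independent path.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, product


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    n = 0
    for i in range(len(a)):
        if a[i] != b[i]:
            n += 1
    return n


def pi_bruteforce(seqs: list[str]) -> float:
    """Mean pairwise difference per site, by explicit double loop."""
    n = len(seqs)
    L = len(seqs[0])
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += hamming(seqs[i], seqs[j])
            npairs += 1
    return total / npairs / L


def k_hat_bruteforce(seqs: list[str]) -> float:
    n = len(seqs)
    total = sum(hamming(a, b) for a, b in combinations(seqs, 2))
    return total / (n * (n - 1) / 2)


def segregating_sites(seqs: list[str]) -> int:
    return sum(
        1 for j in range(len(seqs[0])) if len({s[j] for s in seqs}) > 1
    )


def tajimas_d_bruteforce(seqs: list[str]) -> float:
    """Step-by-step recomputation of Tajima's statistic from its paper."""
    n = len(seqs)
    S = segregating_sites(seqs)
    k = k_hat_bruteforce(seqs)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = float(e1) * S + float(e2) * S * (S - 1)
    return (k - S / float(a1)) / math.sqrt(var)


def stirling_unsigned(n: int, k: int) -> int:
    """Exact unsigned Stirling number of the first kind, by recursion."""
    if n == 0 and k == 0:
        return 1
    if n == 0 or k == 0:
        return 0
    return stirling_unsigned(n - 1, k - 1) + (n - 1) * stirling_unsigned(
        n - 1, k
    )


def ewens_pmf_exact(n: int, theta: Fraction) -> list[Fraction]:
    """Exact Ewens Pr(K=k), k=1..n, via integer Stirling numbers."""
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    return [
        stirling_unsigned(n, k) * theta**k / rising for k in range(1, n + 1)
    ]


def fus_fs_bruteforce(seqs: list[str]) -> float:
    n = len(seqs)
    k_hat = Fraction(
        sum(hamming(a, b) for a, b in combinations(seqs, 2)),
        n * (n - 1) // 2,
    )
    k0 = len(set(seqs))
    pmf = ewens_pmf_exact(n, k_hat)
    s_prime = float(sum(pmf[k0 - 1 :]))
    return math.log(s_prime / (1 - s_prime))


def amova_bruteforce(
    seqs_by_pop: dict[str, list[str]],
) -> tuple[float, float, float, float, float]:
    """(ssd_among, ssd_within, sigma2_a, sigma2_w, phi_st) from scratch."""
    all_seqs = [s for pop in seqs_by_pop.values() for s in pop]
    N = len(all_seqs)
    P = len(seqs_by_pop)
    ssd_total = (
        sum(hamming(a, b) for a, b in combinations(all_seqs, 2)) / N
    )
    ssd_within = 0.0
    for pop in seqs_by_pop.values():
        ssd_within += (
            sum(hamming(a, b) for a, b in combinations(pop, 2)) / len(pop)
        )
    ssd_among = ssd_total - ssd_within
    sigma2_w = ssd_within / (N - P)
    sizes = [len(p) for p in seqs_by_pop.values()]
    n_bar = (N - sum(s * s for s in sizes) / N) / (P - 1)
    sigma2_a = (ssd_among / (P - 1) - sigma2_w) / n_bar
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom != 0 else 0.0
    return ssd_among, ssd_within, sigma2_a, sigma2_w, phi


def mismatch_expected_highprec(
    tau: float, theta0: float, theta1: float, j_max: int
) -> list[float]:
    """Sudden-expansion mismatch probabilities via mpmath-free high
    precision: Fractions for the rational part, math.exp at the end."""
    from decimal import Decimal, getcontext

    getcontext().prec = 60
    t0 = Decimal(str(theta0))
    t1 = Decimal(str(theta1))
    td = Decimal(str(tau))

    def fhat(theta: Decimal, j: int) -> Decimal:
        return theta**j / (theta + 1) ** (j + 1)

    expfac = Decimal(
        str(math.exp(-tau * (theta1 + 1) / theta1))
    )  # double-precision exp; adequate for comparisons at ~1e-12
    out = []
    for j in range(j_max + 1):
        acc = Decimal(0)
        fact = Decimal(1)
        for i in range(j + 1):
            if i > 0:
                fact *= i
            acc += td**i / fact * (fhat(t0, j - i) - fhat(t1, j - i))
        out.append(float(fhat(t1, j) + expfac * acc))
    return out


def quasi_median_closure(seqs: set[str]) -> set[str]:
    """Exhaustive quasi-median closure over ALL triples of sequences."""
    current = set(seqs)
    while True:
        new = set()
        for u, v, w in combinations(sorted(current), 3):
            opts = []
            for a, b, c in zip(u, v, w):
                if a == b or a == c:
                    opts.append((a,))
                elif b == c:
                    opts.append((b,))
                else:
                    opts.append(tuple(sorted({a, b, c})))
            for combo in product(*opts):
                m = "".join(combo)
                if m not in current:
                    new.add(m)
        if not new:
            return current
        current |= new


def random_alignment(rng, n: int, L: int, alphabet: str = "ACGT"):
    """Random alignment with some shared polymorphism (not pure noise)."""
    base = [alphabet[rng.integers(len(alphabet))] for _ in range(L)]
    seqs = []
    for _ in range(n):
        s = list(base)
        n_mut = rng.integers(0, max(2, L // 4))
        for _ in range(n_mut):
            j = rng.integers(L)
            s[j] = alphabet[rng.integers(len(alphabet))]
        seqs.append("".join(s))
    return seqs
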