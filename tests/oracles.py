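"""Independent reference implementations used only by the test suite.

Each oracle is a deliberately naive transcription (scalar loops, explicit
enumeration) kept independent of the package's vectorized code paths.
"""

from __future__ import annotations

from itertools import product
from math import comb, lgamma

import numpy as np

# ---------------------------------------------------------------------
# Weir & Cockerham (1984) variance components, literal scalar transcription
# ---------------------------------------------------------------------


def wc_theta_oracle(pops: list[list[tuple[int, int]]]) -> float:
    """Multilocus theta from per-population lists of (a, b) genotype tuples.

    ``pops[i][j]`` is individual j of population i at a single locus when
    the inner list holds tuples, or use `wc_theta_oracle_multi` for multiple
    loci.  Missing data are encoded as (0, 0) and skipped.
    """
    return wc_theta_oracle_multi([pops])


def wc_theta_oracle_multi(loci: list[list[list[tuple[int, int]]]]) -> float:
    """theta over loci; ``loci[l][i]`` = genotype tuples of pop i at locus l."""
    sum_a = 0.0
    sum_abc = 0.0
    for locus in loci:
        pops = [[g for g in pop if g != (0, 0)] for pop in locus]
        pops = [p for p in pops if len(p) > 0]
        r = len(pops)
        if r < 2:
            continue
        ns = [len(p) for p in pops]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({a for p in pops for g in p for a in g})
        for allele in alleles:
            p_i = []
            h_i = []
            for pop in pops:
                n = len(pop)
                count = sum((g[0] == allele) + (g[1] == allele) for g in pop)
                p_i.append(count / (2 * n))
                h_i.append(sum((g[0] == allele) != (g[1] == allele) for g in pop) / n)
            pbar = sum(n * p for n, p in zip(ns, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, h_i)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


def wc_fis_oracle(loci: list[list[tuple[int, int]]]) -> float:
    """Within-population small-f; ``loci[l]`` = genotype tuples at locus l."""
    sum_b = 0.0
    sum_c = 0.0
    for locus in loci:
        genos = [g for g in locus if g != (0, 0)]
        n = len(genos)
        if n < 2:
            continue
        alleles = sorted({a for g in genos for a in g})
        if len(alleles) < 2:
            continue
        for allele in alleles:
            p = sum((g[0] == allele) + (g[1] == allele) for g in genos) / (2 * n)
            h = sum((g[0] == allele) != (g[1] == allele) for g in genos) / n
            b = (n / (n - 1)) * (p * (1 - p) - ((2 * n - 1) / (4 * n)) * h)
            c = h / 2
            sum_b += b
            sum_c += c
    return 1 - sum_c / (sum_b + sum_c)


# ---------------------------------------------------------------------
# Smouse & Peakall codominant squared distance, dictionary transcription
# ---------------------------------------------------------------------


def genotypic_distance_oracle(g1: tuple[int, int], g2: tuple[int, int]) -> float:
    s1, s2 = sorted(g1), sorted(g2)
    if s1 == s2:
        return 0.0
    shared = 0
    pool = list(s2)
    for a in s1:
        if a in pool:
            pool.remove(a)
            shared += 1
    hom1 = s1[0] == s1[1]
    hom2 = s2[0] == s2[1]
    if hom1 and hom2:
        return 4.0  # different homozygotes (identical case handled above)
    if hom1 != hom2:
        return 1.0 if shared == 1 else 3.0
    return 1.0 if shared == 1 else 2.0


# ---------------------------------------------------------------------
# Exact enumeration for the no-admixture clustering marginal (tiny cases)
# ---------------------------------------------------------------------


def _dirmult_log(counts: dict[int, int], n_alleles: int) -> float:
    tot = sum(counts.values())
    out = lgamma(n_alleles) - lgamma(n_alleles + tot)
    for c in counts.values():
        out += lgamma(c + 1.0)
    return out


def cluster_coassignment_oracle(genotypes: list[list[tuple[int, int]]], K: int,
                                n_alleles: int) -> np.ndarray:
    """Exact pairwise co-assignment probability under the collapsed
    no-admixture model with Dirichlet(1) frequency priors and a uniform
    assignment prior.  ``genotypes[i][l]`` = (a, b) with 0-based alleles."""
    n = len(genotypes)
    L = len(genotypes[0])
    post = np.zeros((n, n))
    total = 0.0
    weights = []
    assignments = list(product(range(K), repeat=n))
    for z in assignments:
        logw = 0.0
        for k in range(K):
            for l in range(L):
                counts: dict[int, int] = {a: 0 for a in range(n_alleles)}
                for i in range(n):
                    if z[i] == k:
                        counts[genotypes[i][l][0]] += 1
                        counts[genotypes[i][l][1]] += 1
                logw += _dirmult_log(counts, n_alleles)
        weights.append(logw)
    weights = np.array(weights)
    weights = np.exp(weights - weights.max())
    weights /= weights.sum()
    for w, z in zip(weights, assignments):
        for i in range(n):
            for j in range(n):
                if z[i] == z[j]:
                    post[i, j] += w
    return post


# ---------------------------------------------------------------------
# Exact enumeration for the genotype-frequency-class posterior (tiny cases)
# ---------------------------------------------------------------------

CLASS_WEIGHTS = {
    "Pure_A": (1.0, 0.0, 0.0),
    "Pure_B": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC_A": (0.5, 0.5, 0.0),
    "BC_B": (0.0, 0.5, 0.5),
}
CLASS_ORDER = ("Pure_A", "Pure_B", "F1", "F2", "BC_A", "BC_B")


def hybclass_posterior_oracle(genotypes: list[list[tuple[int, int]]],
                              n_alleles: int,
                              fixed: dict[int, str] | None = None) -> np.ndarray:
    """Exact class posterior, collapsing pool frequencies (Dirichlet(1)).

    Enumerates classes and ordered gene-copy origin configurations.  For
    each (individual, locus) the ordered origin pair o in {AA, AB, BA, BB}
    has prior (w0, w1/2, w1/2, w2) given the class; given all origins the
    data likelihood is the product over pools of Dirichlet-multinomial
    marginals of the allele copies routed to that pool.  ``genotypes``
    uses 0-based alleles; ``fixed`` pins individuals to named classes.
    """
    fixed = fixed or {}
    n = len(genotypes)
    L = len(genotypes[0])
    origin_opts = [(0, 0), (0, 1), (1, 0), (1, 1)]

    def origin_prior(cls: str, o: tuple[int, int]) -> float:
        w = CLASS_WEIGHTS[cls]
        if o == (0, 0):
            return w[0]
        if o == (1, 1):
            return w[2]
        return w[1] / 2

    post = np.zeros((n, 6))
    class_lists = [
        [fixed[i]] if i in fixed else list(CLASS_ORDER) for i in range(n)
    ]
    norm = 0.0
    for zs in product(*class_lists):
        for origins in product(origin_opts, repeat=n * L):
            prior = 1.0
            countsA: dict[tuple[int, int], int] = {}
            countsB: dict[tuple[int, int], int] = {}
            ok = True
            for i in range(n):
                for l in range(L):
                    o = origins[i * L + l]
                    p = origin_prior(zs[i], o)
                    if p == 0.0:
                        ok = False
                        break
                    prior *= p
                    a, b = genotypes[i][l]
                    for allele, pool in ((a, o[0]), (b, o[1])):
                        tgt = countsA if pool == 0 else countsB
                        tgt[(l, allele)] = tgt.get((l, allele), 0) + 1
                if not ok:
                    break
            if not ok:
                continue
            loglik = 0.0
            for counts in (countsA, countsB):
                for l in range(L):
                    loc_counts = {a: counts.get((l, a), 0) for a in range(n_alleles)}
                    loglik += _dirmult_log(loc_counts, n_alleles)
            w = prior * np.exp(loglik)
            norm += w
            for i in range(n):
                post[i, CLASS_ORDER.index(zs[i])] += w
    return post / norm


# ---------------------------------------------------------------------
# Brute-force minimum spanning total for small haplotype sets
# ---------------------------------------------------------------------


def min_spanning_total_oracle(dist: np.ndarray) -> int:
    """Minimum total edge weight of a spanning tree (Prim, scalar loops)."""
    n = dist.shape[0]
    in_tree = [0]
    total = 0
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j not in in_tree:
                    if best is None or dist[i, j] < best[0]:
                        best = (dist[i, j], j)
        total += best[0]
        in_tree.append(best[1])
    return int(total)
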