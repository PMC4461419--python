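"""Posterior classification into genotype frequency classes.

Two generations of crossing between two parental gene pools produce six
distinguishable classes — pure individuals of either pool, F1, F2, and the
two backcrosses — each defined by fixed expected proportions of the three
locus-ancestry categories (both gene copies from pool A, one from each,
both from pool B):

    Pure_A (1, 0, 0)     Pure_B (0, 0, 1)     F1 (0, 1, 0)
    F2 (1/4, 1/2, 1/4)   BC_A (1/2, 1/2, 0)   BC_B (0, 1/2, 1/2)

A Gibbs sampler alternates between per-individual class assignments,
per-gene-copy pool origins, and pool allele frequencies (Dirichlet(1)
prior).  The class prior is uniform.  Reference individuals of known
purity may be pinned to anchor the two pools; by default the model is
fully unsupervised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .datatypes import GenotypeMatrix
from .bayesclust import _encode_alleles

__all__ = [
    "CLASS_NAMES",
    "CLASS_CATEGORY_WEIGHTS",
    "class_genotype_likelihood",
    "classify_hybrids",
    "HybridPosterior",
]

CLASS_NAMES = ("Pure_A", "Pure_B", "F1", "F2", "BC_A", "BC_B")

# rows: classes; columns: ancestry categories (AA, one-each, BB)
CLASS_CATEGORY_WEIGHTS = np.array(
    [
        [1.0, 0.0, 0.0],  # Pure_A
        [0.0, 0.0, 1.0],  # Pure_B
        [0.0, 1.0, 0.0],  # F1
        [0.25, 0.5, 0.25],  # F2
        [0.5, 0.5, 0.0],  # BC_A
        [0.0, 0.5, 0.5],  # BC_B
    ]
)


def class_genotype_likelihood(
    genotype: tuple[int, int],
    hybrid_class: str,
    pool_a_freqs: dict[int, float],
    pool_b_freqs: dict[int, float],
) -> float:
    """P(single-locus genotype | genotype frequency class, pool frequencies).

    Within-pool categories contribute p_a^2 (homozygote) or 2 p_a p_b
    (heterozygote); the mixed category contributes p_Aa p_Ba for
    homozygotes and p_Aa p_Bb + p_Ab p_Ba for heterozygotes.
    """
    for name, freqs in (("A", pool_a_freqs), ("B", pool_b_freqs)):
        if abs(sum(freqs.values()) - 1.0) > 1e-6:
            raise ValueError(f"pool {name} frequencies must sum to 1")
    if hybrid_class not in CLASS_NAMES:
        raise ValueError(f"unknown genotype frequency class {hybrid_class!r}")
    w = CLASS_CATEGORY_WEIGHTS[CLASS_NAMES.index(hybrid_class)]
    a, b = genotype
    pa = pool_a_freqs.get
    pb = pool_b_freqs.get
    if a == b:
        cats = (pa(a, 0.0) ** 2, pa(a, 0.0) * pb(a, 0.0), pb(a, 0.0) ** 2)
    else:
        cats = (
            2 * pa(a, 0.0) * pa(b, 0.0),
            pa(a, 0.0) * pb(b, 0.0) + pa(b, 0.0) * pb(a, 0.0),
            2 * pb(a, 0.0) * pb(b, 0.0),
        )
    return float(np.dot(w, cats))


@njit(cache=True)
def _gibbs_hybclass(alleles, n_alleles, W, fixed, burnin, sweeps, thin, seed):
    np.random.seed(seed)
    n, L, _ = alleles.shape
    C = W.shape[0]
    # init frequencies from pooled data plus jitter
    pA = np.ones((L, n_alleles))
    pB = np.ones((L, n_alleles))
    for l in range(L):
        for i in range(n):
            a = alleles[i, l, 0]
            if a >= 0:
                pA[l, a] += 1.0
                pB[l, alleles[i, l, 1]] += 1.0
        sA = 0.0
        sB = 0.0
        for a_ in range(n_alleles):
            pA[l, a_] *= np.random.gamma(5.0, 1.0)
            pB[l, a_] *= np.random.gamma(5.0, 1.0)
            sA += pA[l, a_]
            sB += pB[l, a_]
        for a_ in range(n_alleles):
            pA[l, a_] /= sA
            pB[l, a_] /= sB
    z = np.empty(n, np.int64)
    for i in range(n):
        z[i] = fixed[i] if fixed[i] >= 0 else np.random.randint(0, C)
    occ = np.zeros((n, C))
    n_rec = 0
    logp = np.empty(C)
    cats = np.empty(3)
    countsA = np.zeros((L, n_alleles))
    countsB = np.zeros((L, n_alleles))
    for sweep in range(sweeps):
        # (i) class given frequencies (categories marginalized per locus)
        for i in range(n):
            if fixed[i] >= 0:
                z[i] = fixed[i]
                continue
            for c in range(C):
                logp[c] = 0.0
            for l in range(L):
                a = alleles[i, l, 0]
                b = alleles[i, l, 1]
                if a < 0:
                    continue
                if a == b:
                    cats[0] = pA[l, a] * pA[l, a]
                    cats[1] = pA[l, a] * pB[l, a]
                    cats[2] = pB[l, a] * pB[l, a]
                else:
                    cats[0] = 2.0 * pA[l, a] * pA[l, b]
                    cats[1] = pA[l, a] * pB[l, b] + pA[l, b] * pB[l, a]
                    cats[2] = 2.0 * pB[l, a] * pB[l, b]
                for c in range(C):
                    lik = W[c, 0] * cats[0] + W[c, 1] * cats[1] + W[c, 2] * cats[2]
                    logp[c] += np.log(lik + 1e-300)
            mx = logp[0]
            for c in range(1, C):
                if logp[c] > mx:
                    mx = logp[c]
            psum = 0.0
            for c in range(C):
                logp[c] = np.exp(logp[c] - mx)
                psum += logp[c]
            u = np.random.random() * psum
            acc = 0.0
            cnew = C - 1
            for c in range(C):
                acc += logp[c]
                if u <= acc:
                    cnew = c
                    break
            z[i] = cnew
        # (ii) gene-copy pool origins given classes; accumulate pool counts
        for l in range(L):
            for a_ in range(n_alleles):
                countsA[l, a_] = 0.0
                countsB[l, a_] = 0.0
        for i in range(n):
            c = z[i]
            for l in range(L):
                a = alleles[i, l, 0]
                b = alleles[i, l, 1]
                if a < 0:
                    continue
                if a == b:
                    cats[0] = W[c, 0] * pA[l, a] * pA[l, a]
                    cats[1] = W[c, 1] * pA[l, a] * pB[l, a]
                    cats[2] = W[c, 2] * pB[l, a] * pB[l, a]
                else:
                    cats[0] = W[c, 0] * 2.0 * pA[l, a] * pA[l, b]
                    cats[1] = W[c, 1] * (pA[l, a] * pB[l, b] + pA[l, b] * pB[l, a])
                    cats[2] = W[c, 2] * 2.0 * pB[l, a] * pB[l, b]
                tot = cats[0] + cats[1] + cats[2]
                u = np.random.random() * tot
                if u <= cats[0]:
                    countsA[l, a] += 1.0
                    countsA[l, b] += 1.0
                elif u <= cats[0] + cats[1]:
                    if a == b:
                        countsA[l, a] += 1.0
                        countsB[l, a] += 1.0
                    else:
                        # phase: which copy came from pool A
                        wa = pA[l, a] * pB[l, b]
                        wb = pA[l, b] * pB[l, a]
                        if np.random.random() * (wa + wb) <= wa:
                            countsA[l, a] += 1.0
                            countsB[l, b] += 1.0
                        else:
                            countsA[l, b] += 1.0
                            countsB[l, a] += 1.0
                else:
                    countsB[l, a] += 1.0
                    countsB[l, b] += 1.0
        # (iii) pool frequencies given origins, Dirichlet(1 + counts)
        for l in range(L):
            sA = 0.0
            sB = 0.0
            for a_ in range(n_alleles):
                pA[l, a_] = np.random.gamma(countsA[l, a_] + 1.0, 1.0)
                pB[l, a_] = np.random.gamma(countsB[l, a_] + 1.0, 1.0)
                sA += pA[l, a_]
                sB += pB[l, a_]
            for a_ in range(n_alleles):
                pA[l, a_] /= sA
                pB[l, a_] /= sB
        if sweep >= burnin and (sweep - burnin) % thin == 0:
            for i in range(n):
                occ[i, z[i]] += 1.0
            n_rec += 1
    return occ / n_rec


@dataclass
class HybridPosterior:
    """Per-individual posterior over the six genotype frequency classes."""

    posterior: pd.DataFrame  # individuals x CLASS_NAMES
    call_threshold: float = 0.95
    seed: int = 0
    monomorphic_warning: bool = False

    def calls(self, threshold: float | None = None) -> pd.Series:
        """Max-posterior class where it clears the threshold, else 'unassigned'."""
        thr = self.call_threshold if threshold is None else threshold
        best = self.posterior.idxmax(axis=1)
        best_p = self.posterior.max(axis=1)
        return best.where(best_p >= thr, "unassigned")

    def hybrid_calls(self, threshold: float | None = None) -> pd.Series:
        """Hybrid-vs-pure call: summed hybrid-class posterior vs threshold."""
        thr = self.call_threshold if threshold is None else threshold
        hyb = self.posterior[["F1", "F2", "BC_A", "BC_B"]].sum(axis=1)
        out = pd.Series("unassigned", index=self.posterior.index)
        out[hyb >= thr] = "hybrid"
        out[hyb <= 1 - thr] = "pure"
        return out


def classify_hybrids(
    g: GenotypeMatrix,
    burnin: int = 2000,
    sweeps: int = 12000,
    thin: int = 5,
    seed: int = 0,
    pure_a: Sequence[str] | None = None,
    pure_b: Sequence[str] | None = None,
    call_threshold: float = 0.95,
) -> HybridPosterior:
    """Gibbs posterior over the six genotype frequency classes.

    ``pure_a``/``pure_b`` optionally pin named individuals to the pure
    classes, anchoring the two gene pools (and their labels).  Data
    monomorphic at every locus leave the posterior at the prior; this is
    flagged rather than raised.
    """
    if sweeps <= burnin:
        raise ValueError("sweeps must exceed burnin")
    enc, n_alleles = _encode_alleles(g)
    fixed = np.full(g.n_individuals, -1, dtype=np.int64)
    index = {ind: i for i, ind in enumerate(g.individuals)}
    for ind in pure_a or []:
        fixed[index[ind]] = CLASS_NAMES.index("Pure_A")
    for ind in pure_b or []:
        fixed[index[ind]] = CLASS_NAMES.index("Pure_B")
    monomorphic = all(
        len(np.unique(g.alleles[:, l, :][g.alleles[:, l, :] > 0])) <= 1
        for l in range(g.n_loci)
    )
    if monomorphic:
        import warnings

        warnings.warn("all loci monomorphic: posterior will mirror the class prior")
    occ = _gibbs_hybclass(
        enc, n_alleles, CLASS_CATEGORY_WEIGHTS, fixed, burnin, sweeps, thin, seed
    )
    posterior = pd.DataFrame(occ, index=g.individuals, columns=list(CLASS_NAMES))
    return HybridPosterior(posterior, call_threshold, seed, monomorphic)
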