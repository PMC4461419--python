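"""Model-based clustering of multilocus genotypes, plus the Evanno
delta-K heuristic for choosing the number of clusters.

The model is deliberately simple: no admixture, uniform prior over K
clusters, independent Dirichlet(1) priors on per-cluster allele
frequencies, and a collapsed Gibbs sampler over individual assignments.
Assignment posteriors are post-burn-in occupancy frequencies; because
cluster labels are only defined up to permutation within a run, the
pairwise co-assignment matrix is returned as the label-invariant summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from numba import njit

from .datatypes import GenotypeMatrix

__all__ = ["cluster_no_admixture", "cluster_k_range", "evanno_delta_k", "ClusterResult"]


def _encode_alleles(g: GenotypeMatrix) -> tuple[np.ndarray, int]:
    """Map allele labels to dense 0-based codes; missing -> -1."""
    A = g.alleles
    enc = np.full(A.shape, -1, dtype=np.int64)
    n_codes = 0
    for l in range(g.n_loci):
        cell = A[:, l, :]
        present = cell[:, 0] != 0
        labels = np.unique(cell[present])
        lut = {lab: i for i, lab in enumerate(labels)}
        for i in np.flatnonzero(present):
            enc[i, l, 0] = lut[cell[i, 0]]
            enc[i, l, 1] = lut[cell[i, 1]]
        n_codes = max(n_codes, len(labels))
    return enc, max(n_codes, 1)


@njit(cache=True)
def _gibbs_noadmix(alleles, K, n_alleles, burnin, sweeps, thin, seed):
    np.random.seed(seed)
    n, L, _ = alleles.shape
    counts = np.zeros((K, L, n_alleles), np.int64)
    tot = np.zeros((K, L), np.int64)
    z = np.empty(n, np.int64)
    for i in range(n):
        z[i] = np.random.randint(0, K)
        for l in range(L):
            a = alleles[i, l, 0]
            b = alleles[i, l, 1]
            if a >= 0:
                counts[z[i], l, a] += 1
                counts[z[i], l, b] += 1
                tot[z[i], l] += 2
    n_rec = max((sweeps - burnin) // thin, 1)
    zrec = np.zeros((n_rec, n), np.int64)
    logliks = np.zeros(n_rec)
    rec = 0
    logp = np.empty(K)
    for sweep in range(sweeps):
        for i in range(n):
            zi = z[i]
            for l in range(L):
                a = alleles[i, l, 0]
                b = alleles[i, l, 1]
                if a >= 0:
                    counts[zi, l, a] -= 1
                    counts[zi, l, b] -= 1
                    tot[zi, l] -= 2
            for k in range(K):
                lp = 0.0
                for l in range(L):
                    a = alleles[i, l, 0]
                    b = alleles[i, l, 1]
                    if a >= 0:
                        t = tot[k, l]
                        lp += np.log((counts[k, l, a] + 1.0) / (t + n_alleles))
                        extra = 1.0 if a == b else 0.0
                        lp += np.log((counts[k, l, b] + 1.0 + extra) / (t + 1.0 + n_alleles))
                logp[k] = lp
            mx = logp[0]
            for k in range(1, K):
                if logp[k] > mx:
                    mx = logp[k]
            psum = 0.0
            for k in range(K):
                logp[k] = np.exp(logp[k] - mx)
                psum += logp[k]
            u = np.random.random() * psum
            acc = 0.0
            knew = K - 1
            for k in range(K):
                acc += logp[k]
                if u <= acc:
                    knew = k
                    break
            z[i] = knew
            for l in range(L):
                a = alleles[i, l, 0]
                b = alleles[i, l, 1]
                if a >= 0:
                    counts[knew, l, a] += 1
                    counts[knew, l, b] += 1
                    tot[knew, l] += 2
        if sweep >= burnin and (sweep - burnin) % thin == 0 and rec < n_rec:
            for i in range(n):
                zrec[rec, i] = z[i]
            # collapsed log marginal P(X | z) under Dirichlet(1) frequencies
            ll = 0.0
            for k in range(K):
                for l in range(L):
                    s = lgamma(n_alleles) - lgamma(n_alleles + tot[k, l])
                    for a_ in range(n_alleles):
                        s += lgamma(counts[k, l, a_] + 1.0)
                    ll += s
            logliks[rec] = ll
            rec += 1
    return zrec[:rec], logliks[:rec]


@njit(cache=True)
def _coassignment(zrec):
    S, n = zrec.shape
    M = np.zeros((n, n))
    for s in range(S):
        for i in range(n):
            zi = zrec[s, i]
            for j in range(n):
                if zrec[s, j] == zi:
                    M[i, j] += 1.0
    return M / S


@dataclass
class ClusterResult:
    """Posterior summary of one clustering run."""

    K: int
    posterior: pd.DataFrame  # individuals x K occupancy frequencies
    coassignment: pd.DataFrame  # individuals x individuals, label-invariant
    mean_loglik: float
    seed: int

    def modal_assignment(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)


def cluster_no_admixture(
    g: GenotypeMatrix,
    K: int,
    burnin: int = 5000,
    sweeps: int = 20000,
    thin: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """Collapsed-Gibbs no-admixture clustering at fixed K.

    ``sweeps`` is the total chain length including ``burnin``; assignment
    states are recorded every ``thin`` post-burn-in sweeps.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > g.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    if sweeps <= burnin:
        raise ValueError("sweeps must exceed burnin")
    enc, n_alleles = _encode_alleles(g)
    if K == 1:
        post = pd.DataFrame(1.0, index=g.individuals, columns=[0])
        co = pd.DataFrame(1.0, index=g.individuals, columns=g.individuals)
        # single-cluster collapsed likelihood, for the delta-K table
        zrec, ll = _gibbs_noadmix(enc, 1, n_alleles, 0, max(thin, 1), thin, seed)
        return ClusterResult(1, post, co, float(ll.mean()), seed)
    zrec, logliks = _gibbs_noadmix(enc, K, n_alleles, burnin, sweeps, thin, seed)
    occ = np.zeros((g.n_individuals, K))
    for s in range(zrec.shape[0]):
        occ[np.arange(g.n_individuals), zrec[s]] += 1
    occ /= zrec.shape[0]
    posterior = pd.DataFrame(occ, index=g.individuals, columns=range(K))
    co = pd.DataFrame(_coassignment(zrec), index=g.individuals, columns=g.individuals)
    return ClusterResult(K, posterior, co, float(logliks.mean()), seed)


def cluster_k_range(
    g: GenotypeMatrix,
    ks: range | list[int],
    replicates: int = 5,
    burnin: int = 5000,
    sweeps: int = 20000,
    thin: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[int, int], ClusterResult]]:
    """Replicated runs over a K range; returns the log-likelihood table
    (columns K, replicate, loglik) and the per-run results."""
    rows = []
    results = {}
    rng = np.random.default_rng(seed)
    for K in ks:
        for rep in range(replicates):
            run_seed = int(rng.integers(0, 2**31 - 1))
            res = cluster_no_admixture(g, K, burnin, sweeps, thin, run_seed)
            rows.append({"K": K, "replicate": rep, "loglik": res.mean_loglik})
            results[(K, rep)] = res
    return pd.DataFrame(rows), results


def evanno_delta_k(loglik_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno et al. delta-K from replicated mean log-likelihoods.

    ``loglik_table`` needs columns ``K`` and ``loglik`` (one row per
    replicate).  delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(K); interior
    K only.  Replicate-constant likelihoods (sd = 0) yield +inf as a
    documented sentinel rather than an error.
    """
    grouped = loglik_table.groupby("K")["loglik"]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.count()
    if (counts < 2).any():
        raise ValueError("need at least 2 replicates per K")
    ks = means.index.to_numpy()
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need at least 3 consecutive K values")
    out = pd.DataFrame({"mean_loglik": means, "sd_loglik": sds})
    delta = pd.Series(np.nan, index=means.index)
    for K in ks[1:-1]:
        second_diff = abs(means[K + 1] - 2 * means[K] + means[K - 1])
        delta[K] = second_diff / sds[K] if sds[K] > 0 else np.inf
    out["delta_k"] = delta
    return out
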