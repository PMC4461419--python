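"""Diversity and differentiation statistics for codominant genotypes.

Implements the classic FSTAT-style battery: Nei's unbiased gene diversity
(H_E), rarefied allelic richness (A_R), Weir & Cockerham's variance-component
estimators of F_IS (small f) and F_ST (theta), the squared codominant
genotypic distance of Smouse & Peakall, and principal coordinate analysis
of such distance matrices.

Missing genotypes are excluded per locus everywhere; pairwise genotypic
distances are rescaled to the full locus count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeMatrix

__all__ = [
    "gene_diversity",
    "allelic_richness",
    "inbreeding_coefficient",
    "wc_fst",
    "genotypic_distance_matrix",
    "pcoa",
    "diversity_summary",
    "DiversitySummary",
    "FstResult",
    "PcoaResult",
]


def _group_arrays(g: GenotypeMatrix, groups: Sequence[str]):
    groups = np.asarray(groups)
    if groups.shape[0] != g.n_individuals:
        raise ValueError("one group label per individual required")
    labels = list(dict.fromkeys(groups.tolist()))
    return groups, labels


def _freqs_and_het(alleles_2col: np.ndarray):
    """Allele frequencies and per-allele heterozygote proportions.

    ``alleles_2col``: (n, 2) genotyped calls (no missing).  Returns
    (allele labels, freqs, het proportion per allele, n individuals).
    """
    n = alleles_2col.shape[0]
    labels = np.unique(alleles_2col)
    freqs = np.array([(alleles_2col == a).sum() for a in labels], dtype=float) / (2 * n)
    het = np.array(
        [((alleles_2col[:, 0] == a) ^ (alleles_2col[:, 1] == a)).sum() for a in labels],
        dtype=float,
    ) / n
    return labels, freqs, het, n


# ----------------------------------------------------------- diversity


def gene_diversity(g: GenotypeMatrix, groups: Sequence[str]) -> pd.DataFrame:
    """Nei's unbiased gene diversity H_E per group and locus.

    H_E = 2n/(2n-1) * (1 - sum p_a^2) with n genotyped individuals; a final
    ``multilocus`` row holds the mean over loci with data.
    """
    groups, labels = _group_arrays(g, groups)
    out = pd.DataFrame(index=g.loci + ["multilocus"], columns=labels, dtype=float)
    for lab in labels:
        sub = g.subset(groups == lab)
        if not sub.genotyped_mask().any():
            raise ValueError(f"group {lab!r} has no genotyped individuals at any locus")
        for l, locus in enumerate(g.loci):
            cell = sub.alleles[:, l, :]
            cell = cell[cell[:, 0] != MISSING]
            if cell.shape[0] < 1:
                out.loc[locus, lab] = np.nan
                continue
            n = cell.shape[0]
            _, p, _, _ = _freqs_and_het(cell)
            if n == 1:
                out.loc[locus, lab] = np.nan
                continue
            out.loc[locus, lab] = (2 * n / (2 * n - 1)) * (1 - np.sum(p**2))
        out.loc["multilocus", lab] = out.loc[g.loci, lab].mean()
    return out


def default_rarefaction_size(g: GenotypeMatrix, groups: Sequence[str]) -> int:
    """FSTAT convention: 2 x smallest per-group per-locus genotyped n."""
    groups, labels = _group_arrays(g, groups)
    smallest = np.inf
    for lab in labels:
        sub = g.subset(groups == lab)
        n_per_locus = sub.genotyped_mask().sum(axis=0)
        smallest = min(smallest, n_per_locus.min())
    return int(2 * smallest)


def allelic_richness(
    g: GenotypeMatrix, groups: Sequence[str], rarefy_to: int | None = None
) -> pd.DataFrame:
    """Rarefied allelic richness A_R per group and locus.

    Hypergeometric rarefaction to ``rarefy_to`` gene copies:
    A_R = sum_a [1 - C(N - N_a, g) / C(N, g)].  Default g is twice the
    smallest per-group, per-locus genotyped sample size.
    """
    groups, labels = _group_arrays(g, groups)
    if rarefy_to is None:
        rarefy_to = default_rarefaction_size(g, groups)
    if rarefy_to < 2:
        raise ValueError("rarefy_to must be at least 2 gene copies")
    out = pd.DataFrame(index=g.loci + ["multilocus"], columns=labels, dtype=float)

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    for lab in labels:
        sub = g.subset(groups == lab)
        for l, locus in enumerate(g.loci):
            counts = sub.allele_counts(l)
            N = sum(counts.values())
            if N < rarefy_to:
                raise ValueError(
                    f"rarefy_to={rarefy_to} exceeds {N} gene copies for "
                    f"group {lab!r} at locus {locus!r}"
                )
            ar = 0.0
            for Na in counts.values():
                if N - Na < rarefy_to:
                    ar += 1.0
                else:
                    ar += 1.0 - np.exp(log_comb(N - Na, rarefy_to) - log_comb(N, rarefy_to))
            out.loc[locus, lab] = ar
        out.loc["multilocus", lab] = out.loc[g.loci, lab].mean()
    return out


# ------------------------------------------- variance-component F-stats


def _wc_components_locus(pop_cells: list[np.ndarray]):
    """Weir & Cockerham (1984) per-allele variance components at one locus.

    ``pop_cells``: genotyped (n_i, 2) allele arrays, one per population.
    Returns arrays (a, b, c) summed nowhere (one entry per allele), or
    None when the locus is uninformative (fewer than 2 pops with data or
    mean sample size <= 1).
    """
    cells = [c for c in pop_cells if c.shape[0] > 0]
    r = len(cells)
    if r < 2:
        return None
    ns = np.array([c.shape[0] for c in cells], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    alleles = np.unique(np.concatenate([c.ravel() for c in cells]))
    P = np.array([[(c == a).sum() / (2 * c.shape[0]) for a in alleles] for c in cells])
    H = np.array(
        [[((c[:, 0] == a) ^ (c[:, 1] == a)).mean() for a in alleles] for c in cells]
    )
    pbar = (ns[:, None] * P).sum(axis=0) / (r * nbar)
    s2 = (ns[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (ns[:, None] * H).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


@dataclass
class FstResult:
    """Weir & Cockerham theta, multilocus and pairwise."""

    theta: float
    pairwise: pd.DataFrame
    per_locus: pd.Series

    def __repr__(self) -> str:
        return f"FstResult(theta={self.theta:.4f}, groups={list(self.pairwise.index)})"


def wc_fst(g: GenotypeMatrix, groups: Sequence[str]) -> FstResult:
    """Multilocus and pairwise Weir & Cockerham (1984) theta.

    The multilocus estimate is the ratio of variance components summed over
    loci and alleles; negative estimates are reported as computed.
    """
    groups, labels = _group_arrays(g, groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups for F_ST")

    def theta_for(selected: list[str]) -> tuple[float, pd.Series]:
        num = den = 0.0
        per_locus = {}
        for l, locus in enumerate(g.loci):
            cells = []
            for lab in selected:
                cell = g.alleles[groups == lab, l, :]
                cells.append(cell[cell[:, 0] != MISSING])
            comp = _wc_components_locus(cells)
            if comp is None:
                per_locus[locus] = np.nan
                continue
            a, b, c = comp
            num += a.sum()
            den += (a + b + c).sum()
            tot = (a + b + c).sum()
            per_locus[locus] = a.sum() / tot if tot > 0 else np.nan
        if den == 0:
            raise ValueError("no informative loci for F_ST among " + ", ".join(selected))
        return num / den, pd.Series(per_locus)

    theta, per_locus = theta_for(labels)
    pairwise = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    np.fill_diagonal(pairwise.values, 0.0)
    for la, lb in combinations(labels, 2):
        try:
            t, _ = theta_for([la, lb])
        except ValueError:
            warnings.warn(f"no informative loci for the pair {la!r}-{lb!r}: NaN")
            t = np.nan
        pairwise.loc[la, lb] = pairwise.loc[lb, la] = t
    return FstResult(theta, pairwise, per_locus)


def inbreeding_coefficient(g: GenotypeMatrix, groups: Sequence[str]) -> pd.Series:
    """Weir & Cockerham small-f (F_IS) per group, multilocus.

    Within a single population the 1984 components reduce to
    b = n/(n-1) * [p(1-p) - (2n-1)/(4n) * h], c = h/2 per allele, and
    f = 1 - sum(c) / sum(b + c) over loci and alleles.  Groups monomorphic
    at every locus yield NaN with a warning (undefined, not zero).
    """
    groups, labels = _group_arrays(g, groups)
    out = {}
    for lab in labels:
        sub = g.subset(groups == lab)
        sum_b = sum_c = 0.0
        informative = False
        for l in range(g.n_loci):
            cell = sub.alleles[:, l, :]
            cell = cell[cell[:, 0] != MISSING]
            n = cell.shape[0]
            if n < 2:
                continue
            labels_l, p, h, _ = _freqs_and_het(cell)
            if len(labels_l) < 2:
                continue
            informative = True
            b = (n / (n - 1)) * (p * (1 - p) - ((2 * n - 1) / (4 * n)) * h)
            c = h / 2
            sum_b += b.sum()
            sum_c += c.sum()
        if not informative or (sum_b + sum_c) == 0:
            warnings.warn(f"F_IS undefined for group {lab!r} (no polymorphic locus)")
            out[lab] = np.nan
        else:
            out[lab] = 1 - sum_c / (sum_b + sum_c)
    return pd.Series(out, name="F_IS")


@dataclass
class DiversitySummary:
    """Per-group diversity battery: H_E, A_R, F_IS (and the rarefaction g)."""

    he: pd.DataFrame
    ar: pd.DataFrame
    fis: pd.Series
    rarefy_to: int

    def table(self) -> pd.DataFrame:
        """Compact multilocus summary, one row per group."""
        return pd.DataFrame(
            {
                "H_E": self.he.loc["multilocus"],
                "A_R": self.ar.loc["multilocus"],
                "F_IS": self.fis,
            }
        )


def diversity_summary(
    g: GenotypeMatrix, groups: Sequence[str], rarefy_to: int | None = None
) -> DiversitySummary:
    if rarefy_to is None:
        rarefy_to = default_rarefaction_size(g, groups)
    return DiversitySummary(
        he=gene_diversity(g, groups),
        ar=allelic_richness(g, groups, rarefy_to),
        fis=inbreeding_coefficient(g, groups),
        rarefy_to=rarefy_to,
    )


# ------------------------------------------------- genotypic distances


def genotypic_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Squared codominant genotypic distances (Smouse & Peakall scheme).

    Per locus: identical genotypes 0; hom vs het sharing an allele 1; two
    hets sharing one allele 1; two hets sharing none 2; hom vs het sharing
    none 3; two different homozygotes 4.  Summed over loci; pairs missing
    at some loci are rescaled by n_loci / n_compared.
    """
    A = g.alleles  # (n, L, 2)
    n, L, _ = A.shape
    present = g.genotyped_mask()  # (n, L)
    a1, a2 = A[:, :, 0], A[:, :, 1]
    hom = a1 == a2

    # multiset overlap m in {0,1,2} between genotype pairs, per locus
    def eq(x, y):  # (n,L) vs (n,L) -> (n,n,L)
        return x[:, None, :] == y[None, :, :]

    m_hom_i = (eq(a1, a1).astype(np.int8) + eq(a1, a2)).astype(np.int8)  # copies of i's allele in j
    # shared count for het i: each of i's two distinct alleles present in j (capped at 1)
    in_j_1 = eq(a1, a1) | eq(a1, a2)
    in_j_2 = eq(a2, a1) | eq(a2, a2)
    m_het_i = in_j_1.astype(np.int8) + in_j_2.astype(np.int8)
    hom_i = hom[:, None, :]
    m = np.where(hom_i, np.minimum(m_hom_i, 2), m_het_i)

    hom_j = hom[None, :, :]
    d = np.empty_like(m, dtype=np.float64)
    d[m == 2] = 0.0
    d[(m == 1)] = 1.0
    both_hom = hom_i & hom_j
    one_hom = hom_i ^ hom_j
    d[(m == 0) & both_hom] = 4.0
    d[(m == 0) & one_hom] = 3.0
    d[(m == 0) & ~both_hom & ~one_hom] = 2.0
    # identical homozygotes give m==2 -> 0; hom vs het sharing -> m==1 -> 1

    both_present = present[:, None, :] & present[None, :, :]
    n_common = both_present.sum(axis=2)
    if np.any((n_common == 0) & ~np.eye(n, dtype=bool)):
        raise ValueError("some individual pair shares no genotyped locus")
    d = np.where(both_present, d, 0.0).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = d * (L / np.maximum(n_common, 1))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class PcoaResult:
    """Principal coordinates with explicit negative-eigenvalue reporting."""

    coordinates: np.ndarray  # (n, n_positive_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per positive axis, sums to 100


def pcoa(d_squared: np.ndarray) -> PcoaResult:
    """Principal coordinate analysis of a squared-distance matrix.

    Gower double-centering of -d^2/2 followed by eigendecomposition; axes
    ordered by eigenvalue.  Percent variance is relative to the sum of
    positive eigenvalues; negative eigenvalues are reported, not dropped.
    """
    D = np.asarray(d_squared, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    B = (B + B.T) / 2
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(1.0, abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    percent = 100 * vals[pos] / vals[pos].sum()
    return PcoaResult(coords, vals, percent)
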