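"""Core data containers shared across the analysis stages.

The toolkit operates on four substrates: codominant diploid multilocus
genotypes (microsatellites), aligned organellar haplotype sequences,
per-individual flowering time series, and per-individual quantitative
trait tables.  Each container is a thin, validated wrapper around numpy
or pandas objects so that downstream statistics can stay vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # allele code for missing data; real alleles are positive ints


@dataclass
class GenotypeMatrix:
    """Diploid codominant genotypes, individuals x loci.

    ``alleles`` has shape (n_individuals, n_loci, 2) with positive integer
    allele labels; both entries of a cell are 0 when the genotype is
    missing.  The pair within a cell is unordered.
    """

    alleles: np.ndarray
    individuals: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, loci, 2)")
        n, L, _ = self.alleles.shape
        if len(self.individuals) != n:
            raise ValueError("individual ids do not match allele array")
        if len(self.loci) != L:
            raise ValueError("locus ids do not match allele array")
        if np.any(self.alleles < 0):
            raise ValueError("allele labels must be positive (0 = missing)")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if np.any(half):
            raise ValueError("half-missing genotypes: each cell needs 0 or 2 calls")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def genotyped_mask(self) -> np.ndarray:
        """Boolean (n, loci) mask: True where the genotype is present."""
        return self.alleles[:, :, 0] != MISSING

    def subset(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.alleles[index],
            [self.individuals[i] for i in index],
            list(self.loci),
        )

    def allele_counts(self, locus: int) -> dict[int, int]:
        """Observed gene-copy counts per allele at one locus."""
        col = self.alleles[:, locus, :].ravel()
        col = col[col != MISSING]
        labels, counts = np.unique(col, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class HaplotypeSet:
    """Collapsed aligned haplotypes with per-individual assignment.

    ``sequences`` maps haplotype id -> aligned sequence (equal lengths,
    IUPAC DNA plus '-'); ``assignment`` maps individual id -> haplotype id.
    """

    sequences: dict[str, str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must all have the same length")
        unknown = set(self.assignment.values()) - set(self.sequences)
        if unknown:
            raise ValueError(f"assignment refers to unknown haplotypes: {unknown}")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def frequencies(self) -> dict[str, int]:
        freq = {h: 0 for h in self.sequences}
        for h in self.assignment.values():
            freq[h] += 1
        return freq

    @property
    def n_individuals(self) -> int:
        return len(self.assignment)


@dataclass
class FloweringSchedule:
    """Per-individual proportions of flowering stems across censuses.

    ``values`` is a DataFrame with individuals as rows and census dates
    (ordinal day numbers) as columns; entries lie in [0, 1].  ``lineage``
    assigns each individual a group label.
    """

    values: pd.DataFrame
    lineage: pd.Series
    source: pd.Series | None = None  # original individual behind each row
    # (set by bootstrap resampling so pairwise statistics can skip
    # self-pairs between copies of the same individual)

    def __post_init__(self) -> None:
        dates = np.asarray(self.values.columns, dtype=float)
        if np.any(np.diff(dates) <= 0):
            raise ValueError("census dates must be strictly increasing")
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError("flowering proportions must lie in [0, 1]")
        self.lineage = self.lineage.reindex(self.values.index)
        if self.lineage.isna().any():
            raise ValueError("every individual needs a lineage label")
        if self.source is None:
            self.source = pd.Series(self.values.index, index=self.values.index)

    @property
    def censuses(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    def lineage_members(self, label: str) -> list[str]:
        return list(self.lineage.index[self.lineage == label])

    def subset(self, individuals: Sequence[str]) -> "FloweringSchedule":
        # duplicates allowed (bootstrap resamples); index is made unique but
        # the source individual is remembered for self-pair exclusion
        inds = list(individuals)
        vals = self.values.loc[inds].copy()
        lin = self.lineage.loc[inds].copy()
        src = self.source.loc[inds].copy()
        new_index = [f"{ind}#{i}" for i, ind in enumerate(inds)]
        vals.index = new_index
        lin.index = new_index
        src.index = new_index
        return FloweringSchedule(vals, lin, src)


@dataclass
class TraitTable:
    """Quantitative traits, herbivory counts and habitat covariates.

    ``data`` holds one row per individual; ``group`` is the column with
    lineage labels, ``damaged``/``total`` the herbivory capsule counts.
    """

    data: pd.DataFrame
    group_col: str = "lineage"
    damaged_col: str = "damaged_capsules"
    total_col: str = "total_capsules"

    def __post_init__(self) -> None:
        if self.group_col not in self.data.columns:
            raise ValueError(f"missing group column {self.group_col!r}")
        if self.damaged_col in self.data.columns and self.total_col in self.data.columns:
            d = self.data[self.damaged_col]
            t = self.data[self.total_col]
            if (d < 0).any() or (t < 0).any() or (d > t).any():
                raise ValueError("capsule counts must satisfy 0 <= damaged <= total")

    @property
    def groups(self) -> pd.Series:
        return self.data[self.group_col]

    def trait(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass
class BootstrapCI:
    """Percentile bootstrap confidence interval."""

    lower: float
    upper: float
    level: float
    replicates: int
    seed: int | None = None
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if self.upper < self.lower:
            raise ValueError("upper CI bound below lower bound")


@dataclass
class OverlapResult:
    """A phenology statistic with optional bootstrap CI."""

    statistic: str
    value: float
    mode: str
    n_pairs: int | None = None
    n_excluded_pairs: int = 0
    ci: BootstrapCI | None = None

    def __repr__(self) -> str:  # compact, table-friendly
        s = f"{self.statistic}[{self.mode}] = {self.value:.4f}"
        if self.ci is not None:
            s += f" ({int(self.ci.level*100)}% CI {self.ci.lower:.4f}..{self.ci.upper:.4f})"
        return s
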