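import numpy as np
import pandas as pd
import pytest

from cryptolin.datatypes import FloweringSchedule, GenotypeMatrix


def gm(rows, loci=None, ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from [[(a, b), ...], ...] genotype rows."""
    arr = np.array(rows, dtype=np.int64)
    n, L = arr.shape[0], arr.shape[1]
    return GenotypeMatrix(
        arr,
        ids or [f"ind{i}" for i in range(n)],
        loci or [f"loc{j}" for j in range(L)],
    )


def schedule(values, lineages, dates=None) -> FloweringSchedule:
    """Build a FloweringSchedule from a {ind: series} dict and labels."""
    dates = dates if dates is not None else list(range(1, len(next(iter(values.values()))) + 1))
    df = pd.DataFrame.from_dict(values, orient="index", columns=[float(d) for d in dates])
    return FloweringSchedule(df, pd.Series(lineages))


@pytest.fixture(scope="session")
def default_dataset():
    """One study-calibration synthetic dataset shared across tests."""
    from cryptolin import synthgen

    return synthgen.simulate_dataset(synthgen.SimulationConfig(seed=0))


def random_genotype_instance(rng, max_pops=3, max_inds=6, max_loci=2, n_alleles=3):
    """Random small multi-population genotype instance for oracle checks.

    Returns (GenotypeMatrix, group labels, per-locus per-pop genotype
    tuples for the oracle).
    """
    n_pops = rng.integers(2, max_pops + 1)
    n_loci = rng.integers(1, max_loci + 1)
    rows, groups = [], []
    for p in range(n_pops):
        n_ind = rng.integers(2, max_inds + 1)
        for _ in range(n_ind):
            row = []
            for _ in range(n_loci):
                if rng.random() < 0.05:
                    row.append((0, 0))  # missing
                else:
                    row.append(
                        (int(rng.integers(1, n_alleles + 1)), int(rng.integers(1, n_alleles + 1)))
                    )
            rows.append(row)
            groups.append(f"pop{p}")
    g = gm(rows)
    loci_oracle = []
    for l in range(n_loci):
        locus = []
        for p in range(n_pops):
            locus.append(
                [tuple(map(int, g.alleles[i, l])) for i in range(len(rows)) if groups[i] == f"pop{p}"]
            )
        loci_oracle.append(locus)
    return g, np.array(groups), loci_oracle
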