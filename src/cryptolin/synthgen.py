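"""Synthetic study systems with the statistical structure the analyses assume.

The generator emulates a three-lineage system of highly selfing rushes —
two cryptic conspecific lineages plus a close congener — sampled at one
site: microsatellite genotypes with calibrated pairwise differentiation
and strong homozygote excess, a small percentage of hybrids of known
genotype frequency class, maternally inherited organellar haplotypes with
a fixed sharing pattern, per-individual flowering-proportion time series
with lineage-specific onset and duration, and quantitative traits with
lineage means, overdispersed seed-predation counts and lineage-independent
soil moisture.

Differentiation is produced by the F-model: lineage allele frequencies are
drawn from Dirichlet(p_anc * (1 - d)/d) around ancestral frequencies,
where d is a per-lineage drift parameter.  The expected pairwise
Weir–Cockerham theta between two lineages is, to first order, the mean of
their drift parameters, so the calibration for a pairwise target matrix T
solves the linear system d_k + d_l = 2 T_kl.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import FloweringSchedule, GenotypeMatrix, HaplotypeSet, TraitTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "calibrate_drift",
    "generate_genotypes",
    "generate_hybrid_genotypes",
    "generate_haplotype_sequences",
    "generate_flowering_schedule",
    "generate_trait_table",
    "simulate_dataset",
]

HYBRID_CLASSES = ("F1", "F2", "BC_A", "BC_B")

_DEFAULT_FST = (
    (0.0, 0.57, 0.57),
    (0.57, 0.0, 0.72),
    (0.57, 0.72, 0.0),
)

# mutation tree on the reference haplotype: (parent, child, steps).  The
# congener pool {h1,h2,h3} is tight (1-2 steps), the eff1 clade {h4..h7}
# sits 3 steps away behind h4, so every eff1-vs-rest pair is 3-6 steps.
_DEFAULT_HAPLOTYPE_TREE = (
    ("h3", "h1", 1),
    ("h1", "h2", 1),
    ("h3", "h4", 3),
    ("h4", "h5", 1),
    ("h4", "h6", 1),
    ("h4", "h7", 1),
)

_DEFAULT_HAPLOTYPE_POOLS = {
    "cong": {"h1": 0.35, "h2": 0.25, "h3": 0.40},
    "eff1": {"h4": 0.45, "h5": 0.20, "h6": 0.20, "h7": 0.15},
    "eff2": {"h3": 1.0},
}

_DEFAULT_TRAIT_MEANS = {
    # trait: (cong, eff1, eff2); eff1 mostly intermediate, ridge count and
    # relative cataphyll length separating the congener, spathe length and
    # flower density separating the two cryptic lineages
    "stem_height_mm": (850.0, 950.0, 1000.0),
    "spathe_length_mm": (120.0, 160.0, 200.0),
    "cataphyll_length_mm": (90.0, 70.0, 95.0),
    "ridge_count": (55.0, 32.0, 30.0),
    "log_inflorescence_volume": (6.2, 6.8, 7.4),
    "log_flower_density": (1.8, 1.2, 0.7),
    "seed_length_um": (520.0, 540.0, 560.0),
    "seed_width_um": (260.0, 262.0, 264.0),
}

_DEFAULT_TRAIT_SDS = {
    "stem_height_mm": 120.0,
    "spathe_length_mm": 40.0,
    "cataphyll_length_mm": 15.0,
    "ridge_count": 4.0,
    "log_inflorescence_volume": 0.5,
    "log_flower_density": 0.4,
    "seed_length_um": 30.0,
    "seed_width_um": 20.0,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system (defaults = study scale)."""

    lineage_names: tuple[str, ...] = ("cong", "eff1", "eff2")
    n_individuals_per_lineage: tuple[int, ...] = (110, 110, 110)
    n_loci: int = 11
    alleles_per_locus: int = 6
    target_fst: tuple = _DEFAULT_FST
    selfing_f: float = 0.9
    hybrid_fraction: float = 0.07
    hybrid_pair_weights: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("cong", "eff1"): 0.68,
            ("eff1", "eff2"): 0.24,
            ("cong", "eff2"): 0.08,
        }
    )
    hybrid_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"F1": 0.30, "F2": 0.35, "BC_A": 0.175, "BC_B": 0.175}
    )
    maternal_bias: Mapping[str, float] | None = None  # lineage -> relative weight
    haplotype_tree: tuple = _DEFAULT_HAPLOTYPE_TREE
    haplotype_pools: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_HAPLOTYPE_POOLS.items()}
    )
    sequence_length: int = 500
    census_dates: tuple[float, ...] = tuple(float(d) for d in range(148, 200, 3))
    season_start_day: float = 151.0
    flowering_offsets_days: tuple[float, ...] = (0.0, 7.0, 19.0)
    flowering_duration_days: tuple[float, ...] = (17.0, 21.0, 18.0)
    flowering_jitter_sd: float = 3.0
    flowering_peak: float = 0.9
    trait_means: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_TRAIT_MEANS)
    )
    trait_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TRAIT_SDS))
    trait_cov: np.ndarray | None = None  # optional shared covariance across traits
    herbivory_means: tuple[float, ...] = (0.19, 0.17, 0.04)
    herbivory_dispersion: float = 0.08  # beta-binomial rho
    capsule_count_mean: float = 60.0
    soil_moisture_range: tuple[float, float] = (0.07, 0.29)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.lineage_names)
        if len(self.n_individuals_per_lineage) != k:
            raise ValueError("one sample size per lineage required")
        T = np.asarray(self.target_fst, dtype=float)
        if T.shape != (k, k) or not np.allclose(T, T.T) or np.any(np.diag(T) != 0):
            raise ValueError("target_fst must be symmetric with zero diagonal")
        if np.any(T < 0) or np.any(T >= 1):
            raise ValueError("target_fst entries must lie in [0, 1)")
        for name, x in (
            ("selfing_f", self.selfing_f),
            ("hybrid_fraction", self.hybrid_fraction),
            ("flowering_peak", self.flowering_peak),
            ("herbivory_dispersion", self.herbivory_dispersion),
        ):
            if not 0 <= x <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(np.array(self.herbivory_means) < 0) or np.any(
            np.array(self.herbivory_means) > 1
        ):
            raise ValueError("herbivory means are proportions")
        dates = np.asarray(self.census_dates, dtype=float)
        if np.any(np.diff(dates) <= 0):
            raise ValueError("census_dates must be strictly increasing")
        if np.any(np.asarray(self.flowering_duration_days) <= 0):
            raise ValueError("flowering durations must be positive")
        if self.alleles_per_locus < 2:
            raise ValueError("need at least 2 alleles per locus")
        lo, hi = self.soil_moisture_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("soil_moisture_range must be an interval inside [0, 1]")

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_names)

    def lineage_index(self, name: str) -> int:
        return self.lineage_names.index(name)


def calibrate_drift(target_fst: np.ndarray) -> np.ndarray:
    """Per-lineage F-model drift parameters hitting a pairwise theta target.

    Solves d_k + d_l = 2 T_kl in the least-squares sense (exact for three
    lineages).  Raises when the target is unattainable, i.e. when any
    solved drift parameter leaves (0, 1).
    """
    T = np.asarray(target_fst, dtype=float)
    k = T.shape[0]
    rows, rhs = [], []
    for a in range(k):
        for b in range(a + 1, k):
            row = np.zeros(k)
            row[a] = row[b] = 1.0
            rows.append(row)
            rhs.append(2 * T[a, b])
    d, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    if np.any(d <= 0) or np.any(d >= 1):
        raise ValueError(
            f"target F_ST matrix is unattainable under the F-model (drift={d})"
        )
    return d


def parametric_theta(pk: np.ndarray, pl: np.ndarray) -> float:
    """Infinite-sample Weir–Cockerham theta between two known frequency sets.

    With equal, large samples the 1984 variance components reduce to
    a = sum Delta^2/2 and a+b+c = sum (Delta^2/4 + pbar(1-pbar)) over loci
    and alleles (the heterozygosity terms cancel), with Delta = pk - pl.
    """
    delta2 = (pk - pl) ** 2
    pbar = (pk + pl) / 2
    num = (delta2 / 2).sum()
    den = (delta2 / 4 + pbar * (1 - pbar)).sum()
    return float(num / den) if den > 0 else np.nan


def _tune_lineage_freqs(
    ancestral: np.ndarray, raw: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Shrink drawn lineage frequencies toward the ancestor so the realized
    (parametric) pairwise theta matches the target matrix.

    Each lineage k gets one scale factor s_k in (0, s_max]; adjusted
    frequencies are p_anc + s_k (p_k - p_anc), which stay on the simplex
    for s_k <= 1.  The raw draws use inflated drift so the solution is
    almost always a shrink.
    """
    from scipy.optimize import least_squares

    K = raw.shape[0]
    dev = raw - ancestral[None]
    s_max = np.ones(K)
    for k in range(K):
        push = dev[k] < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            lim = np.where(push, ancestral[None][0] / np.maximum(-dev[k], 1e-12), np.inf)
        s_max[k] = min(float(np.min(lim)), 4.0)

    pairs = [(a, b) for a in range(K) for b in range(a + 1, K)]

    def residuals(s):
        adj = ancestral[None] + s[:, None, None] * dev
        return np.array(
            [parametric_theta(adj[a], adj[b]) - target[a, b] for a, b in pairs]
        )

    sol = least_squares(
        residuals, x0=np.full(K, 0.8), bounds=(np.full(K, 0.05), s_max), xtol=1e-12
    )
    adj = ancestral[None] + sol.x[:, None, None] * dev
    adj = np.clip(adj, 1e-9, None)
    return adj / adj.sum(axis=2, keepdims=True)


def _draw_genotypes(freqs: np.ndarray, n: int, selfing_f: float, rng) -> np.ndarray:
    """Genotypes with homozygote excess P(aa) = p^2 + F p (1 - p)."""
    L, A = freqs.shape
    out = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        first = rng.choice(A, size=n, p=freqs[l])
        ibd = rng.random(n) < selfing_f
        second = np.where(ibd, first, rng.choice(A, size=n, p=freqs[l]))
        out[:, l, 0] = first + 1
        out[:, l, 1] = second + 1
    return out


def generate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Pure-lineage genotypes.

    Returns (genotypes, lineage labels, lineage allele frequencies of
    shape (n_lineages, n_loci, n_alleles)).  Ancestral frequencies are
    Dirichlet(1) per locus; lineage frequencies follow the F-model with
    drift calibrated to ``config.target_fst``; genotypes have homozygote
    excess governed by ``config.selfing_f``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d = calibrate_drift(config.target_fst)
    # overdraw drift, then shrink toward the ancestor to hit the realized
    # (parametric) pairwise theta exactly; shrinking keeps the simplex
    d_draw = np.clip(d * 1.3, None, 0.98)
    L, A = config.n_loci, config.alleles_per_locus
    ancestral = rng.dirichlet(np.ones(A), size=L)
    raw = np.empty((config.n_lineages, L, A))
    for k in range(config.n_lineages):
        conc = ancestral * (1 - d_draw[k]) / d_draw[k]
        for l in range(L):
            raw[k, l] = rng.dirichlet(np.maximum(conc[l], 1e-6))
    lineage_freqs = _tune_lineage_freqs(ancestral, raw, np.asarray(config.target_fst, dtype=float))
    blocks, labels, ids = [], [], []
    for k, name in enumerate(config.lineage_names):
        n = config.n_individuals_per_lineage[k]
        blocks.append(_draw_genotypes(lineage_freqs[k], n, config.selfing_f, rng))
        labels.extend([name] * n)
        ids.extend([f"{name}_{i + 1:03d}" for i in range(n)])
    g = GenotypeMatrix(
        np.concatenate(blocks), ids, [f"loc{j + 1:02d}" for j in range(L)]
    )
    return g, np.array(labels), lineage_freqs


def _gamete(freqs_by_pool: tuple[np.ndarray, np.ndarray], origins: np.ndarray, rng):
    """One gamete: per locus an allele drawn from the pool given by origins."""
    L = freqs_by_pool[0].shape[0]
    out = np.empty(L, dtype=np.int64)
    for l in range(L):
        out[l] = rng.choice(freqs_by_pool[origins[l]].shape[1], p=freqs_by_pool[origins[l]][l])
    return out + 1


def generate_hybrid_genotypes(
    parent_freqs_a: np.ndarray,
    parent_freqs_b: np.ndarray,
    hybrid_class: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hybrid genotypes by explicit gamete sampling; shape (n, L, 2).

    F1: one gamete from each pool.  F2: two gametes from simulated F1s
    (each locus from pool A or B with probability 1/2, independently).
    BC_A/BC_B: one F1 gamete plus one parental gamete.
    """
    if hybrid_class not in HYBRID_CLASSES:
        raise ValueError(f"unknown hybrid class {hybrid_class!r}")
    pools = (parent_freqs_a, parent_freqs_b)
    L = parent_freqs_a.shape[0]
    out = np.empty((n, L, 2), dtype=np.int64)
    zeros = np.zeros(L, dtype=np.int64)
    ones = np.ones(L, dtype=np.int64)
    for i in range(n):
        def f1_gamete():
            return _gamete(pools, (rng.random(L) < 0.5).astype(np.int64), rng)

        if hybrid_class == "F1":
            g1, g2 = _gamete(pools, zeros, rng), _gamete(pools, ones, rng)
        elif hybrid_class == "F2":
            g1, g2 = f1_gamete(), f1_gamete()
        elif hybrid_class == "BC_A":
            g1, g2 = f1_gamete(), _gamete(pools, zeros, rng)
        else:  # BC_B
            g1, g2 = f1_gamete(), _gamete(pools, ones, rng)
        out[i, :, 0] = g1
        out[i, :, 1] = g2
    return out


def _build_haplotype_sequences(config: SimulationConfig, rng) -> dict[str, str]:
    """Sequences realizing the mutation tree's exact step distances."""
    total_steps = sum(s for _, _, s in config.haplotype_tree)
    if total_steps > config.sequence_length:
        raise ValueError(
            f"haplotype tree needs {total_steps} mutated sites but sequences "
            f"have only {config.sequence_length}"
        )
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=config.sequence_length)
    positions = rng.permutation(config.sequence_length)[:total_steps]
    root = config.haplotype_tree[0][0]
    seqs = {root: ref.copy()}
    pos_iter = iter(positions)
    for parent, child, steps in config.haplotype_tree:
        if parent not in seqs:
            raise ValueError(f"haplotype tree edge from unknown node {parent!r}")
        seq = seqs[parent].copy()
        for _ in range(steps):
            p = next(pos_iter)
            current = seq[p]
            seq[p] = rng.choice([b for b in "ACGT" if b != current])
        seqs[child] = seq
    return {h: "".join(s) for h, s in seqs.items()}


def generate_haplotype_sequences(
    config: SimulationConfig,
    maternal_lineage: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> HaplotypeSet:
    """Aligned haplotype sequences plus maternal per-individual assignment.

    ``maternal_lineage`` maps individual id -> maternal lineage; each
    individual inherits a haplotype drawn from that lineage's pool.  When
    omitted, one individual per pool haplotype is emitted (the bare
    haplotype inventory).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    seqs = _build_haplotype_sequences(config, rng)
    if maternal_lineage is None:
        assignment = {f"ref_{h}": h for h in seqs}
        return HaplotypeSet(seqs, assignment)
    assignment = {}
    for ind, lin in maternal_lineage.items():
        pool = config.haplotype_pools[lin]
        haps = list(pool)
        probs = np.array([pool[h] for h in haps], dtype=float)
        probs = probs / probs.sum()
        assignment[ind] = haps[rng.choice(len(haps), p=probs)]
    used = set(assignment.values())
    sequences = {h: s for h, s in seqs.items() if h in used or maternal_lineage is None}
    return HaplotypeSet(sequences, assignment)


def generate_flowering_schedule(
    config: SimulationConfig,
    lineage_of: Mapping[str, str] | None = None,
    offsets_of: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> FloweringSchedule:
    """Per-individual flowering-proportion series at the census dates.

    Each individual flowers along a truncated Gaussian curve: onset =
    season start + lineage offset + N(0, jitter), peak at onset +
    duration/2, sd = duration/4, scaled to ``flowering_peak`` and zero
    outside [onset, onset + duration].
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if lineage_of is None:
        lineage_of = {}
        for k, name in enumerate(config.lineage_names):
            for i in range(config.n_individuals_per_lineage[k]):
                lineage_of[f"{name}_{i + 1:03d}"] = name
    dates = np.asarray(config.census_dates, dtype=float)
    offsets = dict(zip(config.lineage_names, config.flowering_offsets_days))
    durations = dict(zip(config.lineage_names, config.flowering_duration_days))
    rows = {}
    lineages = {}
    for ind, lin in lineage_of.items():
        if offsets_of is not None and ind in offsets_of:
            offset = offsets_of[ind]
            duration = float(np.mean(list(durations.values())))
        else:
            offset = offsets[lin]
            duration = durations[lin]
        onset = config.season_start_day + offset + rng.normal(0, config.flowering_jitter_sd)
        mu = onset + duration / 2
        sigma = duration / 4
        v = config.flowering_peak * np.exp(-((dates - mu) ** 2) / (2 * sigma**2))
        v[(dates < onset) | (dates > onset + duration)] = 0.0
        rows[ind] = v
        lineages[ind] = lin
    values = pd.DataFrame.from_dict(rows, orient="index", columns=dates)
    return FloweringSchedule(values, pd.Series(lineages))


def generate_trait_table(
    config: SimulationConfig,
    lineage_of: Mapping[str, str],
    trait_mix: Mapping[str, tuple[str, str]] | None = None,
    rng: np.random.Generator | None = None,
) -> TraitTable:
    """Quantitative traits, herbivory counts and soil moisture.

    Pure individuals draw multivariate-normal traits around their lineage
    means; hybrids (listed in ``trait_mix`` as individual -> parental
    pair) use the midpoint of the parental means.  Herbivory is
    beta-binomial damaged-capsule counts; soil moisture is uniform on the
    configured range, independent of lineage.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    traits = list(config.trait_means)
    k_of = {name: k for k, name in enumerate(config.lineage_names)}
    means_matrix = np.array([config.trait_means[t] for t in traits])  # traits x lineages
    if config.trait_cov is not None:
        cov = np.asarray(config.trait_cov, dtype=float)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError("trait covariance matrix is not positive definite")
    else:
        sds = np.array([config.trait_sds[t] for t in traits])
        cov = np.diag(sds**2)
    offsets = dict(zip(config.lineage_names, config.flowering_offsets_days))
    herb = dict(zip(config.lineage_names, config.herbivory_means))
    rho = config.herbivory_dispersion
    records = {}
    for ind, lin in lineage_of.items():
        if trait_mix is not None and ind in trait_mix:
            pa, pb = trait_mix[ind]
            mu = (means_matrix[:, k_of[pa]] + means_matrix[:, k_of[pb]]) / 2
            ff_mean = config.season_start_day + (offsets[pa] + offsets[pb]) / 2
            h_mean = (herb[pa] + herb[pb]) / 2
        else:
            mu = means_matrix[:, k_of[lin]]
            ff_mean = config.season_start_day + offsets[lin]
            h_mean = herb[lin]
        vals = rng.multivariate_normal(mu, cov)
        rec = dict(zip(traits, vals))
        rec["first_flowering"] = ff_mean + rng.normal(0, config.flowering_jitter_sd)
        total = max(int(rng.poisson(config.capsule_count_mean)), 1)
        if rho > 0 and 0 < h_mean < 1:
            a = h_mean * (1 - rho) / rho
            b = (1 - h_mean) * (1 - rho) / rho
            p = rng.beta(a, b)
        else:
            p = h_mean
        rec["damaged_capsules"] = int(rng.binomial(total, p))
        rec["total_capsules"] = total
        rec["soil_moisture"] = rng.uniform(*config.soil_moisture_range)
        rec["lineage"] = lin
        records[ind] = rec
    df = pd.DataFrame.from_dict(records, orient="index")
    return TraitTable(df)


@dataclass
class SyntheticDataset:
    """A complete simulated study system with ground-truth labels."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    labels: pd.Series  # lineage name for pure individuals, 'hybrid' otherwise
    truth: pd.DataFrame  # kind, lineage/pair, class, maternal lineage
    lineage_freqs: np.ndarray
    haplotypes: HaplotypeSet
    schedule: FloweringSchedule
    traits: TraitTable

    def pure_mask(self) -> np.ndarray:
        return (self.truth["kind"] == "pure").to_numpy()


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Simulate the full study system from one seeded configuration.

    Hybrid count = round(h/(1-h) * n_pure) so that hybrids make up
    ``hybrid_fraction`` of the final sample.  Hybrid maternal parents are
    drawn uniformly from the pair unless ``maternal_bias`` weights them.
    """
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    g_pure, labels_pure, lineage_freqs = generate_genotypes(config, rng)
    n_pure = g_pure.n_individuals
    h = config.hybrid_fraction
    n_hyb = int(round(h / (1 - h) * n_pure)) if h > 0 else 0

    pair_items = list(config.hybrid_pair_weights.items())
    pair_probs = np.array([w for _, w in pair_items], dtype=float)
    pair_probs = pair_probs / pair_probs.sum()
    class_items = list(config.hybrid_class_weights.items())
    class_probs = np.array([w for _, w in class_items], dtype=float)
    class_probs = class_probs / class_probs.sum()

    hyb_blocks, hyb_ids = [], []
    truth_rows = [
        {"kind": "pure", "lineage": lab, "hybrid_class": "", "pair": "", "maternal": lab}
        for lab in labels_pure
    ]
    for i in range(n_hyb):
        pair = pair_items[rng.choice(len(pair_items), p=pair_probs)][0]
        cls = class_items[rng.choice(len(class_items), p=class_probs)][0]
        ka, kb = config.lineage_index(pair[0]), config.lineage_index(pair[1])
        geno = generate_hybrid_genotypes(
            lineage_freqs[ka], lineage_freqs[kb], cls, 1, rng
        )
        if config.maternal_bias:
            wa = config.maternal_bias.get(pair[0], 1.0)
            wb = config.maternal_bias.get(pair[1], 1.0)
            maternal = pair[0] if rng.random() < wa / (wa + wb) else pair[1]
        else:
            maternal = pair[rng.integers(0, 2)]
        hyb_blocks.append(geno)
        hyb_ids.append(f"hyb_{i + 1:03d}")
        truth_rows.append(
            {
                "kind": "hybrid",
                "lineage": "hybrid",
                "hybrid_class": cls,
                "pair": f"{pair[0]}x{pair[1]}",
                "maternal": maternal,
            }
        )
    if n_hyb:
        alleles = np.concatenate([g_pure.alleles] + hyb_blocks)
        ids = g_pure.individuals + hyb_ids
    else:
        alleles = g_pure.alleles
        ids = g_pure.individuals
    genotypes = GenotypeMatrix(alleles, ids, g_pure.loci)
    truth = pd.DataFrame(truth_rows, index=ids)
    labels = truth["lineage"].rename("label")

    maternal_of = dict(truth["maternal"])
    haplotypes = generate_haplotype_sequences(config, maternal_of, rng)

    offsets = dict(zip(config.lineage_names, config.flowering_offsets_days))
    offsets_of: dict[str, float] = {}
    trait_mix: dict[str, tuple[str, str]] = {}
    for ind in ids:
        row = truth.loc[ind]
        if row["kind"] == "hybrid":
            pa, pb = row["pair"].split("x")
            offsets_of[ind] = (offsets[pa] + offsets[pb]) / 2
            trait_mix[ind] = (pa, pb)
    schedule = _hybrid_aware_schedule(config, truth, ids, offsets_of, rng)
    traits = generate_trait_table(
        config,
        {ind: (truth.loc[ind, "lineage"] if truth.loc[ind, "kind"] == "pure" else
               truth.loc[ind, "pair"].split("x")[0]) for ind in ids},
        trait_mix=trait_mix,
        rng=rng,
    )
    traits.data["lineage"] = labels
    return SyntheticDataset(
        config=config,
        genotypes=genotypes,
        labels=labels,
        truth=truth,
        lineage_freqs=lineage_freqs,
        haplotypes=haplotypes,
        schedule=schedule,
        traits=traits,
    )


def _hybrid_aware_schedule(config, truth, ids, offsets_of, rng) -> FloweringSchedule:
    lineage_of = {}
    for ind in ids:
        row = truth.loc[ind]
        lineage_of[ind] = row["lineage"] if row["kind"] == "pure" else "hybrid"
    # build series: pure from lineage parameters, hybrids from midpoint offsets
    dates = np.asarray(config.census_dates, dtype=float)
    offsets = dict(zip(config.lineage_names, config.flowering_offsets_days))
    durations = dict(zip(config.lineage_names, config.flowering_duration_days))
    mean_duration = float(np.mean(list(durations.values())))
    rows = {}
    for ind in ids:
        lin = lineage_of[ind]
        if lin == "hybrid":
            offset = offsets_of[ind]
            duration = mean_duration
        else:
            offset = offsets[lin]
            duration = durations[lin]
        onset = config.season_start_day + offset + rng.normal(0, config.flowering_jitter_sd)
        mu = onset + duration / 2
        sigma = duration / 4
        v = config.flowering_peak * np.exp(-((dates - mu) ** 2) / (2 * sigma**2))
        v[(dates < onset) | (dates > onset + duration)] = 0.0
        rows[ind] = v
    values = pd.DataFrame.from_dict(rows, orient="index", columns=dates)
    return FloweringSchedule(values, pd.Series(lineage_of))
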