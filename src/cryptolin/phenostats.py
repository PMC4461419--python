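"""Flowering-phenology statistics: among-individual synchrony, the
lineage-specific probability of hybrid formation under random mating, and
stratified bootstrap confidence intervals.

Synchrony (mean r) is the mean Pearson correlation of per-individual
flowering-proportion series over pairwise individual comparisons, taken
within lineages, between lineages, or over all pairs.  The probability of
hybrid formation weights, per census, the chance that a pollen donor
belongs to the other lineage by the focal lineage's share of its own
flowering effort on that census, and sums over censuses.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import BootstrapCI, FloweringSchedule, OverlapResult

__all__ = [
    "flowering_synchrony",
    "hybrid_formation_probability",
    "bootstrap_ci",
]

SYNCHRONY_MODES = ("within", "between", "overall")


def _pair_mask(s: FloweringSchedule, mode: str, lineage: str | None) -> np.ndarray:
    """Upper-triangular boolean mask of the pairs the mode selects.

    Self-pairs between bootstrap copies of the same source individual are
    always excluded.
    """
    lin = s.lineage.to_numpy()
    src = s.source.to_numpy()
    n = len(lin)
    mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    mask &= src[:, None] != src[None, :]
    if mode == "within":
        if lineage is None:
            raise ValueError("mode='within' requires a lineage label")
        member = lin == lineage
        mask &= member[:, None] & member[None, :]
    elif mode == "between":
        mask &= lin[:, None] != lin[None, :]
    elif mode != "overall":
        raise ValueError(f"unknown mode {mode!r}; choose from {SYNCHRONY_MODES}")
    return mask


def mean_pairwise_r(
    s: FloweringSchedule, mode: str = "overall", lineage: str | None = None
) -> tuple[float, int, int]:
    """Mean pairwise Pearson r; returns (mean r, n pairs used, n excluded).

    Pairs where either series has zero variance are excluded and counted.
    """
    V = s.values.to_numpy(dtype=float)
    if V.shape[1] < 3:
        raise ValueError("need at least 3 censuses")
    sd = V.std(axis=1)
    usable = sd > 1e-12  # proportions are O(1); treat tiny sd as constant
    mask = _pair_mask(s, mode, lineage)
    kept = mask & usable[:, None] & usable[None, :]
    n_pairs = int(kept.sum())
    n_excluded = int(mask.sum()) - n_pairs
    if n_pairs < 1:
        raise ValueError("fewer than one usable pair of individuals")
    Z = (V - V.mean(axis=1, keepdims=True)) / np.where(usable, sd, 1.0)[:, None]
    R = Z @ Z.T / V.shape[1]
    r = float(R[kept].mean())
    return r, n_pairs, n_excluded


def flowering_synchrony(
    s: FloweringSchedule,
    mode: str = "overall",
    lineage: str | None = None,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> OverlapResult:
    """Among-individual flowering synchrony (mean r), optionally with a
    stratified percentile-bootstrap CI."""
    r, n_pairs, n_excluded = mean_pairwise_r(s, mode, lineage)
    ci = None
    if n_boot > 0:
        ci = bootstrap_ci(
            lambda sub: mean_pairwise_r(sub, mode, lineage)[0],
            s,
            replicates=n_boot,
            level=level,
            seed=seed,
        )
    name = mode if lineage is None else f"{mode}:{lineage}"
    return OverlapResult("mean_r", r, name, n_pairs, n_excluded, ci)


def _mean_flowering_by_census(s: FloweringSchedule, lineage: str) -> np.ndarray:
    members = s.lineage == lineage
    if not members.any():
        raise ValueError(f"lineage {lineage!r} not present in the schedule")
    return s.values.loc[members.to_numpy()].to_numpy(dtype=float).mean(axis=0)


def hybrid_formation_probability(
    s: FloweringSchedule,
    lineage_i: str,
    lineage_j: str,
    N_i: int,
    N_j: int,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
    strategy: str = "frequency_weighted",
) -> dict[str, OverlapResult]:
    """Lineage-specific probability of hybrid formation, both directions.

    Under random mating the per-census probability that lineage i mates
    with lineage j is the frequency-weighted share of j's flowering,
    m_ij(n) = xbar_j(n) N_j / (xbar_i(n) N_i + xbar_j(n) N_j) (0 when the
    denominator is 0), with xbar the mean flowering proportion over the
    lineage's individuals and N the absolute census population sizes.
    P_i = sum_n [xbar_i(n) / sum_m xbar_i(m)] * m_ij(n).
    """
    if strategy != "frequency_weighted":
        raise ValueError(f"unknown mating-probability strategy {strategy!r}")
    if N_i <= 0 or N_j <= 0:
        raise ValueError("lineage population sizes must be positive")

    def p_one(sub: FloweringSchedule, a: str, b: str, Na: int, Nb: int) -> float:
        xa = _mean_flowering_by_census(sub, a)
        xb = _mean_flowering_by_census(sub, b)
        total = xa.sum()
        if total == 0:
            warnings.warn(f"lineage {a!r} never flowers: P undefined")
            return np.nan
        denom = xa * Na + xb * Nb
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(denom > 0, xb * Nb / np.where(denom > 0, denom, 1.0), 0.0)
        return float(np.sum(xa / total * m))

    out = {}
    for a, b, Na, Nb in ((lineage_i, lineage_j, N_i, N_j), (lineage_j, lineage_i, N_j, N_i)):
        value = p_one(s, a, b, Na, Nb)
        ci = None
        if n_boot > 0 and np.isfinite(value):
            ci = bootstrap_ci(
                lambda sub: p_one(sub, a, b, Na, Nb),
                s,
                replicates=n_boot,
                level=level,
                seed=seed,
            )
        out[a] = OverlapResult("P_hybrid_formation", value, f"{a}->{b}", ci=ci)
    return out


def bootstrap_ci(
    statistic: Callable[[FloweringSchedule], float],
    s: FloweringSchedule,
    replicates: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapCI:
    """Percentile bootstrap CI, resampling individuals within lineages.

    Resamples on which the statistic is undefined (NaN or an error) are
    redrawn; the number of redraws is reported on the interval.
    """
    if replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    lin = s.lineage.to_numpy()
    src = s.source.to_numpy()
    vals_arr = s.values.to_numpy(dtype=float)
    cols = s.values.columns
    strata = [np.flatnonzero(lin == lab) for lab in pd.unique(lin)]

    def take(pick: np.ndarray) -> FloweringSchedule:
        idx = pd.RangeIndex(len(pick))
        return FloweringSchedule(
            pd.DataFrame(vals_arr[pick], index=idx, columns=cols),
            pd.Series(lin[pick], index=idx),
            pd.Series(src[pick], index=idx),
        )

    values = np.empty(replicates)
    n_redrawn = 0
    for r in range(replicates):
        while True:
            pick = np.concatenate([rng.choice(st, size=len(st), replace=True) for st in strata])
            sub = take(pick)
            try:
                v = statistic(sub)
            except ValueError:
                v = np.nan
            if np.isfinite(v):
                values[r] = v
                break
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise ValueError("statistic undefined on too many bootstrap resamples")
        continue
    alpha = (1 - level) / 2
    lo, hi = np.quantile(values, [alpha, 1 - alpha])
    return BootstrapCI(float(lo), float(hi), level, replicates, seed, n_redrawn)
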