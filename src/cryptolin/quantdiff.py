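"""Quantitative-trait divergence analyses.

One-way ANOVA with method-of-moments variance components and Tukey HSD
contrasts (compact letter display), correlation-matrix trait PCA, linear
discriminant analysis with diagnostic-trait correlations, an
overdispersed (quasi-)binomial GLM for proportion data such as damaged
capsules or germination, and the P_ST statistic

    P_ST = (c/h^2) sigma2_B / [ (c/h^2) sigma2_B + 2 sigma2_W ]

the phenotypic analogue of Q_ST, with c the share of between-group
variance that is additive and h^2 the heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import TraitTable

__all__ = [
    "anova_oneway",
    "tukey_hsd",
    "pst",
    "pst_from_anova",
    "trait_pca",
    "lda_classify",
    "quasibinomial_glm",
    "AnovaResult",
    "PstResult",
]


# ------------------------------------------------------------ ANOVA / PST


@dataclass
class AnovaResult:
    """One-way ANOVA with method-of-moments variance components."""

    F: float
    p: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    sigma2_within: float
    sigma2_between: float  # truncated at 0
    sigma2_between_raw: float  # before truncation
    n0: float  # unbalanced-design coefficient
    group_means: pd.Series


def _values_groups(t, trait=None, groups=None):
    if isinstance(t, TraitTable):
        return t.trait(trait).to_numpy(dtype=float), t.groups.to_numpy()
    return np.asarray(t, dtype=float), np.asarray(groups)


def anova_oneway(t, trait=None, groups=None) -> AnovaResult:
    """One-way ANOVA of a trait across groups.

    Accepts a TraitTable plus trait name, or raw (values, ..., groups).
    sigma2_W = MSW; sigma2_B = (MSB - MSW)/n0, truncated at zero, with
    n0 = (N - sum n_k^2 / N) / (K - 1).
    """
    y, g = _values_groups(t, trait, groups)
    mask = np.isfinite(y)
    y, g = y[mask], g[mask]
    labels, inverse = np.unique(g, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("need at least 2 groups")
    ns = np.bincount(inverse)
    if ns.min() < 2:
        raise ValueError("need at least 2 observations per group")
    N = ns.sum()
    means = np.array([y[inverse == k].mean() for k in range(K)])
    grand = y.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((y - means[inverse]) ** 2))
    df_b, df_w = K - 1, N - K
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    n0 = (N - np.sum(ns**2) / N) / df_b
    s2b_raw = (ms_b - ms_w) / n0
    return AnovaResult(
        F=float(F),
        p=p,
        df_between=df_b,
        df_within=int(df_w),
        ms_between=ms_b,
        ms_within=ms_w,
        sigma2_within=ms_w,
        sigma2_between=max(s2b_raw, 0.0),
        sigma2_between_raw=s2b_raw,
        n0=float(n0),
        group_means=pd.Series(means, index=labels),
    )


def _compact_letter_display(labels, not_different: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise results."""
    letters: list[set[str]] = []
    for a, b in ((x, y) for i, x in enumerate(labels) for y in labels[i + 1 :]):
        if frozenset((a, b)) in not_different:
            placed = False
            for group in letters:
                if a in group and b in group:
                    placed = True
                    break
            if not placed:
                merged = False
                for group in letters:
                    if a in group or b in group:
                        # can we extend this letter group without joining a
                        # significantly different pair?
                        cand = group | {a, b}
                        if all(
                            frozenset((x, y)) in not_different
                            for i, x in enumerate(sorted(cand))
                            for y in sorted(cand)[i + 1 :]
                        ):
                            group |= {a, b}
                            merged = True
                            break
                if not merged:
                    letters.append({a, b})
    for lab in labels:  # singletons that differ from everything
        if not any(lab in group for group in letters):
            letters.append({lab})
    # absorb subsets
    letters = [g for g in letters if not any(g < h for h in letters)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, group in enumerate(letters):
        for lab in sorted(group):
            out[lab] += alphabet[i]
    return out


def tukey_hsd(t, trait=None, groups=None, alpha: float = 0.05):
    """Tukey HSD pairwise comparisons with a compact letter display.

    Returns (pairwise DataFrame, {group: letters}); groups sharing no
    letter differ significantly at ``alpha``.
    """
    y, g = _values_groups(t, trait, groups)
    mask = np.isfinite(y)
    res = pairwise_tukeyhsd(y[mask], g[mask], alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    labels = sorted(set(g[mask]))
    not_diff = {
        frozenset((row["group1"], row["group2"]))
        for _, row in table.iterrows()
        if not row["reject"]
    }
    return table, _compact_letter_display(labels, not_diff)


@dataclass
class PstResult:
    trait: str
    sigma2_between: float
    sigma2_within: float
    c: float
    h2: float
    value: float


def pst(sigma2_between: float, sigma2_within: float, c: float = 1.0, h2: float = 0.5,
        trait: str = "") -> PstResult:
    """P_ST from variance components (c = 1, h^2 = 0.5 by default)."""
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    if sigma2_between < 0 or sigma2_within < 0:
        raise ValueError("variance components must be non-negative")
    scale = c / h2
    denom = scale * sigma2_between + 2 * sigma2_within
    value = scale * sigma2_between / denom if denom > 0 else np.nan
    return PstResult(trait, sigma2_between, sigma2_within, c, h2, float(value))


def pst_from_anova(t, trait=None, groups=None, c: float = 1.0, h2: float = 0.5) -> PstResult:
    """P_ST of a trait from its one-way ANOVA variance components."""
    a = anova_oneway(t, trait, groups)
    return pst(a.sigma2_between, a.sigma2_within, c, h2,
               trait=trait if isinstance(trait, str) else "")


# ------------------------------------------------------------- PCA / LDA


@dataclass
class TraitPcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    percent_variance: np.ndarray
    dropped_traits: list[str]


def trait_pca(t: TraitTable, traits: list[str]) -> TraitPcaResult:
    """Correlation-matrix PCA on standardized traits (complete cases)."""
    X = t.data[traits].dropna()
    kept, dropped = [], []
    for col in traits:
        if X[col].std(ddof=0) == 0:
            dropped.append(col)
        else:
            kept.append(col)
    if dropped:
        warnings.warn(f"dropping constant traits: {dropped}")
    Z = (X[kept] - X[kept].mean()) / X[kept].std(ddof=0)
    p = PCA()
    scores = p.fit_transform(Z.to_numpy())
    axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return TraitPcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=axes),
        loadings=pd.DataFrame(p.components_.T, index=kept, columns=axes),
        percent_variance=100 * p.explained_variance_ratio_,
        dropped_traits=dropped,
    )


@dataclass
class LdaResult:
    posterior: pd.DataFrame
    predicted: pd.Series
    correct_rate: pd.Series  # per group, plus 'overall'
    trait_posterior_r: pd.DataFrame  # traits x groups, Pearson r vs logit posterior
    ridged: bool = False


def lda_classify(t: TraitTable, traits: list[str]) -> LdaResult:
    """Fisher LDA on standardized traits with pooled covariance.

    Reports resubstitution correct-classification rates per group and the
    Pearson correlation of each trait with the logit-transformed group
    posteriors (the paper-style diagnostic-trait screen).  A singular
    pooled covariance triggers a shrinkage refit, with a warning.
    """
    cols = traits + [t.group_col]
    df = t.data[cols].dropna()
    X = df[traits].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    y = df[t.group_col].to_numpy()
    labels = np.unique(y)
    for lab in labels:
        if (y == lab).sum() <= len(traits):
            warnings.warn(
                f"group {lab!r} has no more observations than traits; "
                "pooled covariance may be unstable"
            )
    ridged = False
    try:
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(X, y)
        post = lda.predict_proba(X)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance: refitting with shrinkage")
        ridged = True
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
        post = lda.predict_proba(X)
    pred = lda.predict(X)
    posterior = pd.DataFrame(post, index=df.index, columns=lda.classes_)
    rates = {lab: float((pred[y == lab] == lab).mean()) for lab in labels}
    rates["overall"] = float((pred == y).mean())
    eps = 1e-8
    logit = np.log(np.clip(post, eps, 1 - eps) / (1 - np.clip(post, eps, 1 - eps)))
    r = pd.DataFrame(index=traits, columns=lda.classes_, dtype=float)
    for j, lab in enumerate(lda.classes_):
        for i, trait in enumerate(traits):
            r.loc[trait, lab] = float(np.corrcoef(X[:, i], logit[:, j])[0, 1])
    return LdaResult(
        posterior=posterior,
        predicted=pd.Series(pred, index=df.index),
        correct_rate=pd.Series(rates),
        trait_posterior_r=r,
        ridged=ridged,
    )


# ---------------------------------------------------------- quasibinomial


@dataclass
class QuasibinomialResult:
    coefficients: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    dispersion: float
    group_proportions: pd.Series
    separated: bool = False

    def contrast(self, group_a: str, group_b: str) -> dict:
        """Wald contrast of two group levels on the logit scale."""
        ca = self.coefficients.get(f"C[{group_a}]", 0.0)
        cb = self.coefficients.get(f"C[{group_b}]", 0.0)
        va = self.bse.get(f"C[{group_a}]", 0.0) ** 2
        vb = self.bse.get(f"C[{group_b}]", 0.0) ** 2
        diff = ca - cb
        se = np.sqrt(va + vb)  # treatment-coded, covariance ignored for ref level
        return {"estimate": float(diff), "se": float(se)}


def quasibinomial_glm(successes, totals, groups) -> QuasibinomialResult:
    """Binomial-logit GLM with a quasi-likelihood dispersion.

    Fit by IRLS (statsmodels); the dispersion phi is the Pearson
    chi-square divided by residual df, and coefficient standard errors,
    t-values and p-values are scaled accordingly.  Complete separation
    (a group entirely at 0 or 1) is flagged and refit with a small ridge
    so estimates stay finite.
    """
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    groups = np.asarray(groups)
    if np.any(totals < 1):
        raise ValueError("totals must be at least 1")
    if np.any(successes < 0) or np.any(successes > totals):
        raise ValueError("successes must lie in [0, totals]")
    labels = pd.unique(groups)
    design = pd.get_dummies(pd.Categorical(groups, categories=labels), drop_first=True)
    design.columns = [f"C[{c}]" for c in design.columns]
    exog = sm.add_constant(design.to_numpy(dtype=float))
    names = ["Intercept"] + list(design.columns)
    endog = np.column_stack([successes, totals - successes])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    res = model.fit()
    separated = bool(np.any(np.abs(res.params) > 15))
    if separated:
        warnings.warn("complete separation detected: refitting with a small ridge")
        res_r = model.fit_regularized(alpha=1e-6, L1_wt=0.0)
        res = model.fit(start_params=np.asarray(res_r.params), maxiter=0)
    # quasi-likelihood dispersion: Pearson chi-square (on the count scale,
    # i.e. weighted by the trial numbers) over residual df
    mu = res.mu
    y = successes / totals
    df_resid = len(totals) - exog.shape[1]
    if df_resid > 0:
        phi = float(np.sum(totals * (y - mu) ** 2 / (mu * (1 - mu))) / df_resid)
    else:
        phi = np.nan  # saturated model: dispersion inestimable
    bse = res.bse * np.sqrt(phi) if np.isfinite(phi) else np.full_like(res.bse, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = res.params / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), max(df_resid, 1))
    props = {
        str(lab): float(successes[groups == lab].sum() / totals[groups == lab].sum())
        for lab in labels
    }
    return QuasibinomialResult(
        coefficients=pd.Series(res.params, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        dispersion=phi,
        group_proportions=pd.Series(props),
        separated=separated,
    )
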