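# Methods

`cryptolin` implements the analysis chain used to characterize sympatric
cryptic plant lineages — the motivating system is the common rush
*Juncus effusus*, in which two highly selfing, morphologically cryptic
lineages (*eff1*, *eff2*) coexist with the congener *J. conglomeratus*
(*cong*) — together with a synthetic-data generator that emulates such a
system so every stage can be exercised, and its estimators validated,
without field data.

## Population-genetic statistics (`popgen`)

Gene diversity is Nei's unbiased estimator,
H_E = 2n/(2n−1) · (1 − Σ p_a²), per locus and group, with the multilocus
value the mean over loci.  Allelic richness uses hypergeometric
rarefaction to a common number of gene copies g,
A_R = Σ_a [1 − C(N−N_a, g)/C(N, g)]; the default g is twice the smallest
per-group, per-locus genotyped sample size (the FSTAT convention, using
the global minimum; an override is accepted).  F_IS and F_ST are the
Weir & Cockerham (1984) variance-component estimators: per-allele
components a, b, c are summed over alleles and loci and combined as
ratios (θ = Σa/Σ(a+b+c); small-f within groups from b and c with r = 1).
Negative multilocus estimates are reported as computed, never truncated.
The test suite checks both estimators against an independent scalar-loop
transcription of the published formulas to 1e−12 on random instances.

Genotypic distances use the codominant squared-distance scheme of Smouse
& Peakall (identical genotypes 0; homozygote vs heterozygote sharing an
allele 1; two heterozygotes sharing one allele 1, sharing none 2;
homozygote vs heterozygote sharing none 3; two different homozygotes 4),
summed over loci.  Missing data are excluded per locus everywhere; for
pairwise distances the sum is rescaled by (total loci / loci compared)
rather than imputed.  PCoA applies Gower double-centering to −d²/2 and an
eigendecomposition; axis percentages are taken over positive eigenvalues
only, and negative eigenvalues are reported rather than dropped
(scikit-bio's implementation serves as a cross-check in the tests).

## Genotype clustering (`bayesclust`)

The clustering model is deliberately minimal: K clusters, no admixture,
uniform assignment prior, independent Dirichlet(1) priors on per-cluster,
per-locus allele frequencies, and a collapsed Gibbs sampler over
individual assignments.  This is a simplification of the full
STRUCTURE-style model family (no admixture proportions, no correlated
frequencies, no explicit selfing likelihood); it is adequate here because
the downstream inferences rest only on discrete cluster membership of
strongly differentiated groups.  Label switching is handled by reporting
the pairwise co-assignment matrix — the probability two individuals share
a cluster — which is invariant under label permutation; per-individual
occupancy posteriors are also returned.  The per-sweep collapsed marginal
likelihood log P(X | Z) feeds the Evanno ΔK heuristic,
ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / sd(K), computed over replicate runs;
zero replicate variance yields an infinite sentinel rather than an error.
Default chain lengths are 5,000 burn-in plus 20,000 total sweeps (desk
scale); the pipeline uses shorter chains, configurable per run.  On
two-individual instances the sampler is checked against exact enumeration
of the collapsed marginal.

## Hybrid classification (`hybclass`)

Six genotype frequency classes arise after two generations of crossing
between two parental gene pools: Pure_A, Pure_B, F1, F2 and the two
backcrosses.  Each class fixes the expected proportions of the three
locus-ancestry categories (both gene copies from pool A / one from each /
both from B): (1,0,0), (0,0,1), (0,1,0), (¼,½,¼), (½,½,0), (0,½,½).
Genotype likelihoods combine category weights with within-pool
Hardy–Weinberg products and the cross-pool term
p_Aa·p_Bb + p_Ab·p_Ba for heterozygotes.  A Gibbs sampler alternates
(i) per-individual class given pool frequencies, (ii) per-gene-copy pool
origins given the class, (iii) pool frequencies from Dirichlet(1 +
counts).  The class prior is uniform (configurable); reference
individuals may be pinned to the pure classes to anchor pool labels, and
unsupervised operation is the default.  The call rule is max-posterior
with a 0.95 threshold, and a binary hybrid-vs-pure call based on the
summed posterior of the four hybrid classes at the same threshold — the
rule used in the study system to select hybrids for fitness assays.
Exactness is checked by enumeration over class × origin configurations on
two-locus toys.

The model assumes random mating within ancestry categories; under strong
selfing, pure individuals homozygous for alleles shared between pools can
receive posterior mass on F2/backcross classes.  Class-level confusion
among hybrid categories is therefore expected and is reported, not
hidden; the binary hybrid-vs-pure discrimination remains sharp (≥ 90% on
the synthetic calibration, typically ≥ 97%).

## Haplotype networks (`haplonet`)

Aligned organellar sequences are collapsed to unique haplotypes (numbered
by decreasing frequency, ties by first occurrence).  Step distances
support three gap treatments: `ignore` (pairwise deletion),
`fifth_state` (each gap column a state), and the default
`indel_block_as_one` (a contiguous gap run counts one step) — the default
reflects common practice for intergenic spacers; the mode is exposed
because the appropriate treatment is data-dependent.  The network adds
connections in order of increasing step count (ties broken by higher
summed haplotype frequency, then lexicographic ids) while they join
distinct components, up to a fixed connection limit (default 7 steps);
more distant pairs stay disconnected, so the result can be a forest.
Exact ties for a merge are kept as marked alternative ("loop") edges.
Multi-step connections are expanded through inferred intermediate nodes
of frequency zero.  The probability-of-parsimony limit calculation of the
original statistical-parsimony method is not implemented — the limit is a
parameter, matching how it is fixed in practice.  The construction is
verified against brute-force minimum spanning totals on small sets.

## Flowering phenology (`phenostats`)

Among-individual synchrony (mean r) is the mean Pearson correlation of
per-individual flowering-proportion series across censuses, over pairs
within a lineage, between lineages, or overall.  Pairs involving a
zero-variance series are excluded and counted.  The lineage-specific
probability of hybrid formation assumes random mating: per census n,
m_ij(n) = x̄_j(n)·N_j / (x̄_i(n)·N_i + x̄_j(n)·N_j) (defined 0 when the
denominator is 0), where x̄ is the lineage mean flowering proportion and
N the absolute lineage sizes; P_i weights m_ij by the focal lineage's
share of its own flowering effort, P_i = Σ_n [x̄_i(n)/Σ_m x̄_i(m)]·m_ij(n).
The per-census probabilities of mating within vs between lineages sum to
one.  This frequency-weighted form is implemented behind a named strategy
(`"frequency_weighted"`) so alternative algebras can be swapped in; its
symmetry (identical schedules, equal N → 0.5) and disjointness (no
temporal overlap → 0) properties pin the intended behavior.

Confidence intervals are percentile bootstrap over individuals resampled
with replacement within lineage strata (1,000 replicates by default);
BCa was not used because the method being mirrored specifies plain
bootstrap intervals.  Bootstrap copies of the same source individual are
never paired with themselves in pairwise statistics — self-pairs have
r = 1 by construction and would bias synchrony upward; with this
exclusion the 95% interval for mean r attains ~0.90 coverage at 20
individuals per lineage (the scale of the study's census), which the
acceptance suite verifies over 500 replicates.  Resamples on which a
statistic is undefined are redrawn and counted.

## Quantitative traits (`quantdiff`)

One-way ANOVA is computed from sums of squares; method-of-moments
variance components use σ²_W = MSW and σ²_B = (MSB − MSW)/n₀ with the
unbalanced-design coefficient n₀ = (N − Σn_k²/N)/(K−1), truncating
negative σ²_B at zero (the raw value is also reported).  Tukey HSD
contrasts come from statsmodels, summarized as a compact letter display
at α = 0.05.  P_ST = (c/h²)·σ²_B / [(c/h²)·σ²_B + 2σ²_W], with c = 1 and
h² = 0.5 by default — the neutral-comparison convention for phenotypic
divergence when heritabilities are unknown.  Trait PCA standardizes to
unit variance (correlation-matrix PCA, scikit-learn), dropping constant
traits with a warning.  LDA uses pooled covariance (scikit-learn),
reports per-group resubstitution rates, and screens diagnostic traits by
correlating each trait with logit-transformed group posteriors (clipped
at 1e−8).  Herbivory and germination proportions use a binomial-logit
GLM with a quasi-likelihood dispersion φ = Pearson χ²/df computed on the
count scale; standard errors, t- and p-values are scaled by √φ (the
dispersion is computed directly because statsmodels' scale option
mis-handles two-column binomial endog).  Complete separation is flagged
and refit with a small ridge so estimates stay finite.

## Synthetic study systems (`synthgen`)

The generator's defaults are the study conditions: three lineages
(cong, eff1, eff2) of 110 individuals each plus 7% hybrids (≈ 355 total,
the genotyped sample size), 11 microsatellite loci with 6 possible
alleles, pairwise F_ST targets 0.57/0.57/0.72, selfing-level inbreeding
F = 0.9, hybrid pair weights 0.68/0.24/0.08 (cong×eff1, eff1×eff2,
cong×eff2) and class weights 0.30/0.35/0.175/0.175 (F1/F2/BC×2, the
observed hybrid-class spectrum), seven chloroplast haplotypes with h3
shared between cong and eff2, h1–h2 private to cong, h4–h7 a private eff1
clade 3–6 steps from the rest, flowering onsets offset 0/+7/+19 days with
durations 17/21/18 days, herbivory means 19/17/4%, and soil moisture
uniform on 7–29% independent of lineage.

Differentiation follows the F-model: lineage frequencies are drawn from
Dirichlet(p_anc·(1−d)/d) around ancestral Dirichlet(1) frequencies.  In
the infinite-sample limit the Weir–Cockerham θ between two lineages
reduces to Σ Δ²/2 over Σ (Δ²/4 + p̄(1−p̄)) (heterozygosity terms cancel),
whose expectation is approximately the mean of the two drift parameters;
per-lineage drift therefore solves the linear system d_k + d_l = 2·T_kl.
Because an 11-locus draw of the F-model has substantial among-locus
variance in realized θ (sd ≈ 0.07), the generator then tunes the draw:
frequencies are drawn with inflated drift (×1.3) and per-lineage shrink
factors toward the ancestor are solved by least squares so the parametric
θ of the realized frequencies matches the target matrix exactly.  After
tuning, realized multilocus θ at 100 individuals per lineage deviates
from target with sd ≈ 0.018 (30-seed pilot), so estimator-recovery checks
at ±0.08 sit at roughly four standard deviations.  Genotypes are drawn
with homozygote excess P(aa) = p² + F·p(1−p).

Hybrids are produced by explicit gamete sampling: F1 one gamete per pool;
F2 two gametes from simulated F1s (per locus pool A or B with probability
½, free recombination); backcrosses one F1 gamete plus one parental
gamete.  Maternal parents are drawn uniformly from the pair unless a
maternal-bias weighting is configured (the observed system showed a bias
toward eff1 mothers; the default is unbiased).  Haplotypes are assigned
maternally, including to hybrids.  Haplotype sequences realize a
configured mutation tree exactly, each edge mutating its own set of
sites, so pairwise Hamming distances equal path lengths.

Flowering curves are truncated Gaussians: onset = season start + lineage
offset + N(0, jitter), peak at onset + duration/2, sd = duration/4,
scaled to a peak proportion (0.9) and zero outside [onset,
onset+duration].  Only onsets, offsets and durations are constrained by
the emulated system; the curve shape, the peak height, and the
start-date jitter (sd 3 days) are free choices.  Jitter of 3 days puts
the P_ST of first flowering between the cryptic lineages near 0.8 at
c = 1, h² = 0.5, in the region where quantitative divergence is
comparable to the neutral F_ST of the same simulated lineages.  Traits
are multivariate normal around lineage means (eff1 mostly intermediate;
ridge count separating the congener; spathe length and flower density
separating the cryptic pair; seed width deliberately near-identical);
hybrids take parental midpoints.  Herbivory is beta-binomial
(dispersion ρ = 0.08) over Poisson(60) capsules, giving the
overdispersion the quasibinomial analysis exists to absorb.

What the generator does not emulate: real microsatellite mutation
processes (stepwise mutation, allele-size homoplasy), linkage, spatial
structure, year effects in phenology, correlated trait errors, or the
asymmetric synchrony the field system showed between the two cryptic
lineages (a single jitter parameter makes simulated within-lineage
synchrony similar for both).  Passing recovery tests therefore
demonstrates estimator correctness under the model's assumptions, not
robustness to these real-data features.  The simulated flowering overlap
between the cryptic lineages (P ≈ 0.2) is larger than in the field
(≈ 0.07), since individual curves here are wider relative to the offset;
the disjointness/symmetry properties, not the field values, are the
contract.

## Pipeline (`pipeline`, `cli`)

`cryptolin run` chains simulate (or load) → diversity/differentiation →
PCoA → clustering with ΔK → pairwise hybrid classification → haplotype
network → phenology → traits → a JSON + Markdown report.  Hybrids are
excluded from group diversity, differentiation and trait comparisons (as
in the emulated study's convention), toggleable.  Every stage seed
derives deterministically from the global seed via spawned seed
sequences, and the report is byte-identical across invocations at a
fixed configuration.  Stage failures preserve a partial report and raise
with the stage name.  Default pipeline chain lengths are shorter than
the module defaults (desk-scale runs in minutes); all lengths are
configuration fields.

## Numerical and degenerate-input choices

Zero-variance series in correlations: excluded, counted, never set to 0.
Monomorphic groups: F_IS is NaN with a warning, not 0.  Degenerate
pairwise F_ST (no informative loci): NaN with a warning; the multilocus
estimate still errors if nothing is informative.  ΔK with zero replicate
sd: +inf sentinel.  Bootstrap resamples with undefined statistics:
redrawn and counted, with a hard cap.  Gibbs samplers use fixed integer
seeds end to end (numba kernels seed numpy's legacy generator); posterior
occupancy uses thinned post-burn-in states.  Allelic richness uses
log-gamma arithmetic to avoid overflow in binomial coefficients.
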