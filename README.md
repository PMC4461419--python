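# cryptolin

Analysis toolkit for **sympatric cryptic plant lineages**: genetically
distinct groups that co-occur and are morphologically indistinguishable,
as in the common rush *Juncus effusus*, where two highly selfing cryptic
lineages coexist with the congener *J. conglomeratus*.  The package
covers the full chain such a study needs, on codominant microsatellite
genotypes, chloroplast haplotype alignments, flowering censuses and
quantitative trait tables:

- **`popgen`** — Nei's unbiased gene diversity H_E, rarefied allelic
  richness A_R, Weir–Cockerham F_IS and F_ST (θ), Smouse–Peakall
  codominant genotypic distances, PCoA.
- **`bayesclust`** — no-admixture Gibbs clustering of multilocus
  genotypes with label-invariant co-assignment matrices, and the Evanno
  ΔK heuristic for the number of clusters.
- **`hybclass`** — posterior assignment to the six genotype frequency
  classes (pure ×2, F1, F2, backcross ×2) distinguishable after two
  generations of crossing, with the 0.95 posterior call rule.
- **`haplonet`** — haplotype collapsing and fixed-limit statistical
  parsimony networks (default connection limit 7 steps).
- **`phenostats`** — among-individual flowering synchrony (mean
  pairwise Pearson r), the lineage-specific probability of hybrid
  formation under random mating, and stratified percentile-bootstrap CIs.
- **`quantdiff`** — one-way ANOVA with Tukey letters and variance
  components, trait PCA, LDA with diagnostic-trait screening,
  quasibinomial GLMs for herbivory/germination proportions, and
  P_ST = (c/h²)σ²_B / [(c/h²)σ²_B + 2σ²_W], the phenotypic analogue of
  Q_ST for comparison against neutral F_ST.
- **`synthgen`** — a seeded generator that simulates the whole study
  system (three lineages with calibrated pairwise F_ST ≈ 0.57/0.57/0.72,
  selfing F = 0.9, ~7% hybrids, seven maternally inherited haplotypes
  with a fixed sharing pattern, staggered flowering schedules,
  overdispersed seed-predation counts) with ground-truth labels.
- **`cryptolin`** (CLI) — `simulate`, `popgen`, `cluster`, `hybrids`,
  `network`, `phenology`, `traits`, `pst`, and `run` for the full
  simulate → analyze → report pipeline.

See `docs/methods.md` for the models, estimators, assumptions and
numerical conventions.

## Worked example

Simulate the study system at its default calibration and run the core
statistics:

```python
from cryptolin import synthgen, popgen, phenostats, quantdiff
from cryptolin.datatypes import FloweringSchedule

ds = synthgen.simulate_dataset(synthgen.SimulationConfig(seed=7))
pure = ds.pure_mask()
g, lab = ds.genotypes.subset(pure), ds.labels[pure].to_numpy()

print(popgen.diversity_summary(g, lab).table().round(2))
print(popgen.wc_fst(g, lab).pairwise.round(2))

s = ds.schedule
members = [i for i in s.individuals if s.lineage[i] in ("eff1", "eff2")]
sub = FloweringSchedule(s.values.loc[members].copy(), s.lineage.loc[members].copy())
print(repr(phenostats.flowering_synchrony(sub, "between", n_boot=199, seed=1)))

t = ds.traits.data[pure]
pair = t["lineage"].isin(["eff1", "eff2"])
pst = quantdiff.pst_from_anova(t.loc[pair, "first_flowering"],
                               groups=t.loc[pair, "lineage"])
print(f"P_ST(first flowering, eff1 vs eff2) = {pst.value:.2f}")
```

Output:

```
       H_E   A_R  F_IS
cong  0.42  4.73  0.92
eff1  0.32  4.82  0.88
eff2  0.13  3.91  0.91
      cong  eff1  eff2
cong  0.00  0.57  0.60
eff1  0.57  0.00  0.71
eff2  0.60  0.71  0.00
mean_r[between] = 0.0438 (95% CI -0.0236..0.1121)
P_ST(first flowering, eff1 vs eff2) = 0.90
```

Reading the numbers: the three simulated lineages are strongly
differentiated at nuclear markers (pairwise θ 0.57–0.71, matching the
calibration targets), each with the severe heterozygote deficit of a
selfer (F_IS ≈ 0.9).  Flowering of the two cryptic lineages is offset by
~12 days, so between-lineage synchrony is near zero while quantitative
divergence in first-flowering date (P_ST = 0.90 at c = 1, h² = 0.5) is of
the same order as the neutral θ between them — the comparison that asks
whether flowering-time divergence needs anything beyond drift to explain.

The same pipeline end to end, from the shell:

```sh
cryptolin run --out myrun --seed 3
cat myrun/report.md
```

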