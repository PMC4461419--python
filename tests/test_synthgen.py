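"""Synthetic-data generator: determinism, validation and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from cryptolin import popgen, quantdiff, synthgen
from cryptolin.datatypes import GenotypeMatrix


class TestConfigValidation:
    def test_asymmetric_fst_rejected(self):
        T = [[0.0, 0.5, 0.5], [0.4, 0.0, 0.5], [0.5, 0.5, 0.0]]
        with pytest.raises(ValueError, match="symmetric"):
            synthgen.SimulationConfig(target_fst=T)

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError, match="selfing_f"):
            synthgen.SimulationConfig(selfing_f=1.4)

    def test_nonincreasing_census_dates_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            synthgen.SimulationConfig(census_dates=(3.0, 2.0, 5.0))

    def test_unattainable_fst_target_rejected(self):
        # pairwise targets requiring negative drift for one lineage
        T = [[0.0, 0.05, 0.05], [0.05, 0.0, 0.9], [0.05, 0.9, 0.0]]
        with pytest.raises(ValueError, match="unattainable"):
            synthgen.calibrate_drift(np.array(T))

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ValueError, match="alleles"):
            synthgen.SimulationConfig(alleles_per_locus=1)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = synthgen.simulate_dataset(synthgen.SimulationConfig(seed=42))
        b = synthgen.simulate_dataset(synthgen.SimulationConfig(seed=42))
        assert np.array_equal(a.genotypes.alleles, b.genotypes.alleles)
        assert a.haplotypes.sequences == b.haplotypes.sequences
        assert a.haplotypes.assignment == b.haplotypes.assignment
        assert a.schedule.values.equals(b.schedule.values)
        assert a.traits.data.equals(b.traits.data)

    def test_different_seed_differs(self):
        a = synthgen.simulate_dataset(synthgen.SimulationConfig(seed=1))
        b = synthgen.simulate_dataset(synthgen.SimulationConfig(seed=2))
        assert not np.array_equal(a.genotypes.alleles, b.genotypes.alleles)


class TestGenotypeRecovery:
    def test_realized_fst_within_tolerance(self):
        # recovery via this package's own Weir-Cockerham estimator
        cfg = synthgen.SimulationConfig(
            seed=3, hybrid_fraction=0.0, n_individuals_per_lineage=(100, 100, 100)
        )
        ds = synthgen.simulate_dataset(cfg)
        fst = popgen.wc_fst(ds.genotypes, ds.labels.to_numpy())
        T = np.asarray(cfg.target_fst)
        for i, a in enumerate(cfg.lineage_names):
            for j, b in enumerate(cfg.lineage_names):
                if i < j:
                    assert fst.pairwise.loc[a, b] == pytest.approx(T[i, j], abs=0.08)

    def test_selfing_recovered_as_fis(self):
        cfg = synthgen.SimulationConfig(
            seed=4, selfing_f=0.9, hybrid_fraction=0.0,
            n_individuals_per_lineage=(100, 100, 100),
        )
        ds = synthgen.simulate_dataset(cfg)
        fis = popgen.inbreeding_coefficient(ds.genotypes, ds.labels.to_numpy())
        assert ((fis > 0.8) & (fis < 0.97)).all()

    def test_hybrid_fraction_realized(self):
        ds = synthgen.simulate_dataset(synthgen.SimulationConfig(seed=5))
        frac = (ds.truth["kind"] == "hybrid").mean()
        assert frac == pytest.approx(0.07, abs=0.005)


class TestHybridGenotypes:
    def _fixed_pools(self, L=8):
        # pool A fixed for allele 1, pool B fixed for allele 2
        pa = np.zeros((L, 2))
        pa[:, 0] = 1.0
        pb = np.zeros((L, 2))
        pb[:, 1] = 1.0
        return pa, pb

    def test_f1_from_fixed_pools_all_heterozygous(self):
        pa, pb = self._fixed_pools()
        rng = np.random.default_rng(0)
        g = synthgen.generate_hybrid_genotypes(pa, pb, "F1", 20, rng)
        assert np.all(g[:, :, 0] != g[:, :, 1])

    def test_f2_mendelian_proportions(self):
        pa, pb = self._fixed_pools(L=1)
        rng = np.random.default_rng(1)
        g = synthgen.generate_hybrid_genotypes(pa, pb, "F2", 4000, rng)
        het = (g[:, 0, 0] != g[:, 0, 1]).mean()
        hom_a = ((g[:, 0, 0] == 1) & (g[:, 0, 1] == 1)).mean()
        assert het == pytest.approx(0.5, abs=0.03)
        assert hom_a == pytest.approx(0.25, abs=0.03)

    def test_backcross_heterozygosity_half(self):
        pa, pb = self._fixed_pools(L=1)
        rng = np.random.default_rng(2)
        g = synthgen.generate_hybrid_genotypes(pa, pb, "BC_A", 4000, rng)
        het = (g[:, 0, 0] != g[:, 0, 1]).mean()
        assert het == pytest.approx(0.5, abs=0.03)
        # the non-F1 gamete always carries the pool-A allele
        assert np.all((g[:, 0, 0] == 1) | (g[:, 0, 1] == 1))

    def test_unknown_class_rejected(self):
        pa, pb = self._fixed_pools()
        with pytest.raises(ValueError, match="unknown hybrid class"):
            synthgen.generate_hybrid_genotypes(pa, pb, "F3", 1, np.random.default_rng(0))


class TestHaplotypes:
    def test_tree_step_distances_exact(self, default_dataset):
        from cryptolin import haplonet

        cfg = default_dataset.config
        haps = synthgen.generate_haplotype_sequences(cfg)
        dist = haplonet.pairwise_steps(haps, gap_mode="fifth_state")
        # direct tree edges have the specified lengths
        for parent, child, steps in cfg.haplotype_tree:
            assert dist.loc[parent, child] == steps

    def test_lineage_block_structure(self, default_dataset):
        from cryptolin import haplonet

        haps = synthgen.generate_haplotype_sequences(default_dataset.config)
        dist = haplonet.pairwise_steps(haps)
        eff1_haps = ["h4", "h5", "h6", "h7"]
        rest = ["h1", "h2", "h3"]
        cross = dist.loc[eff1_haps, rest].to_numpy()
        assert cross.min() >= 3 and cross.max() <= 6
        assert dist.loc[rest, rest].to_numpy().max() <= 2

    def test_maternal_inheritance(self, default_dataset):
        ds = default_dataset
        pools = ds.config.haplotype_pools
        for ind, hap in ds.haplotypes.assignment.items():
            maternal = ds.truth.loc[ind, "maternal"]
            assert hap in pools[maternal]

    def test_unrealizable_step_pattern_rejected(self):
        cfg = synthgen.SimulationConfig(sequence_length=4)
        with pytest.raises(ValueError, match="mutated sites"):
            synthgen.generate_haplotype_sequences(cfg)


class TestFloweringSchedule:
    def test_onset_rank_order_follows_offsets(self, default_dataset):
        s = default_dataset.schedule
        onsets = {}
        dates = s.censuses
        for lin in ("cong", "eff1", "eff2"):
            members = s.lineage_members(lin)
            vals = s.values.loc[members].to_numpy()
            first = np.array([dates[np.flatnonzero(v > 0)[0]] for v in vals if v.any()])
            onsets[lin] = first.mean()
        assert onsets["cong"] < onsets["eff1"] < onsets["eff2"]

    def test_zero_jitter_identical_series(self):
        cfg = synthgen.SimulationConfig(seed=9, flowering_jitter_sd=0.0)
        lineage_of = {f"x{i}": "eff1" for i in range(5)}
        s = synthgen.generate_flowering_schedule(cfg, lineage_of, rng=np.random.default_rng(0))
        v = s.values.to_numpy()
        assert np.allclose(v, v[0])

    def test_flowering_span_matches_duration(self):
        cfg = synthgen.SimulationConfig(
            seed=10, flowering_jitter_sd=0.0,
            census_dates=tuple(np.arange(145.0, 205.0, 1.0)),
        )
        lineage_of = {"a": "eff1", "b": "eff2"}
        s = synthgen.generate_flowering_schedule(cfg, lineage_of, rng=np.random.default_rng(0))
        dates = s.censuses
        for ind, lin in lineage_of.items():
            v = s.values.loc[ind].to_numpy()
            active = dates[v > 0]
            expected = dict(zip(cfg.lineage_names, cfg.flowering_duration_days))[lin]
            assert active.max() - active.min() == pytest.approx(expected, abs=2.0)

    def test_values_are_proportions(self, default_dataset):
        v = default_dataset.schedule.values.to_numpy()
        assert v.min() >= 0 and v.max() <= 1


class TestTraitTable:
    def test_herbivory_means_recovered(self):
        cfg = synthgen.SimulationConfig(seed=12, n_individuals_per_lineage=(90, 90, 90),
                                        hybrid_fraction=0.0)
        ds = synthgen.simulate_dataset(cfg)
        t = ds.traits
        for lin, target in zip(cfg.lineage_names, cfg.herbivory_means):
            sub = t.data[t.groups == lin]
            mean_prop = (sub["damaged_capsules"] / sub["total_capsules"]).mean()
            assert mean_prop == pytest.approx(target, abs=0.05)

    def test_soil_moisture_independent_of_lineage(self):
        # ANOVA on moisture rejects at roughly the nominal rate
        rejections = 0
        reps = 200
        for rep in range(reps):
            cfg = synthgen.SimulationConfig(
                seed=1000 + rep, n_individuals_per_lineage=(25, 25, 25),
                hybrid_fraction=0.0,
            )
            ds = synthgen.simulate_dataset(cfg)
            res = quantdiff.anova_oneway(ds.traits, "soil_moisture")
            rejections += res.p < 0.05
        assert 0.015 <= rejections / reps <= 0.11

    def test_identical_trait_means_yield_null_anova(self):
        # equal lineage means -> p approximately uniform (spot check level)
        rejections = 0
        reps = 200
        means = dict(synthgen._DEFAULT_TRAIT_MEANS)
        means["stem_height_mm"] = (900.0, 900.0, 900.0)
        for rep in range(reps):
            cfg = synthgen.SimulationConfig(
                seed=5000 + rep, n_individuals_per_lineage=(20, 20, 20),
                hybrid_fraction=0.0, trait_means=means,
            )
            ds = synthgen.simulate_dataset(cfg)
            res = quantdiff.anova_oneway(ds.traits, "stem_height_mm")
            rejections += res.p < 0.05
        assert 0.015 <= rejections / reps <= 0.11

    def test_non_positive_definite_covariance_rejected(self):
        k = len(synthgen._DEFAULT_TRAIT_MEANS)
        cov = -np.eye(k)
        cfg = synthgen.SimulationConfig(seed=1, trait_cov=cov)
        with pytest.raises(ValueError, match="positive definite"):
            synthgen.generate_trait_table(cfg, {"x": "eff1"})

    def test_soil_moisture_in_configured_range(self, default_dataset):
        sm = default_dataset.traits.data["soil_moisture"]
        lo, hi = default_dataset.config.soil_moisture_range
        assert sm.between(lo, hi).all()


class TestRoundTrip:
    def test_genepop_round_trip(self, tmp_path, default_dataset):
        from cryptolin import io

        ds = default_dataset
        path = tmp_path / "sim.gen"
        io.write_genepop(ds.genotypes, ds.labels, path)
        g2, pops = io.read_genepop(path)
        assert np.array_equal(np.sort(g2.alleles, axis=2),
                              np.sort(ds.genotypes.alleles, axis=2))
        assert g2.loci == ds.genotypes.loci

    def test_fasta_round_trip(self, tmp_path, default_dataset):
        from cryptolin import io

        ds = default_dataset
        path = tmp_path / "haps.fasta"
        io.write_fasta(ds.haplotypes.sequences, path)
        seqs = io.read_alignment_fasta(path)
        assert seqs == ds.haplotypes.sequences

    def test_schedule_and_traits_round_trip(self, tmp_path, default_dataset):
        from cryptolin import io

        ds = default_dataset
        sp = tmp_path / "schedule.csv"
        io.write_schedule_csv(ds.schedule, sp)
        s2 = io.read_schedule_csv(sp)
        assert np.allclose(s2.values.to_numpy(), ds.schedule.values.to_numpy())
        assert (s2.lineage == ds.schedule.lineage).all()
        tp = tmp_path / "traits.csv"
        io.write_traits_csv(ds.traits, tp)
        t2 = io.read_traits_csv(tp)
        pd.testing.assert_frame_equal(
            t2.data, ds.traits.data, check_exact=False, check_names=False
        )
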