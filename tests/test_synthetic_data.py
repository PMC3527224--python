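"""Generator behaviour: divergence rates, coalescent diversity, sweeps, pileups."""

import numpy as np
import pytest

from tetrapop import popgen_stats as pg
from tetrapop import synthetic_data as syn
from tetrapop.inheritance_sim import InheritanceModel


class TestGeneModels:
    def test_generated_models_are_valid(self, sim_config, rng):
        genes = syn.make_gene_models(sim_config, rng)
        assert len(genes) == sim_config.n_genes
        for g in genes[:10]:
            cds = sum(f.end - f.start for f in g.features if f.kind == "CDS")
            assert cds % 3 == 0
            classes = g.site_classes()
            # third positions are one third of CDS sites
            assert (classes == "S").sum() == cds // 3

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            syn.GeneModel("g", 100, [syn.GeneFeature(0, 50, "CDS", 0),
                                     syn.GeneFeature(40, 80, "intron")])
        with pytest.raises(ValueError):
            syn.GeneModel("g", 100, [syn.GeneFeature(0, 50, "CDS", 0)])  # 50 % 3

    def test_bed_round_trip(self, sim_config, rng, tmp_path):
        genes = syn.make_gene_models(sim_config, rng)[:5]
        path = tmp_path / "genes.bed"
        syn.write_gene_models_bed(genes, path, seed=1)
        back = syn.read_gene_models_bed(path)
        assert [g.gene_id for g in back] == [g.gene_id for g in genes]
        assert back[0].features == genes[0].features


class TestTriples:
    def test_zero_divergence_gives_identical_sequences(self, small_gene, rng):
        cfg = syn.SimConfig(seed=1, d_syn=0.0, d_nonsyn=0.0, d_intron=0.0)
        t = syn.simulate_triple(small_gene, cfg, rng)
        assert t.focal == t.sister == t.outgroup

    def test_synonymous_divergence_rate_recovered(self, rng):
        """Mean focal-vs-sister difference rate at synonymous sites ~ 8.7e-4."""
        gene = syn.GeneModel("g", 9999, [syn.GeneFeature(0, 9999, "CDS", 0)])
        cfg = syn.SimConfig(seed=1)
        diffs = syn_sites = 0
        for _ in range(300):
            t = syn.simulate_triple(gene, cfg, rng)
            is_syn = t.site_class == "S"
            f = np.array(list(t.focal))
            s = np.array(list(t.sister))
            diffs += int((f[is_syn] != s[is_syn]).sum())
            syn_sites += int(is_syn.sum())
        rate = diffs / syn_sites
        se = np.sqrt(cfg.d_syn * (1 - cfg.d_syn) / syn_sites)
        assert abs(rate - cfg.d_syn) < 3 * se

    def test_mismatch_count_within_binomial_range(self, rng):
        # d_syn = 0.05 over 3000 synonymous sites: mean 150, sd ~ 11.9
        gene = syn.GeneModel("g", 9000, [syn.GeneFeature(0, 9000, "CDS", 0)])
        cfg = syn.SimConfig(seed=1, d_syn=0.05)
        t = syn.simulate_triple(gene, cfg, rng)
        is_syn = t.site_class == "S"
        mism = int((np.array(list(t.focal))[is_syn] != np.array(list(t.sister))[is_syn]).sum())
        sd = np.sqrt(3000 * 0.05 * 0.95)
        assert abs(mism - 150) < 3 * sd

    def test_zero_length_gene_rejected(self, sim_config, rng):
        with pytest.raises(ValueError):
            syn.GeneModel("g", 0, [])

    def test_fasta_round_trip(self, small_gene, sim_config, rng, tmp_path):
        t = syn.simulate_triple(small_gene, sim_config, rng)
        path = tmp_path / "triples.fasta"
        syn.write_triples_fasta([t], path, seed=1)
        back = syn.read_triples_fasta(path, [small_gene])
        assert back[0].focal == t.focal and back[0].outgroup == t.outgroup


class TestPopulation:
    def test_zero_theta_gives_no_segregating_sites(self, small_gene, rng):
        cfg = syn.SimConfig(seed=1, theta_silent=0.0, theta_nonsyn=0.0)
        s = syn.simulate_population(small_gene, cfg, InheritanceModel("tetrasomic"), rng)
        assert s.n_sites == 0

    def test_mean_segregating_sites_match_coalescent_expectation(self, rng):
        """E[S] = theta_locus * a_47 for the neutral tetrasomic coalescent."""
        gene = syn.GeneModel("g", 999, [syn.GeneFeature(0, 999, "CDS", 0)])
        cfg = syn.SimConfig(seed=1, theta_silent=0.043, theta_nonsyn=0.043)
        a47 = pg.harmonic(47)
        expect = 0.043 * 999 * a47
        S = [
            syn.simulate_population(gene, cfg, InheritanceModel("tetrasomic"), rng).n_sites
            for _ in range(300)
        ]
        se = np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(S) - expect) < 3 * se

    def test_disomic_assembly_takes_two_per_homeolog_pool(self, small_gene, sim_config, rng):
        model = InheritanceModel("disomic", t_d=1.0)
        s = syn.simulate_population(small_gene, sim_config, model, rng)
        # chromosomes 0..23 are pool one, 24..47 pool two
        for ind in range(12):
            chroms = np.nonzero(s.assignment == ind)[0]
            assert (chroms < 24).sum() == 2 and (chroms >= 24).sum() == 2

    def test_true_genotypes_sum_haplotypes(self, small_gene, sim_config, rng):
        s = syn.simulate_population(small_gene, sim_config, InheritanceModel("tetrasomic"), rng)
        manual = np.zeros((12, s.n_sites), dtype=int)
        for h in range(48):
            manual[s.assignment[h]] += s.haplotypes[h]
        np.testing.assert_array_equal(s.genotypes, manual)


class TestSweepInjection:
    def _sample(self, gene, rng):
        cfg = syn.SimConfig(seed=1)
        return syn.simulate_population(gene, cfg, InheritanceModel("tetrasomic"), rng)

    def test_full_replacement_is_monomorphic(self, small_gene, rng):
        s = self._sample(small_gene, rng)
        swept = syn.inject_sweep(s, 1.0, rng)
        assert swept.n_sites == 0
        assert pg.pi(swept.derived_counts(), 48, s.length) == 0.0

    def test_strong_sweep_lowers_pi_and_raises_high_frequency_mass(self, small_gene, rng):
        s = self._sample(small_gene, rng)
        assert s.n_sites > 5
        swept = syn.inject_sweep(s, 0.9, rng)
        pi_before = pg.pi(s.derived_counts(), 48, s.length)
        pi_after = pg.pi(swept.derived_counts(), 48, s.length)
        assert pi_after < pi_before
        high_before = (s.derived_counts() >= 40).sum()
        high_after = (swept.derived_counts() >= 40).sum()
        assert high_after > high_before

    def test_vanishing_fraction_leaves_sample_unchanged(self, small_gene, rng):
        s = self._sample(small_gene, rng)
        same = syn.inject_sweep(s, 1e-6, rng)
        np.testing.assert_array_equal(same.haplotypes, s.haplotypes)

    def test_out_of_range_fraction_rejected(self, small_gene, rng):
        s = self._sample(small_gene, rng)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                syn.inject_sweep(s, bad, rng)


class TestPileups:
    def test_error_free_homozygote_pileup_is_pure(self, small_gene, rng):
        cfg = syn.SimConfig(seed=1, error_rate=0.0)
        s = syn.simulate_population(small_gene, cfg, InheritanceModel("tetrasomic"), rng)
        pile = syn.simulate_pileups(s, cfg, rng)
        counts = pile[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
        k = dict(zip(s.positions, s.genotypes.T.tolist()))
        for row, c in zip(pile.itertuples(), counts):
            dosage = k[row.pos][row.individual]
            if dosage == 0:  # pure ancestral individual: only the ancestral base
                anc = s.ancestral[np.searchsorted(s.positions, row.pos)]
                assert c.sum() == c[syn.BASES.tolist().index(anc)]

    def test_error_fraction_recovered(self, rng):
        """Non-allele base fraction from homozygotes ~ e within binomial error."""
        gene = syn.GeneModel("g", 3000, [syn.GeneFeature(0, 3000, "CDS", 0)])
        cfg = syn.SimConfig(seed=1, error_rate=0.0015, mean_depth=60.0)
        total = wrong = 0
        while total < 1_000_000:
            s = syn.simulate_population(gene, cfg, InheritanceModel("tetrasomic"), rng)
            pile = syn.simulate_pileups(s, cfg, rng)
            counts = pile[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
            geno = s.genotypes
            pos_idx = np.searchsorted(s.positions, pile["pos"].to_numpy())
            dosage = geno[pile["individual"].to_numpy(), pos_idx]
            pure = dosage == 0
            anc_idx = np.searchsorted(syn.BASES, s.ancestral)[pos_idx][pure]
            c = counts[pure]
            total += int(c.sum())
            wrong += int(c.sum() - c[np.arange(len(c)), anc_idx].sum())
        rate = wrong / total
        se = np.sqrt(cfg.error_rate / total)
        assert abs(rate - cfg.error_rate) < 4 * se

    def test_balanced_duplex_tends_to_half(self, rng):
        gene = syn.GeneModel("g", 300, [syn.GeneFeature(0, 300, "CDS", 0)])
        cfg = syn.SimConfig(seed=1, error_rate=1e-9, mean_depth=5000.0)
        s = syn.simulate_population(gene, cfg, InheritanceModel("tetrasomic"), rng)
        pile = syn.simulate_pileups(s, cfg, rng)
        geno = s.genotypes
        pos_idx = np.searchsorted(s.positions, pile["pos"].to_numpy())
        dosage = geno[pile["individual"].to_numpy(), pos_idx]
        duplex = np.nonzero(dosage == 2)[0]
        assert duplex.size > 0
        counts = pile[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
        der = np.searchsorted(syn.BASES, s.derived)[pos_idx]
        for i in duplex[:20]:
            frac = counts[i, der[i]] / counts[i].sum()
            assert frac == pytest.approx(0.5, abs=0.05)

    def test_poisson_depth(self, small_gene, sim_config, rng):
        s = syn.simulate_population(small_gene, sim_config, InheritanceModel("tetrasomic"), rng)
        pile = syn.simulate_pileups(s, sim_config, rng)
        depth = pile[["count_A", "count_C", "count_G", "count_T"]].sum(axis=1)
        assert abs(depth.mean() - 25) < 4 * depth.std() / np.sqrt(len(depth))


class TestDeterminism:
    def test_identical_seeds_identical_outputs(self, small_gene):
        cfg = syn.SimConfig(seed=9)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            t = syn.simulate_triple(small_gene, cfg, rng)
            s = syn.simulate_population(small_gene, cfg, InheritanceModel("tetrasomic"), rng)
            p = syn.simulate_pileups(s, cfg, rng)
            out.append((t.focal, s.haplotypes.tobytes(), p.to_csv()))
        assert out[0] == out[1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            syn.SimConfig(seed=1, error_rate=1.5)
        with pytest.raises(ValueError):
            syn.SimConfig(seed=1, mean_depth=0)
        json_round = syn.SimConfig.from_json(syn.SimConfig(seed=4).to_json())
        assert json_round == syn.SimConfig(seed=4)
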