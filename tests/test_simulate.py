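"""Generators: Markov-chain backcrosses, survivor conditioning,
Balding-Nichols allele counts, beta-binomial ASE counts, gene panels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import encapmap as em
from encapmap.lof import classify_genome


class TestHaldane:
    def test_closed_form_values(self):
        assert em.haldane_recomb(0) == 0.0
        assert em.haldane_recomb(10_000) == pytest.approx(0.5, abs=1e-12)
        # 0.5 * (1 - e^-0.48)
        assert em.haldane_recomb(24) == pytest.approx(0.1906083, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            em.haldane_recomb(-1.0)

    @given(st.floats(0, 500), st.floats(0.01, 500))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, d, delta):
        assert em.haldane_recomb(d + delta) > em.haldane_recomb(d)


class TestBackcross:
    def test_marginal_het_frequency_half(self, fine_map):
        for seed in (1, 2, 3):
            cohort = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 10_000, seed=seed)
            freqs = (cohort.genotypes == em.HET).mean(axis=0)
            assert np.all(np.abs(freqs - 0.5) < 0.02)

    def test_null_penetrance_phenotype_independent(self, fine_map):
        """p_het == p_hom: marker-phenotype chi-square has mean ~ 1."""
        chis = []
        for seed in range(60):
            c = em.simulate_backcross(fine_map, 10.3, 0.5, 0.5, 300, seed=seed)
            y = c.phenotype
            g = c.genotypes[:, 4] == em.HET
            n11 = (g & y).sum(); n10 = (g & ~y).sum()
            n01 = (~g & y).sum(); n00 = (~g & ~y).sum()
            n = 300
            row1, row0 = n11 + n10, n01 + n00
            col1, col0 = n11 + n01, n10 + n00
            exp = np.array([row1 * col1, row1 * col0, row0 * col1, row0 * col0]) / n
            obs = np.array([n11, n10, n01, n00])
            chis.append(((obs - exp) ** 2 / exp).sum())
        assert np.mean(chis) == pytest.approx(1.0, abs=0.35)

    def test_complete_penetrance_survivors_all_het(self):
        gmap = em.GeneticMap("2", (("m1", 5.0), ("m2", 10.3), ("m3", 20.0)))
        cohort = em.simulate_backcross(gmap, 10.3, 1.0, 0.0, 10_000, seed=7)
        surv = cohort.survivors()
        assert np.all(surv.genotypes[:, 1] == em.HET)

    def test_survivor_fraction_matches_conditional_probability(self, fine_map):
        """P(HET | survive) = RR/(RR+1) at the causal locus; at distance d
        it follows the two-state mixture, checked against enumeration of
        the four (marker, causal) genotype cells."""
        rr = 3.21
        p_het, p_hom = 0.963, 0.3
        cohort = em.simulate_survivor_cohort(fine_map, 10.3, p_het, p_hom, 50_000, seed=3)
        # marker m4 at 9.545 cM, m12 at 27 cM
        for j in (3, 11):
            d = abs(fine_map.positions[j] - 10.3)
            r = em.haldane_recomb(d)
            # enumeration over (marker, causal) in {H,S}^2, prior 1/4 each
            num = den = 0.0
            for marker_het in (True, False):
                for causal_het in (True, False):
                    joint = 0.25 * ((1 - r) if marker_het == causal_het else r) * 2
                    surv = p_het if causal_het else p_hom
                    den += joint * surv
                    if marker_het:
                        num += joint * surv
            expected = num / den
            observed = (cohort.genotypes[:, j] == em.HET).mean()
            assert observed == pytest.approx(expected, abs=0.01)
        # at the causal-adjacent limit the closed form is RR/(RR+1)
        assert p_het / (p_het + p_hom) == pytest.approx(rr / (rr + 1), abs=0.01)

    def test_bitwise_reproducible(self, fine_map):
        a = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 500, seed=11)
        b = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 500, seed=11)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.phenotype, b.phenotype)

    def test_invalid_inputs(self, fine_map):
        with pytest.raises(ValueError):
            em.simulate_backcross(fine_map, 50.0, 0.9, 0.3, 10, seed=0)
        with pytest.raises(ValueError):
            em.simulate_backcross(fine_map, 10.3, 0.3, 0.9, 10, seed=0)


class TestPopulationCounts:
    def test_low_divergence_fst_near_zero(self):
        pc = em.simulate_population_counts(3, 500, 0.005, 200, seed=1)
        theta = em.wc_fst_sites(pc.counts, pc.called)
        assert abs(np.nanmean(theta)) < 0.02

    def test_fixed_difference(self):
        pc = em.simulate_population_counts(
            2, 5, 0.2, 50, ancestral_freqs=0.5,
            selected_sites=[(0, 0, 10.0), (0, 1, -10.0)], seed=2,
        )
        theta = em.wc_fst_sites(pc.counts, pc.called)
        assert theta[0] == pytest.approx(1.0)

    def test_simulation_self_consistency(self):
        """Mean per-site F_ST agrees between two independent replicates of
        the same generator configuration (brute-force re-simulation)."""
        a = em.simulate_population_counts(3, 1000, 0.1, 50, seed=10)
        b = em.simulate_population_counts(3, 1000, 0.1, 50, seed=20)
        ma = np.nanmean(em.wc_fst_sites(a.counts, a.called))
        mb = np.nanmean(em.wc_fst_sites(b.counts, b.called))
        assert ma == pytest.approx(mb, abs=0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            em.simulate_population_counts(1, 10, 0.1, 50, seed=0)
        with pytest.raises(ValueError):
            em.simulate_population_counts(2, 10, 1.5, 50, seed=0)
        with pytest.raises(ValueError):
            em.simulate_population_counts(2, 10, 0.1, 0, seed=0)


class TestAseCounts:
    def test_fraction_fold_algebra(self):
        t = em.simulate_ase_counts(34 / 35, 10_000, overdispersion=0.0, seed=5)
        cd = t[t.material == "cDNA"]
        f = cd.ref_count.sum() / (cd.ref_count.sum() + cd.alt_count.sum())
        assert f / (1 - f) == pytest.approx(34, rel=0.08)

    def test_no_bias_case_indistinguishable(self):
        t = em.simulate_ase_counts(0.5, 5000, overdispersion=0.0, seed=6)
        frac = lambda m: t[t.material == m].ref_count.sum() / (5000 * 4)
        _, _, p = em.welch_t_two_groups(
            t[t.material == "cDNA"].ref_count / 5000,
            t[t.material == "gDNA"].ref_count / 5000,
        )
        assert p > 0.01
        assert abs(frac("cDNA") - frac("gDNA")) < 0.03

    def test_overdispersion_inflates_variance(self):
        """Beta-binomial replicate fractions exceed binomial variance
        (variance formula: rho * f(1-f) between-replicate component)."""
        depth, f, rho = 2000, 0.7, 0.05
        fracs = []
        for s in range(100):
            t = em.simulate_ase_counts(f, depth, n_bio=1, n_tech=1, overdispersion=rho, seed=s)
            row = t[t.material == "cDNA"].iloc[0]
            fracs.append(row.ref_count / depth)
        binom_var = f * (1 - f) / depth
        expected_var = binom_var + rho * f * (1 - f)
        observed = np.var(fracs, ddof=1)
        assert observed > 3 * binom_var
        assert observed == pytest.approx(expected_var, rel=0.5)

    def test_gdna_fraction_half(self):
        t = em.simulate_ase_counts(0.97, 20_000, seed=8)
        gd = t[t.material == "gDNA"]
        f = gd.ref_count.sum() / (gd.ref_count.sum() + gd.alt_count.sum())
        assert f == pytest.approx(0.5, abs=0.02)


class TestGenePanel:
    def test_all_functional(self, gene):
        cds, up = gene
        genomes = em.simulate_gene_panel(
            cds, up, genome_count=30, class_frequencies={"functional": 1.0}, seed=1
        )
        for g in genomes:
            rec = classify_genome(g.variants, cds, up, g.genotyped_fraction, g.genome_id)
            assert rec.lof_class == "functional"

    def test_full_missingness_unscorable(self, gene):
        cds, up = gene
        genomes = em.simulate_gene_panel(cds, up, genome_count=20, missing_rate=1.0, seed=2)
        for g in genomes:
            rec = classify_genome(g.variants, cds, up, g.genotyped_fraction, g.genome_id)
            assert rec.lof_class == "unscorable"

    def test_zero_missingness_label_recovery(self, gene):
        cds, up = gene
        genomes = em.simulate_gene_panel(cds, up, genome_count=250, missing_rate=0.0, seed=3)
        for g in genomes:
            rec = classify_genome(g.variants, cds, up, g.genotyped_fraction, g.genome_id)
            assert rec.lof_class == g.truth_class

    def test_class_frequencies_must_sum_to_one(self, gene):
        cds, up = gene
        with pytest.raises(ValueError):
            em.simulate_gene_panel(cds, up, class_frequencies={"functional": 0.5}, seed=0)
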