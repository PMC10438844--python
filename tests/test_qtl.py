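"""Interval mapping, composite interval mapping and LOD support intervals."""

import numpy as np
import pytest

import encapmap as em
from encapmap.qtl import QTLScan, lod_support_interval


def _cohort(gmap, genotypes, phenotype):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    phenotype = np.asarray(phenotype, dtype=bool)
    return em.BackcrossCohort(gmap, genotypes, phenotype, np.ones(len(phenotype), bool))


class TestGenotypeProbabilities:
    def test_typed_marker_is_indicator(self, fine_map):
        cohort = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 50, seed=1)
        for j in (0, 5, 11):
            w = em.genotype_probabilities(cohort, fine_map.positions[j])
            assert np.array_equal(w, (cohort.genotypes[:, j] == em.HET).astype(float))

    def test_midpoint_of_discordant_flanks(self):
        gmap = em.GeneticMap("2", (("a", 0.0), ("b", 20.0)))
        c = _cohort(gmap, [[em.HET, em.HOM_S]], [True])
        assert em.genotype_probabilities(c, 10.0)[0] == pytest.approx(0.5)

    def test_asymmetric_flanks_match_enumeration(self):
        """5 cM from HET, 15 cM from HOM_S: brute-force enumeration of the
        transition products over the hidden state."""
        gmap = em.GeneticMap("2", (("a", 0.0), ("b", 20.0)))
        c = _cohort(gmap, [[em.HET, em.HOM_S]], [True])
        r1, r2 = em.haldane_recomb(5.0), em.haldane_recomb(15.0)
        num = (1 - r1) * r2          # HET at 0 -> HET at 5 -> HOM at 20
        den = num + r1 * (1 - r2)    # + HET -> HOM -> HOM
        assert em.genotype_probabilities(c, 5.0)[0] == pytest.approx(num / den, abs=1e-12)

    def test_missing_markers_marginalised(self):
        gmap = em.GeneticMap("2", (("a", 0.0), ("b", 10.0), ("c", 20.0)))
        # middle marker missing: probability at 10 must use markers a and c
        c = _cohort(gmap, [[em.HET, em.MISSING, em.HET]], [True])
        w = em.genotype_probabilities(c, 10.0)[0]
        r = em.haldane_recomb(10.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert w == pytest.approx(expected, abs=1e-12)
        # no informative markers at all -> 0.5
        c2 = _cohort(gmap, [[em.MISSING] * 3], [True])
        assert em.genotype_probabilities(c2, 10.0)[0] == 0.5


class TestIntervalMapping:
    def test_closed_form_complete_penetrance(self, two_marker_cohort):
        """Fully informative marker, 10/10 split: LOD = 20 log10 2."""
        scan = em.interval_mapping_binary(two_marker_cohort, step=0.5)
        at_marker = scan.score[np.argmin(np.abs(scan.positions - 0.0))]
        assert at_marker == pytest.approx(20 * np.log10(2), abs=1e-6)

    def test_lod_equals_2x2_table_closed_form(self, fine_map):
        """At a typed marker with complete data the EM LOD equals the
        closed-form binomial likelihood ratio of the 2x2 table."""
        cohort = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 300, seed=9)
        scan = em.interval_mapping_binary(cohort, step=5.0)
        for j in (2, 4, 8):
            pos = fine_map.positions[j]
            het = cohort.genotypes[:, j] == em.HET
            y = cohort.phenotype

            def bin_ll(k, n):
                if n == 0 or k == 0 or k == n:
                    return 0.0
                p = k / n
                return k * np.log(p) + (n - k) * np.log(1 - p)

            ll1 = bin_ll(y[het].sum(), het.sum()) + bin_ll(y[~het].sum(), (~het).sum())
            ll0 = bin_ll(y.sum(), len(y))
            expected = (ll1 - ll0) / np.log(10)
            got = scan.score[np.argmin(np.abs(scan.positions - pos))]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_null_mean_max_lod_small(self, fine_map):
        maxes = []
        for s in range(200):
            c = em.simulate_backcross(fine_map, 10.3, 0.6, 0.6, 200, seed=3000 + s)
            maxes.append(em.interval_mapping_binary(c, step=1.0).peak_score)
        assert np.mean(maxes) < 1.5

    def test_relabeling_invariance(self, fine_map):
        cohort = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 200, seed=4)
        flipped = em.BackcrossCohort(
            fine_map, cohort.genotypes, ~cohort.phenotype, cohort.survived
        )
        a = em.interval_mapping_binary(cohort, step=2.0)
        b = em.interval_mapping_binary(flipped, step=2.0)
        np.testing.assert_allclose(a.score, b.score, atol=1e-6)

    def test_monomorphic_phenotype_rejected(self, fine_map):
        c = em.simulate_backcross(fine_map, 10.3, 1.0, 1.0, 50, seed=0)
        with pytest.raises(ValueError):
            em.interval_mapping_binary(c)

    def test_support_interval_contains_peak(self, fine_map):
        cohort = em.simulate_backcross(fine_map, 10.3, 0.9, 0.2, 400, seed=5)
        scan = em.interval_mapping_binary(cohort, step=0.5)
        lo, hi = scan.support_interval
        assert lo <= scan.peak_position <= hi


class TestCompositeIntervalMapping:
    def test_single_qtl_peaks_coincide(self, fine_map):
        cohort = em.simulate_backcross(fine_map, 10.3, 0.95, 0.2, 400, seed=6)
        im = em.interval_mapping_binary(cohort, step=1.0)
        cim = em.composite_interval_mapping(cohort, step=1.0, window=10.0)
        assert abs(im.peak_position - cim.peak_position) <= 2.0

    def test_excluded_cofactor_reduces_to_interval_mapping(self, fine_map):
        """With the single cofactor excluded by the window, the CIM value at
        a typed complete-data marker equals the IM value."""
        cohort = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 250, seed=7)
        marker = fine_map.names[4]
        im = em.interval_mapping_binary(cohort, step=50.0)  # grid = markers only
        cim = em.composite_interval_mapping(
            cohort, step=50.0, cofactors=[marker], window=10.0
        )
        j = np.argmin(np.abs(im.positions - fine_map.positions[4]))
        assert cim.score[j] == pytest.approx(im.score[j], abs=1e-5)

    def test_two_linked_qtl_resolved(self):
        """Two causal loci 60 cM apart: CIM peaks land near both."""
        gmap = em.evenly_spaced_map(n_markers=17, start=0.0, end=80.0)
        from encapmap.simulate import _simulate_states

        hits = 0
        n_sims = 10
        for s in range(n_sims):
            rng = np.random.default_rng(500 + s)
            all_pos = np.sort(np.append(gmap.positions, [10.0, 70.0]))
            i1, i2 = np.searchsorted(all_pos, [10.0, 70.0])
            states = _simulate_states(rng, 800, all_pos)
            pen = 0.10 + 0.40 * states[:, i1] + 0.40 * states[:, i2]
            y = rng.random(800) < pen
            marker_cols = [k for k in range(len(all_pos)) if k not in (i1, i2)]
            cohort = em.BackcrossCohort(
                gmap, states[:, marker_cols], y, np.ones(800, bool)
            )
            scan = em.composite_interval_mapping(cohort, step=1.0, window=15.0)
            # local peaks: grid maxima above half the global peak
            sc = scan.score
            peaks = [
                scan.positions[k]
                for k in range(1, len(sc) - 1)
                if sc[k] >= sc[k - 1] and sc[k] >= sc[k + 1] and sc[k] > sc.max() / 2
            ]
            ok1 = any(abs(p - 10.0) <= 7.5 for p in peaks)
            ok2 = any(abs(p - 70.0) <= 7.5 for p in peaks)
            hits += ok1 and ok2
        assert hits >= 8

    def test_window_larger_than_span_rejected(self, fine_map):
        cohort = em.simulate_backcross(fine_map, 10.3, 0.9, 0.3, 100, seed=8)
        with pytest.raises(ValueError):
            em.composite_interval_mapping(cohort, window=100.0)


class TestLodSupportInterval:
    def test_single_point(self):
        scan = QTLScan(np.array([5.0]), np.array([3.0]), "IM")
        assert lod_support_interval(scan) == (5.0, 5.0)

    def test_triangular_profile(self):
        """Peak 5 at 10 cM, slope 0.5/cM: drop 1.5 crosses at 7 and 13."""
        pos = np.arange(0.0, 20.5, 0.5)
        score = 5.0 - 0.5 * np.abs(pos - 10.0)
        scan = QTLScan(pos, score, "IM")
        lo, hi = lod_support_interval(scan, drop=1.5)
        assert lo == pytest.approx(7.0)
        assert hi == pytest.approx(13.0)

    def test_interpolated_crossing(self):
        pos = np.array([0.0, 10.0, 20.0])
        score = np.array([0.0, 4.0, 0.0])
        lo, hi = lod_support_interval(QTLScan(pos, score, "IM"), drop=1.5)
        assert lo == pytest.approx(10 - 1.5 / 0.4)
        assert hi == pytest.approx(10 + 1.5 / 0.4)

    def test_monotone_profile_pinned_to_boundary(self):
        pos = np.arange(0.0, 10.0)
        scan = QTLScan(pos, 0.5 * pos, "IM")
        lo, hi = lod_support_interval(scan, drop=1.5)
        assert hi == pos[-1]
        assert lo == pytest.approx(pos[-1] - 3.0)

    def test_flat_scan_full_span_with_flag(self):
        scan = QTLScan(np.arange(5.0), np.ones(5), "IM")
        assert lod_support_interval(scan, 1.5) == (0.0, 4.0)
        assert scan.flat

    def test_widening_drop_never_shrinks(self):
        rng = np.random.default_rng(0)
        pos = np.arange(0.0, 30.0, 0.5)
        for _ in range(20):
            score = np.abs(np.cumsum(rng.normal(size=len(pos)))) / 3
            scan = QTLScan(pos, score, "IM")
            prev = lod_support_interval(scan, 0.5)
            for drop in (1.0, 1.5, 2.5):
                cur = lod_support_interval(scan, drop)
                assert cur[0] <= prev[0] + 1e-9 and cur[1] >= prev[1] - 1e-9
                prev = cur
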