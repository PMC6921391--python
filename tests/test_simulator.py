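"""Synthetic genotypes, count simulation and doublet injection."""

import numpy as np
import pytest

import poolsplit as ps
from poolsplit.simulator import (
    alt_read_probability,
    read_truth_tsv,
    write_truth_tsv,
)

from conftest import write_bam
from oracles import (
    sibling_concordance_probability,
    unrelated_concordance_probability,
)


class TestSynthDonorGenotypes:
    def test_hardy_weinberg_frequencies_within_3_sigma(self):
        """Genotype counts at fixed f=0.3 match HW(0.49, 0.42, 0.09)."""
        f = 0.3
        n = 10_000
        geno = ps.synth_donor_genotypes(
            1, n, np.random.default_rng(0),
            allele_freq_sampler=lambda n_snvs, rng: np.full(n_snvs, f))
        counts = np.bincount(geno.genotypes[0], minlength=3)
        for g, p in enumerate([(1 - f) ** 2, 2 * f * (1 - f), f**2]):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[g] - n * p) < 3 * sigma

    def test_forced_fixed_allele_gives_all_homozygous_alt(self):
        geno = ps.synth_donor_genotypes(
            4, 50, np.random.default_rng(1),
            allele_freq_sampler=lambda n, rng: np.ones(n))
        assert (geno.genotypes == 2).all()

    def test_gp_concentrated_on_true_genotype(self):
        geno = ps.synth_donor_genotypes(2, 100, np.random.default_rng(2))
        picked = geno.gp.argmax(axis=2)
        np.testing.assert_array_equal(picked, geno.genotypes)
        np.testing.assert_allclose(geno.gp.sum(axis=2), 1.0)


class TestSynthSiblingPair:
    def test_homozygous_parents_transmit_faithfully(self):
        """Monomorphic parents (f=0) can only produce RR offspring."""
        geno = ps.synth_sibling_pair(
            30, np.random.default_rng(3), parent_freqs=np.zeros(30))
        assert (geno.genotypes == 0).all()

    def test_empty_is_valid(self):
        geno = ps.synth_sibling_pair(0, np.random.default_rng(4))
        assert geno.n_snvs == 0 and geno.n_donors == 2

    def test_concordance_matches_enumeration_and_beats_unrelated(self):
        """Sibling genotype concordance at f=0.5 matches the closed-form
        enumeration within 3 sigma, and exceeds the unrelated baseline."""
        f, n = 0.5, 20_000
        geno = ps.synth_sibling_pair(
            n, np.random.default_rng(5), parent_freqs=np.full(n, f))
        observed = (geno.genotypes[0] == geno.genotypes[1]).mean()
        expected = sibling_concordance_probability(f)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * sigma
        assert observed > unrelated_concordance_probability(f)


class TestAltReadProbability:
    @pytest.mark.parametrize("gp,expected", [
        ((0.0, 0.0, 1.0), 1.0),   # certain AA: every read alt
        ((0.0, 1.0, 0.0), 0.5),   # certain het: half the reads alt
        ((1.0, 0.0, 0.0), 0.0),   # certain RR: no alt reads
        ((0.98, 0.01, 0.01), 0.015),
    ])
    def test_pointwise(self, gp, expected):
        assert alt_read_probability(np.array(gp)) == pytest.approx(expected)

    def test_unnormalized_likelihoods_renormalized(self):
        assert alt_read_probability(np.array([2.0, 2.0, 0.0])
                                    ) == pytest.approx(0.25)

    def test_het_donor_alt_fraction_within_3_sigma(self):
        """Aggregate alt fraction from a fully heterozygous donor matches
        the analytic allele probability over >=10,000 reads."""
        rng = np.random.default_rng(6)
        geno = ps.synth_donor_genotypes(1, 200, rng)
        geno.genotypes[:] = 1
        geno.gp[:] = [0.01, 0.98, 0.01]
        profile = ps.DepthProfile(mean_reads_per_cell=4000)
        m, _ = ps.simulate_counts(geno, 5, profile, rng)
        n_alt = m.alt.sum()
        n_tot = m.total().sum()
        assert n_tot >= 10_000
        p = alt_read_probability(np.array([0.01, 0.98, 0.01]))
        sigma = np.sqrt(n_tot * p * (1 - p))
        assert abs(n_alt - n_tot * p) < 3 * sigma


class TestSimulateCounts:
    def test_truth_covers_every_barcode(self):
        rng = np.random.default_rng(7)
        geno = ps.synth_donor_genotypes(3, 100, rng)
        m, truth = ps.simulate_counts(
            geno, 50, ps.DepthProfile(mean_reads_per_cell=100), rng)
        assert set(truth.barcode_to_donor) == set(m.barcodes)
        assert set(truth.barcode_to_donor.values()) <= set(geno.donors)

    def test_deterministic_given_seed(self):
        geno = ps.synth_donor_genotypes(2, 80, np.random.default_rng(8))
        prof = ps.DepthProfile(mean_reads_per_cell=200)
        m1, _ = ps.simulate_counts(geno, 30, prof, np.random.default_rng(9))
        m2, _ = ps.simulate_counts(geno, 30, prof, np.random.default_rng(9))
        assert (m1.alt != m2.alt).nnz == 0
        assert (m1.ref != m2.ref).nnz == 0


class TestInjectDoublets:
    def _pool(self, n_cells=100, seed=10):
        rng = np.random.default_rng(seed)
        geno = ps.synth_donor_genotypes(2, 200, rng)
        return ps.simulate_counts(
            geno, n_cells, ps.DepthProfile(mean_reads_per_cell=150), rng), rng

    def test_zero_fraction_unchanged(self):
        (m, truth), rng = self._pool()
        m2, t2 = ps.inject_doublets(m, truth, 0.0, rng)
        assert m2 is m and t2 is truth

    def test_three_percent_of_hundred(self):
        """100 cells at 3%: 97 columns remain, 3 marked DBL."""
        (m, truth), rng = self._pool()
        m2, t2 = ps.inject_doublets(m, truth, 0.03, rng)
        assert m2.n_cells == 97
        assert len(t2.doublets) == 3
        assert len(t2.barcode_to_donor) == 94
        labels = t2.labels()
        assert sum(1 for v in labels.values() if v == "DBL") == 3

    def test_counts_conserved_and_columns_sum(self):
        (m, truth), rng = self._pool()
        total_before = int(m.total().sum())
        m2, t2 = ps.inject_doublets(m, truth, 0.05, rng)
        assert int(m2.total().sum()) == total_before
        # each merged column equals the sum of its two source columns
        col_of = {bc: j for j, bc in enumerate(m.barcodes)}
        new_col = {bc: j for j, bc in enumerate(m2.barcodes)}
        for kept, merged, _pair in t2.doublets:
            expect = (m.alt[:, col_of[kept]] + m.alt[:, col_of[merged]])
            got = m2.alt[:, new_col[kept]]
            assert (got != expect).nnz == 0
            assert merged not in new_col

    def test_excessive_fraction_rejected(self):
        (m, truth), rng = self._pool()
        with pytest.raises(ps.errors.PoolsplitError):
            ps.inject_doublets(m, truth, 0.6, rng)

    def test_truth_tsv_round_trip(self, tmp_path):
        (m, truth), rng = self._pool()
        _, t2 = ps.inject_doublets(m, truth, 0.04, rng)
        path = tmp_path / "truth.tsv"
        write_truth_tsv(t2, str(path), header="test")
        back = read_truth_tsv(str(path))
        assert back.barcode_to_donor == t2.barcode_to_donor
        assert back.doublets == t2.doublets


class TestTemplateBamMode:
    def test_real_coverage_simulated_alleles(self, tmp_path):
        """Template reads keep their barcodes/positions; alleles follow the
        assigned donor's genotype likelihoods."""
        rng = np.random.default_rng(11)
        n_reads = 400
        barcodes = ["BC0", "BC1"]
        reads = [("chr1", 99, "A", "1M", barcodes[i % 2], 60, 0)
                 for i in range(n_reads)]
        bam = write_bam(tmp_path / "t.bam", reads)
        geno = ps.synth_donor_genotypes(2, 1, rng)
        geno.snv_ids = ["chr1:100"]
        geno.genotypes[:] = [[0], [2]]  # donor0 RR, donor1 AA
        geno.gp[0, 0] = [0.98, 0.01, 0.01]
        geno.gp[1, 0] = [0.01, 0.01, 0.98]
        snvs = [ps.SNVRecord("chr1", 100, "A", "C", 50.0)]
        m, truth = ps.simulate_counts_from_bam(bam, snvs, barcodes, geno,
                                               rng=rng)
        assert int(m.total().sum()) == n_reads
        for j, bc in enumerate(m.barcodes):
            donor = truth.barcode_to_donor[bc]
            frac = m.alt[0, j] / (m.alt[0, j] + m.ref[0, j])
            assert frac < 0.2 if donor == "donor0" else frac > 0.8
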