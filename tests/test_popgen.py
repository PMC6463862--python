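import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from askpoly import (GeneModel, HaplotypeAlignment, SnpRecord, SnpTable,
                     build_frame_map, classify_coding_snps, maf_spectrum,
                     nucleotide_diversity, segregating_sites, summarize_region,
                     tajima_significance, tajimas_d, watterson_theta)
from askpoly.popgen import TajimaConstants, tajima_d_beta_bounds

from conftest import brute_force_pi


def _aln(rows):
    return HaplotypeAlignment.from_sequences(
        "t", [(f"r{i}", s) for i, s in enumerate(rows)])


class TestSegregatingSites:
    def test_identical_rows_zero(self):
        assert segregating_sites(_aln(["ACGT", "ACGT", "ACGT"])) == 0

    def test_hand_counted_fixture(self, four_haplotype_alignment):
        assert segregating_sites(four_haplotype_alignment) == 3

    def test_column_with_missing_but_one_allele_not_segregating(self):
        assert segregating_sites(_aln(["A", "N", "A", "A"])) == 0

    def test_column_with_missing_and_two_alleles_segregating(self):
        assert segregating_sites(_aln(["A", "N", "C", "A"])) == 1

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            segregating_sites(_aln(["ACGT"]))


class TestNucleotideDiversity:
    def test_two_sequences(self):
        pi_locus, pi_site = nucleotide_diversity(
            _aln(["AAAAAAAAAA", "AACAAAACAA"]))
        assert pi_locus == 2.0 and pi_site == 0.2

    def test_hand_enumerated_fixture(self, four_haplotype_alignment):
        pi_locus, _ = nucleotide_diversity(four_haplotype_alignment)
        assert pi_locus == pytest.approx(10 / 6)

    def test_identical_rows_zero(self):
        assert nucleotide_diversity(_aln(["ACGT"] * 5)) == (0.0, 0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = rng.integers(2, 6)
            L = rng.integers(1, 9)
            mat = rng.choice(list("ACN"), size=(n, L))
            aln = HaplotypeAlignment("r", [f"s{i}" for i in range(n)], mat)
            pi_locus, _ = nucleotide_diversity(aln)
            assert pi_locus == pytest.approx(brute_force_pi(mat))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.text(alphabet="ACGTN", min_size=6, max_size=6),
                    min_size=2, max_size=5))
    def test_property_matches_brute_force(self, rows):
        aln = HaplotypeAlignment.from_sequences(
            "h", [(f"s{i}", r) for i, r in enumerate(rows)])
        pi_locus, pi_site = nucleotide_diversity(aln)
        assert pi_locus == pytest.approx(brute_force_pi(aln.matrix))
        assert 0.0 <= pi_site <= 1.0

    def test_invariant_under_row_permutation(self, four_haplotype_alignment):
        aln = four_haplotype_alignment
        perm = aln.subset(["d", "b", "a", "c"])
        assert nucleotide_diversity(perm) == nucleotide_diversity(aln)
        assert tajimas_d(perm) == tajimas_d(aln)


class TestWattersonTheta:
    def test_no_segregating_sites(self):
        assert watterson_theta(0, 10, 100) == (0.0, 0.0)

    def test_n_two_closed_form(self):
        assert watterson_theta(5, 2, 100)[0] == 5.0

    def test_harmonic_number_denominator(self):
        theta_locus, _ = watterson_theta(3, 4, 3)
        assert theta_locus == pytest.approx(3 / (1 + 1 / 2 + 1 / 3))


class TestTajimasD:
    def test_zero_when_pi_equals_theta(self):
        # n = 3 with both variants shared by the same pair of sequences:
        # pi_locus = 4/3 equals S/a1 = 2/1.5 exactly, so D = 0
        aln = _aln(["AAAAAAAAAA", "AACAAAACAA", "AAAAAAAAAA"])
        D, defined = tajimas_d(aln)
        assert defined and D == 0.0

    def test_sign_matches_pi_minus_theta(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            mat = rng.choice(list("ACGT"), size=(5, 12), p=[0.7, 0.1, 0.1, 0.1])
            aln = HaplotypeAlignment("r", [f"s{i}" for i in range(5)], mat)
            D, defined = tajimas_d(aln)
            if not defined:
                continue
            pi_locus, _ = nucleotide_diversity(aln)
            S = segregating_sites(aln)
            diff = pi_locus - S / TajimaConstants.from_n(5).a1
            assert np.sign(D) == np.sign(diff) or diff == 0

    def test_hand_computed_fixture(self, four_haplotype_alignment):
        D, defined = tajimas_d(four_haplotype_alignment)
        assert defined
        assert D == pytest.approx(0.168, abs=5e-4)

    def test_undefined_when_no_variation(self):
        D, defined = tajimas_d(_aln(["ACGT"] * 4))
        assert not defined and np.isnan(D)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(_aln(["AC", "AG"]))


class TestTajimaSignificance:
    def test_zero_never_significant(self):
        for n in (4, 10, 50, 500):
            assert not tajima_significance(0.0, n)

    def test_moderate_d_not_significant_for_large_n(self):
        for D in (-0.99, 0.5, 0.99):
            assert not tajima_significance(D, 500)

    def test_monotone_in_magnitude(self):
        n = 30
        sigs = [tajima_significance(d, n) for d in (-1.0, -1.5, -2.0, -2.5, -3.0)]
        # once significant, stays significant as |D| grows
        first = sigs.index(True) if True in sigs else len(sigs)
        assert all(sigs[first:])

    def test_bounds_significant(self):
        d_min, d_max, _, _ = tajima_d_beta_bounds(20)
        assert tajima_significance(d_min - 0.01, 20)
        assert tajima_significance(d_max + 0.01, 20)

    def test_quantiles_match_numeric_integration(self):
        # independent check of the beta approximation: integrate the density
        # over [Dmin, Dmax] numerically and compare tail masses at the
        # decision boundary found by bisection
        from scipy.stats import beta as beta_dist

        for n in (10, 50, 774):
            d_min, d_max, a_shape, b_shape = tajima_d_beta_bounds(n)
            const = (beta_dist(b_shape, a_shape).cdf(1.0) /
                     (d_max - d_min))

            def density(D):
                x = (D - d_min) / (d_max - d_min)
                return beta_dist(b_shape, a_shape).pdf(x) / (d_max - d_min)

            total, _ = quad(density, d_min, d_max)
            assert total == pytest.approx(1.0, abs=1e-6)
            # find the lower 2.5% point by bisection on the numeric integral
            lo, hi = d_min, d_max
            for _ in range(60):
                mid = (lo + hi) / 2
                mass, _ = quad(density, d_min, mid)
                lo, hi = (mid, hi) if mass < 0.025 else (lo, mid)
            q_low = (lo + hi) / 2
            assert tajima_significance(q_low - 1e-3, n)
            assert not tajima_significance(q_low + 1e-3, n)

    def test_unsupported_n_rejected(self):
        with pytest.raises(ValueError):
            tajima_significance(0.5, 3)


class TestSummarizeRegion:
    def test_consistency(self, four_haplotype_alignment):
        s = summarize_region(four_haplotype_alignment)
        assert (s.S, s.n, s.L) == (3, 4, 3)
        assert s.pi_locus == pytest.approx(10 / 6)
        assert s.theta_locus == pytest.approx(3 / TajimaConstants.from_n(4).a1)
        assert s.pi_site <= 1.0
        assert s.tajima_d == pytest.approx(0.168, abs=5e-4)
        assert not s.d_significant


class TestMafSpectrum:
    def _table(self, alt_counts, roster_size=20):
        records = []
        for site, count in enumerate(alt_counts, start=1):
            for i in range(count):
                records.append(SnpRecord("chr1", site, "A", "T", f"acc{i:03d}", 30))
        roster = [f"acc{i:03d}" for i in range(roster_size)]
        return SnpTable.from_records(records, roster=roster)

    def test_single_carrier_is_singleton(self):
        spec = maf_spectrum(self._table([1]))
        assert spec.singleton_fraction["all"] == 1.0

    def test_fraction_of_singletons(self):
        spec = maf_spectrum(self._table([1, 1, 1, 1, 5, 5, 6, 7, 8, 9]))
        assert spec.singleton_fraction["all"] == pytest.approx(0.4)
        assert spec.histogram.sum() == 10

    def test_minor_allele_folding(self):
        # 19 of 20 carriers: minor allele is the reference, count 1
        spec = maf_spectrum(self._table([19]))
        assert spec.minor_counts.iloc[0] == 1
        assert spec.singleton_fraction["all"] == 1.0

    def test_hand_counted_fixture_fraction(self):
        # minor counts (1, 2, 1) -> singleton fraction 2/3
        spec = maf_spectrum(self._table([1, 2, 3], roster_size=4))
        assert list(spec.minor_counts) == [1, 2, 1]
        assert spec.singleton_fraction["all"] == pytest.approx(2 / 3)

    def test_monomorphic_sites_excluded(self):
        spec = maf_spectrum(self._table([20, 1], roster_size=20))
        assert spec.n_excluded_monomorphic == 1
        assert len(spec.minor_counts) == 1

    def test_per_class_fractions(self):
        table = self._table([1, 1, 4, 6])
        classes = {("chr1", 1): "nonsynonymous", ("chr1", 2): "synonymous",
                   ("chr1", 3): "nonsynonymous", ("chr1", 4): "synonymous"}
        spec = maf_spectrum(table, classes=classes)
        assert spec.singleton_fraction["nonsynonymous"] == pytest.approx(0.5)
        assert spec.singleton_fraction["synonymous"] == pytest.approx(0.5)


class TestClassifyCodingSnps:
    CDS = "ATGCTGTGGTGA"  # M L W *
    GENE = GeneModel("g", "chr1", "+", 101, 112, ((101, 112),))

    def _classify(self, pos, ref, alt, strand="+", gene=None):
        gene = gene or self.GENE
        table = SnpTable.from_records(
            [SnpRecord("chr1", pos, ref, alt, "acc1", 30)], roster=["acc1"])
        fmap = build_frame_map(gene)
        return classify_coding_snps(table, self.CDS, fmap, strand=strand)

    def test_synonymous_leucine(self):
        row = self._classify(106, "G", "A").iloc[0]  # CTG -> CTA
        assert row.snp_class == "synonymous" and not row.nonsense

    def test_nonsynonymous_start_codon(self):
        row = self._classify(103, "G", "A").iloc[0]  # ATG -> ATA (M -> I)
        assert row.snp_class == "nonsynonymous" and not row.nonsense

    def test_stop_gain_flagged_nonsense(self):
        row = self._classify(109, "G", "A").iloc[0]  # TGG -> TGA (W -> *)
        assert row.snp_class == "nonsynonymous" and row.nonsense

    def test_minus_strand_alleles_complemented(self):
        # same CDS annotated on the minus strand: chromosomal alleles are
        # the reverse complement of the coding ones
        gene = GeneModel("g", "chr1", "-", 101, 112, ((101, 112),))
        table = SnpTable.from_records(
            [SnpRecord("chr1", 107, "C", "T", "acc1", 30)], roster=["acc1"])
        fmap = build_frame_map(gene)
        row = classify_coding_snps(table, self.CDS, fmap, strand="-").iloc[0]
        # chromosomal pos 107 maps to CDS index 5 (third base of CTG);
        # chromosomal C>T is coding G>A: CTG -> CTA, synonymous
        assert row.codon_ref == "CTG" and row.snp_class == "synonymous"

    def test_position_outside_frame_map_raises(self):
        with pytest.raises(ValueError):
            self._classify(99, "A", "T")
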