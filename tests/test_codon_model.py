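import numpy as np
import pytest

from pinnevo import genetic_code as gc
from pinnevo.codon_selection import (
    CodonFreqs,
    CodonLikelihood,
    build_f3x4,
    codon_rate_matrix,
    syn_nonsyn_flux,
)
from pinnevo.errors import DegenerateInputError, InvalidParameterError
from pinnevo.io_formats import CodonAlignment, LabeledTree


class TestF3x4:
    def test_point_mass(self):
        aln = CodonAlignment("g", ["a", "b"], ["ATGATG", "ATGATG"])
        fr = build_f3x4(aln)
        # positional floors leave a whisker of mass off ATG
        assert fr.pi[gc.CODON_INDEX["ATG"]] > 0.999
        assert fr.pi.sum() == pytest.approx(1.0)

    def test_uniform_positions_give_uniform_codons(self):
        # AAA/CCC/GGG/TTT gives each nucleotide weight 1/4 at every position
        aln = CodonAlignment("g", ["a"], ["AAACCCGGGTTT"])
        fr = build_f3x4(aln)
        np.testing.assert_allclose(fr.pi, np.full(61, 1 / 61), atol=1e-9)

    def test_hand_counted_positions(self):
        # 2 taxa x 3 codons = 6 codons: position 1 sees A,A,G / A,A,G
        aln = CodonAlignment("g", ["a", "b"], ["ATGAAAGGG", "ATGAAAGGG"])
        fr = build_f3x4(aln)
        # position 1: 4 A's, 2 G's of 6
        assert fr.position_freqs[0, 0] == pytest.approx(4 / 6, abs=1e-4)
        assert fr.position_freqs[0, 2] == pytest.approx(2 / 6, abs=1e-4)

    def test_gaps_excluded_from_counts(self):
        a = build_f3x4(CodonAlignment("g", ["a", "b"], ["ATG---", "ATG---"]))
        b = build_f3x4(CodonAlignment("g", ["a", "b"], ["ATG", "ATG"]))
        np.testing.assert_allclose(a.pi, b.pi)

    def test_all_gaps_degenerate(self):
        with pytest.raises(DegenerateInputError):
            build_f3x4(CodonAlignment("g", ["a"], ["---"]))


@pytest.fixture
def uniform_freqs() -> CodonFreqs:
    return CodonFreqs(pi=np.full(61, 1 / 61), position_freqs=np.full((3, 4), 0.25))


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous(self, uniform_freqs):
        Q = codon_rate_matrix(uniform_freqs, 2.0, 0.0, scale=False)
        i, j = gc.CODON_INDEX["ATG"], gc.CODON_INDEX["ATA"]  # M -> I
        assert Q[i, j] == 0.0
        i, j = gc.CODON_INDEX["AAA"], gc.CODON_INDEX["AAG"]  # K -> K synonymous
        assert Q[i, j] > 0.0

    def test_detailed_balance(self, toy_codon_alignment):
        fr = build_f3x4(toy_codon_alignment)
        Q = codon_rate_matrix(fr, 2.3, 0.7)
        flux = fr.pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-14)

    def test_rows_sum_to_zero(self, uniform_freqs):
        Q = codon_rate_matrix(uniform_freqs, 1.5, 0.4)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_unit_scaling_matches_direct_summation(self, uniform_freqs):
        """Scaled generator has unit expected rate; oracle sums all fluxes."""
        Q = codon_rate_matrix(uniform_freqs, 1.0, 1.0)
        total = sum(
            uniform_freqs.pi[i] * Q[i, j]
            for i in range(61)
            for j in range(61)
            if i != j
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_flux_decomposition_totals(self, uniform_freqs):
        kappa, omega = 2.0, 0.5
        a_s, a_n = syn_nonsyn_flux(uniform_freqs, kappa)
        Q = codon_rate_matrix(uniform_freqs, kappa, omega, scale=False)
        total = -np.dot(uniform_freqs.pi, np.diag(Q))
        assert a_s + omega * a_n == pytest.approx(total, rel=1e-12)

    @pytest.mark.parametrize("kappa,omega", [(-1, 0.5), (0, 0.5), (2, -0.1)])
    def test_domain_errors(self, uniform_freqs, kappa, omega):
        with pytest.raises(InvalidParameterError):
            codon_rate_matrix(uniform_freqs, kappa, omega)


class TestPruning:
    def test_single_leaf_equals_log_pi(self, toy_codon_alignment):
        aln = CodonAlignment("g", ["A"], [toy_codon_alignment.rows[0]])
        tree = LabeledTree.from_newick("A;")
        cl = CodonLikelihood(tree, aln)
        site = cl.expand(cl.pattern_loglik(2.0, 0.5, 0.5, cl.input_lengths))
        expected = [
            np.log(cl.freqs.pi[gc.CODON_INDEX[c]])
            for c in gc.codons_of(aln.rows[0])
        ]
        np.testing.assert_allclose(site, expected, atol=1e-12)

    def test_site_independence_duplication(self, star_tree):
        aln1 = CodonAlignment("g", ["A", "B", "C"], ["ATG", "ATA", "ATG"])
        aln2 = CodonAlignment("g", ["A", "B", "C"], ["ATGATG", "ATAATA", "ATGATG"])
        fr = build_f3x4(aln1)
        cl1 = CodonLikelihood(star_tree, aln1, fr)
        cl2 = CodonLikelihood(star_tree, aln2, fr)
        l1 = cl1.total(cl1.pattern_loglik(2.0, 0.5, 0.5, cl1.input_lengths))
        l2 = cl2.total(cl2.pattern_loglik(2.0, 0.5, 0.5, cl2.input_lengths))
        assert l2 == pytest.approx(2 * l1, abs=1e-9)

    def test_rerooting_invariance(self, toy_codon_alignment):
        """A reversible model gives the same lnL from any rooting."""
        t1 = LabeledTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")
        # same unrooted tree, rooted on the A branch instead
        t2 = LabeledTree.from_newick("(A:0.05,(B:0.2,C:0.45):0.05);")
        fr = build_f3x4(toy_codon_alignment)
        vals = []
        for t in (t1, t2):
            cl = CodonLikelihood(t, toy_codon_alignment, fr)
            vals.append(cl.total(cl.pattern_loglik(2.0, 0.5, 0.5, cl.input_lengths)))
        assert vals[0] == pytest.approx(vals[1], abs=1e-9)

    def test_gap_codon_is_missing_data(self):
        """A fully gapped partner leaf reduces to the stationary probability."""
        aln = CodonAlignment("g", ["A", "B"], ["ATG", "---"])
        tree = LabeledTree.from_newick("(A:0.1,B:0.2);")
        fr = CodonFreqs(pi=np.full(61, 1 / 61),
                        position_freqs=np.full((3, 4), 0.25))
        cl = CodonLikelihood(tree, aln, fr)
        site = cl.expand(cl.pattern_loglik(2.0, 0.5, 0.5, cl.input_lengths))
        assert site[0] == pytest.approx(np.log(1 / 61), abs=1e-10)

    def test_stop_codon_in_data_treated_as_missing(self):
        aln = CodonAlignment("g", ["A", "B"], ["ATGTAA", "ATGAAA"])
        tree = LabeledTree.from_newick("(A:0.1,B:0.2);")
        cl = CodonLikelihood(tree, aln)
        assert np.isfinite(
            cl.total(cl.pattern_loglik(2.0, 0.5, 0.5, cl.input_lengths))
        )
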