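import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinnevo.errors import InvalidParameterError, TaxonMismatchError
from pinnevo.io_formats import LabeledTree, ProteinAlignment
from pinnevo.sitewise_support import (
    SSLSProfile,
    delta_ssls,
    protein_freqs,
    select_top_fraction,
    site_loglik_protein,
)
from pinnevo.synthetic_data import (
    SimSpec,
    marine_monophyly_tree,
    simulate_alignment,
    species_tree,
)


class TestSiteLoglik:
    def test_single_leaf_equals_log_freq(self):
        aln = ProteinAlignment("g", ["A"], ["MKW"])
        tree = LabeledTree.from_newick("A;")
        lnl = site_loglik_protein(tree, aln, optimize_branch_lengths=False)
        f = protein_freqs(aln)
        from pinnevo.genetic_code import AA_INDEX

        expected = [np.log(f[AA_INDEX[a]]) for a in "MKW"]
        np.testing.assert_allclose(lnl, expected, atol=1e-12)

    def test_all_gap_column_is_zero(self, toy_protein_alignment):
        rows = [r[:1] + "-" + r[2:] for r in toy_protein_alignment.rows]
        aln = ProteinAlignment("g", toy_protein_alignment.taxa, rows)
        tree = LabeledTree.from_newick("(A:0.3,B:0.5,C:0.2);")
        lnl = site_loglik_protein(tree, aln, optimize_branch_lengths=False)
        assert lnl[1] == pytest.approx(0.0, abs=1e-12)


class TestDeltaSsls:
    def test_identical_topologies_give_zero(self, toy_protein_alignment):
        t = LabeledTree.from_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        prof = delta_ssls(t, t.copy(), toy_protein_alignment)
        np.testing.assert_allclose(prof.delta, 0.0, atol=1e-6)

    def test_taxon_mismatch_rejected(self, toy_protein_alignment):
        t0 = LabeledTree.from_newick("((A:1,B:1):1,C:1);")
        t1 = LabeledTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(TaxonMismatchError):
            delta_ssls(t0, t1, toy_protein_alignment)

    def test_sum_identity(self):
        """Sum of per-site deltas equals the difference of total lnLs."""
        h0, h1 = species_tree(), marine_monophyly_tree()
        aln, prot, _ = simulate_alignment(
            SimSpec(tree=h0, n_codons=60, model="M0", omega=0.3, seed=7)
        )
        prof = delta_ssls(h0, h1, prot)
        assert prof.delta.sum() == pytest.approx(
            prof.site_lnL_h0.sum() - prof.site_lnL_h1.sum(), abs=1e-9
        )

    @pytest.mark.parametrize("sim_on,expect_positive", [("h0", True), ("h1", False)])
    def test_mean_delta_sign_follows_generating_topology(
        self, sim_on, expect_positive
    ):
        h0, h1 = species_tree(), marine_monophyly_tree()
        gen = h0 if sim_on == "h0" else h1
        aln, prot, _ = simulate_alignment(
            SimSpec(tree=gen, n_codons=150, model="M0", omega=0.8, seed=99)
        )
        prof = delta_ssls(h0, h1, prot)
        assert bool(prof.delta.mean() > 0) is expect_positive


class TestSelectTopFraction:
    def _profiles(self, sizes, deltas=None, rng=None):
        out = []
        for k, n in enumerate(sizes):
            d = (
                np.asarray(deltas[k])
                if deltas is not None
                else rng.normal(size=n)
            )
            out.append(
                SSLSProfile(f"g{k}", site_lnL_h0=d, site_lnL_h1=np.zeros(n))
            )
        return out

    def test_floor_rule_small(self, rng):
        top = select_top_fraction(self._profiles([100], rng=rng), 0.01)
        assert top.k_selected == 1

    def test_tie_break_order(self):
        profs = self._profiles([3, 3], deltas=[[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        top = select_top_fraction(profs, 0.5)
        assert top.k_selected == 3
        assert top.sites == [("g0", 1), ("g0", 2), ("g0", 3)]

    def test_fraction_domain(self, rng):
        with pytest.raises(InvalidParameterError):
            select_top_fraction(self._profiles([10], rng=rng), 0.0)

    def test_dsg_flagging(self):
        profs = self._profiles([2, 2], deltas=[[5.0, 4.0], [1.0, 0.0]])
        top = select_top_fraction(profs, 0.5)
        assert top.dsg_genes == {"g0"}

    @settings(max_examples=30, deadline=None)
    @given(
        sizes=st.lists(st.integers(min_value=1, max_value=40), min_size=1,
                       max_size=5),
        fraction=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_selected_count_is_floor(self, sizes, fraction):
        rng = np.random.default_rng(0)
        top = select_top_fraction(self._profiles(sizes, rng=rng), fraction)
        assert top.k_selected == math.floor(fraction * sum(sizes))
        assert len(top.sites) == top.k_selected
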