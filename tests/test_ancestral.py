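import pytest

from pinnevo.ancestral_substitutions import (
    CladeMap,
    classify_substitutions,
    intersect_rdu,
    joint_reconstruct,
)
from pinnevo.errors import TaxonMismatchError
from pinnevo.io_formats import LabeledTree, ProteinAlignment
from pinnevo.sitewise_support import TopSiteSet
from pinnevo.studies import joint_reconstruction_agreement
from pinnevo.synthetic_data import ALL_TAXA, species_tree


class TestJointReconstruct:
    def test_consensus_column(self):
        tree = LabeledTree.from_newick("((A:0.2,B:0.3):0.25,(C:0.15,D:0.4):0.1);")
        aln = ProteinAlignment("g", ["A", "B", "C", "D"], ["A", "A", "A", "A"])
        rec = joint_reconstruct(tree, aln, optimize_branch_lengths=False)
        for node, _ in rec.struct.postorder_internal:
            assert rec.state_at(node, 0) == "A"

    def test_matches_exhaustive_search(self):
        assert joint_reconstruction_agreement(seed=11, n_sites=25) == 1.0

    def test_near_zero_branches_prefer_majority(self):
        tree = LabeledTree.from_newick(
            "(A:0.000001,B:0.000001,C:0.000001);"
        )
        aln = ProteinAlignment("g", ["A", "B", "C"], ["K", "K", "L"])
        rec = joint_reconstruct(tree, aln, optimize_branch_lengths=False)
        assert rec.state_at(rec.struct.root, 0) == "K"

    def test_gapped_leaf_does_not_break(self):
        tree = LabeledTree.from_newick("((A:0.2,B:0.3):0.25,(C:0.15,D:0.4):0.1);")
        aln = ProteinAlignment("g", ["A", "B", "C", "D"], ["K", "-", "K", "K"])
        rec = joint_reconstruct(tree, aln, optimize_branch_lengths=False)
        assert rec.state_at(rec.struct.root, 0) == "K"


def _species_alignment(col: dict[str, str]) -> ProteinAlignment:
    """One-column alignment over the 12 mammals plus anchoring columns."""
    # pad with 30 invariant columns so +F and branch fits are sane
    rows = [col.get(t, "A") + "G" * 15 + "L" * 15 for t in ALL_TAXA]
    return ProteinAlignment("g", list(ALL_TAXA), rows)


PINS = ("spotted_seal", "northern_fur_seal", "steller_sea_lion")


class TestClassifySubstitutions:
    def _classify(self, col):
        tree = species_tree()
        aln = _species_alignment(col)
        rec = joint_reconstruct(tree, aln, optimize_branch_lengths=False)
        return classify_substitutions(rec, aln)[0]

    def test_pinniped_unique(self):
        call = self._classify({t: "V" for t in PINS})
        assert call.category == "unique"
        assert call.clade_states["pinnipeds"] == "V"

    def test_residue_in_other_mammal_blocks_unique(self):
        call = self._classify({**{t: "V" for t in PINS}, "mouse": "V"})
        assert call.category == "none"

    def test_parallel_in_three_marine_clades(self):
        col = {t: "V" for t in PINS}
        col.update(dolphin="V", minke_whale="V", manatee="V")
        call = self._classify(col)
        assert call.category == "parallel"

    def test_gap_in_clade_member_does_not_veto(self):
        col = {**{t: "V" for t in PINS}}
        col["spotted_seal"] = "-"
        assert self._classify(col).category == "unique"

    def test_strict_mode_requires_full_observation(self):
        tree = species_tree()
        col = {**{t: "V" for t in PINS}, "mouse": "-"}
        aln = _species_alignment(col)
        rec = joint_reconstruct(tree, aln, optimize_branch_lengths=False)
        strict = classify_substitutions(rec, aln, strict=True)[0]
        assert strict.category == "none"

    def test_taxon_order_invariance(self):
        tree = species_tree()
        col = {t: "V" for t in PINS}
        aln = _species_alignment(col)
        rec = joint_reconstruct(tree, aln, optimize_branch_lengths=False)
        cats = [c.category for c in classify_substitutions(rec, aln)]
        order = list(reversed(aln.taxa))
        aln2 = ProteinAlignment("g", order,
                                [aln.row(t) for t in order])
        rec2 = joint_reconstruct(tree, aln2, optimize_branch_lengths=False)
        cats2 = [c.category for c in classify_substitutions(rec2, aln2)]
        assert cats == cats2

    def test_unknown_clade_taxon_rejected(self):
        tree = species_tree()
        aln = _species_alignment({})
        rec = joint_reconstruct(tree, aln, optimize_branch_lengths=False)
        bad = CladeMap(clades={"pinnipeds": ("nessie",)},
                       sisters={"pinnipeds": "dog"})
        with pytest.raises(TaxonMismatchError):
            classify_substitutions(rec, aln, bad)


class TestIntersectRdu:
    def _top(self, sites):
        return TopSiteSet(fraction=0.01, k_selected=len(sites), sites=sites,
                          dsg_genes={g for g, _ in sites})

    def _unique_call(self, gene, site):
        from pinnevo.ancestral_substitutions import SubstitutionCall

        return SubstitutionCall(gene, site, "unique", {}, {}, {})

    def test_matching_position_reported(self):
        rep = intersect_rdu({"g1"}, self._top([("g1", 10)]),
                            [self._unique_call("g1", 10)])
        assert rep.final_genes == ["g1"]

    def test_position_mismatch_excluded(self):
        rep = intersect_rdu({"g1"}, self._top([("g1", 10)]),
                            [self._unique_call("g1", 11)])
        assert rep.final_genes == []

    def test_non_reg_excluded(self):
        rep = intersect_rdu(set(), self._top([("g1", 10)]),
                            [self._unique_call("g1", 10)])
        assert rep.final_genes == []
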