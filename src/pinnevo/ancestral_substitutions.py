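"""Joint ancestral reconstruction and unique/parallel substitution calls.

Ancestral amino-acid states are reconstructed by the *joint* maximum-
probability method (Pupko-style max-product dynamic programming over the
tree under JTT+F, with branch lengths re-optimized per gene), i.e. the
single assignment of states to all internal nodes that maximizes the joint
probability of the full column.

Substitution categories, evaluated per residue column:

unique (to the focal clade, pinnipeds by default)
    every observed member of the focal clade carries the same residue r,
    r differs from the reconstructed state at the clade's ancestral node
    (the MRCA of the clade with its terrestrial sister, e.g. pinnipeds+dog),
    and r is observed in no other taxon of the alignment;
parallel
    all three marine clades carry one identical residue r, and r differs
    from the reconstructed state at each clade's own ancestral node
    (again the MRCA with the respective terrestrial sister: dog for
    pinnipeds, cow for cetaceans, elephant for sirenians).

Leaves with a gap or X are uninformative: they neither support nor veto a
call (strict mode requires every taxon observed instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genetic_code as gc

from ._pruning import TreeStructure, leaf_state_matrix
from .errors import TaxonMismatchError
from .io_formats import LabeledTree, ProteinAlignment
from .sitewise_support import ProteinLikelihood, TopSiteSet
from .synthetic_data import MARINE_CLADES, TERRESTRIAL_SISTERS

# alphabetical tie-break permutation over the PAML-ordered alphabet
_ALPHA_PERM = np.argsort(list(gc.AMINO_ACIDS), kind="stable")
_NEG_INF = -1e30


@dataclass
class CladeMap:
    """Named marine clades, each with a terrestrial sister taxon.

    ``ancestral node`` of a clade always means the MRCA of the clade's taxa
    together with its terrestrial sister.
    """

    clades: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in MARINE_CLADES.items()}
    )
    sisters: dict[str, str] = field(
        default_factory=lambda: dict(TERRESTRIAL_SISTERS)
    )
    focal: str = "pinnipeds"

    def validate_against(self, taxa: list[str]) -> None:
        known = set(taxa)
        for name, members in self.clades.items():
            missing = set(members) - known
            if missing:
                raise TaxonMismatchError(
                    f"clade {name!r} names absent taxa {sorted(missing)}"
                )
            if self.sisters[name] not in known:
                raise TaxonMismatchError(
                    f"sister {self.sisters[name]!r} of clade {name!r} absent"
                )

    def marine_taxa(self) -> set[str]:
        return {t for members in self.clades.values() for t in members}


@dataclass
class AncestralReconstruction:
    """Joint max-probability states at every internal node, per site."""

    struct: TreeStructure
    node_states: np.ndarray  # (n_nodes, n_sites) indices into AMINO_ACIDS; -1 n/a
    joint_logprob: np.ndarray  # per site, log P of the full joint assignment
    tree: LabeledTree
    _node_of: dict = field(default_factory=dict, repr=False)

    def state_at(self, node_id: int, site: int) -> str:
        s = self.node_states[node_id, site]
        return gc.AMINO_ACIDS[s] if s >= 0 else "-"

    def mrca_node_id(self, taxa) -> int:
        key = tuple(sorted(taxa))
        if key not in self._node_of:
            node = self.tree.mrca(taxa)
            # map the dendropy node to its structure id via its leaf set
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            self._node_of[key] = self._id_by_leafset(frozenset(leaves))
        return self._node_of[key]

    def _id_by_leafset(self, leafset: frozenset) -> int:
        below: dict[int, set] = {
            i: {self.struct.taxa[i]} for i in range(self.struct.n_leaves)
        }
        for node, children in self.struct.postorder_internal:
            below[node] = set().union(*(below[c] for c in children))
        for i, s in below.items():
            if s == leafset:
                return i
        raise TaxonMismatchError(f"no node spans exactly {sorted(leafset)}")

    def ancestral_fastas(self) -> dict[str, str]:
        """Reconstructed sequences keyed by internal-node name ``nodeNN``."""
        out = {}
        for node, _ in self.struct.postorder_internal:
            out[f"node{node}"] = "".join(
                self.state_at(node, s) for s in range(self.node_states.shape[1])
            )
        return out


def _argmax_alpha(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Argmax with ties broken in alphabetical residue order."""
    reordered = np.take(values, _ALPHA_PERM, axis=axis)
    idx = np.argmax(reordered, axis=axis)
    return _ALPHA_PERM[idx]


def joint_reconstruct(
    tree: LabeledTree,
    aln: ProteinAlignment,
    optimize_branch_lengths: bool = True,
) -> AncestralReconstruction:
    """Joint (max-product) ancestral reconstruction under JTT+F.

    Branch lengths are first re-estimated for this gene on the fixed
    topology; the DP then finds, per site, the internal-state assignment of
    maximum joint probability.  Gapped leaves contribute a flat partial
    (the DP maximizes over their state).
    """
    pl = ProteinLikelihood(tree, aln)
    blens = (
        pl.optimize_branch_lengths()[0]
        if optimize_branch_lengths
        else pl.input_lengths
    )
    struct = pl.struct
    states = leaf_state_matrix(aln.rows, gc.AA_INDEX, 20, width=1)
    n_sites = aln.n_sites
    logP = {
        b: np.log(np.clip(pl.eig.transition_matrix(blens[b]), 1e-300, None))
        for b in struct.branch_ids
    }

    # C[v][site, parent_state] = max over v's subtree given parent state
    # B[v][site, parent_state] = argmax state of v itself
    C: dict[int, np.ndarray] = {}
    B: dict[int, np.ndarray] = {}
    for i in range(struct.n_leaves):
        if i == struct.root:
            continue
        idx = states[i]
        lp = logP[i]  # (parent_state, leaf_state)
        b_missing = _argmax_alpha(lp, axis=1)  # per parent state
        c_missing = np.take_along_axis(lp, b_missing[:, None], axis=1)[:, 0]
        obs = idx >= 0
        Ci = np.empty((n_sites, 20))
        Bi = np.empty((n_sites, 20), dtype=np.intp)
        Ci[~obs] = c_missing
        Bi[~obs] = b_missing
        Ci[obs] = lp[:, idx[obs]].T  # observed leaf: state fixed
        Bi[obs] = idx[obs][:, None]
        C[i], B[i] = Ci, Bi
    order = struct.postorder_internal
    for node, children in order:
        M = np.zeros((n_sites, 20))
        for c in children:
            M += C[c]
        if node == struct.root:
            root_scores = M + np.log(pl.freqs)[None, :]
            root_state = _argmax_alpha(root_scores, axis=1)
            joint_logprob = np.take_along_axis(
                root_scores, root_state[:, None], axis=1
            )[:, 0]
        else:
            sc = logP[node][None, :, :] + M[:, None, :]  # (site, parent, self)
            B[node] = _argmax_alpha(sc, axis=2)
            C[node] = np.take_along_axis(sc, B[node][:, :, None], axis=2)[:, :, 0]

    node_states = np.full((struct.n_nodes, n_sites), -1, dtype=np.intp)
    node_states[struct.root] = root_state
    for node, children in reversed(order):  # preorder: parents before children
        for c in children:
            if c < struct.n_leaves:
                continue  # leaves keep their observed states
            node_states[c] = np.take_along_axis(
                B[c], node_states[node][:, None], axis=1
            )[:, 0]
    return AncestralReconstruction(
        struct=struct,
        node_states=node_states,
        joint_logprob=joint_logprob,
        tree=tree,
    )


@dataclass
class SubstitutionCall:
    """Classification of one residue column."""

    gene_id: str
    site: int  # 1-based
    category: str  # "parallel" | "unique" | "none"
    clade_states: dict[str, str | None]
    ancestral_states: dict[str, str]
    outgroup_states: dict[str, str]


def _clade_residue(aln: ProteinAlignment, taxa, site: int,
                   strict: bool) -> str | None:
    """The single residue shared by a clade at ``site``; None if not shared."""
    seen = set()
    for t in taxa:
        a = aln.row(t)[site]
        if a in ("-", "X"):
            if strict:
                return None
            continue
        seen.add(a)
    if len(seen) != 1:
        return None
    return next(iter(seen))


def classify_substitutions(
    recon: AncestralReconstruction,
    aln: ProteinAlignment,
    clade_map: CladeMap | None = None,
    strict: bool = False,
) -> list[SubstitutionCall]:
    """Classify every site as parallel, unique (focal clade), or none."""
    clade_map = clade_map or CladeMap()
    clade_map.validate_against(aln.taxa)
    marine = clade_map.marine_taxa()
    focal_taxa = clade_map.clades[clade_map.focal]
    other_taxa = [t for t in aln.taxa if t not in focal_taxa]
    anc_node = {
        name: recon.mrca_node_id(tuple(members) + (clade_map.sisters[name],))
        for name, members in clade_map.clades.items()
    }
    calls = []
    for site in range(aln.n_sites):
        clade_res = {
            name: _clade_residue(aln, members, site, strict)
            for name, members in clade_map.clades.items()
        }
        anc_res = {
            name: recon.state_at(anc_node[name], site) for name in clade_map.clades
        }
        out_res = {
            t: aln.row(t)[site] for t in aln.taxa if t not in marine
        }
        if strict and any(a in ("-", "X") for a in out_res.values()):
            category = "none"
        else:
            shared = set(clade_res.values())
            parallel = (
                len(shared) == 1
                and None not in shared
                and all(
                    clade_res[name] != anc_res[name] for name in clade_map.clades
                )
            )
            r = clade_res[clade_map.focal]
            unique = (
                r is not None
                and r != anc_res[clade_map.focal]
                and all(
                    aln.row(t)[site] != r
                    for t in other_taxa
                    if aln.row(t)[site] not in ("-", "X")
                )
            )
            category = "parallel" if parallel else ("unique" if unique else "none")
        calls.append(
            SubstitutionCall(
                gene_id=aln.gene_id,
                site=site + 1,
                category=category,
                clade_states=clade_res,
                ancestral_states=anc_res,
                outgroup_states=out_res,
            )
        )
    return calls


@dataclass
class IntersectionReport:
    """REG genes whose top-dSSLS residues coincide with unique substitutions."""

    final_genes: list[str]
    matched_sites: dict[str, list[int]]  # gene -> 1-based positions
    unique_counts: dict[str, int]  # unique substitutions per gene (all genes)


def intersect_rdu(
    regs: set[str],
    top_sites: TopSiteSet,
    unique_calls: list[SubstitutionCall],
) -> IntersectionReport:
    """Genes in REGs with a top-fraction dSSLS residue at the same position
    as a unique substitution."""
    unique_positions = {
        (c.gene_id, c.site) for c in unique_calls if c.category == "unique"
    }
    unique_counts: dict[str, int] = {}
    for c in unique_calls:
        if c.category == "unique":
            unique_counts[c.gene_id] = unique_counts.get(c.gene_id, 0) + 1
    matched: dict[str, list[int]] = {}
    for g, pos in top_sites.sites:
        if g in regs and (g, pos) in unique_positions:
            matched.setdefault(g, []).append(pos)
    final = sorted(matched)
    return IntersectionReport(
        final_genes=final,
        matched_sites={g: sorted(v) for g, v in matched.items()},
        unique_counts=unique_counts,
    )
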