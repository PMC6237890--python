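"""Felsenstein pruning over an arbitrary finite state space.

Shared by the codon models (61 states) and the amino-acid models (20
states).  The tree is flattened once into postorder arrays; transition
matrices are supplied per branch by the caller, typically through the
eigendecomposition of a reversible generator.

Per-node rescaling keeps conditional likelihoods in floating range, so
alignments of any practical depth are safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, TaxonMismatchError
from .io_formats import LabeledTree


@dataclass
class TreeStructure:
    """Postorder-flattened tree against a fixed taxon order.

    Leaves occupy node ids ``0 .. n_leaves-1`` in the given taxon order;
    internal nodes follow, with the root last.
    """

    n_leaves: int
    n_nodes: int
    postorder_internal: list[tuple[int, list[int]]]  # (node id, child ids)
    edge_length: np.ndarray  # branch above each node; nan at root
    foreground: np.ndarray  # bool per node (branch above node)
    root: int
    taxa: list[str]

    @property
    def branch_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if i != self.root]


def build_structure(tree: LabeledTree, taxa: list[str]) -> TreeStructure:
    """Flatten ``tree`` with leaves ordered as in ``taxa``."""
    tree.check_taxa(taxa)
    leaf_id = {t: i for i, t in enumerate(taxa)}
    n_leaves = len(taxa)
    ids: dict = {}
    next_id = n_leaves
    postorder_internal = []
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            ids[nd] = leaf_id[nd.taxon.label]
        else:
            ids[nd] = next_id
            next_id += 1
            postorder_internal.append((ids[nd], [ids[c] for c in nd.child_nodes()]))
    n_nodes = next_id
    edge_length = np.full(n_nodes, np.nan)
    foreground = np.zeros(n_nodes, dtype=bool)
    for nd in tree.tree:
        i = ids[nd]
        if nd.parent_node is not None:
            edge_length[i] = nd.edge.length if nd.edge.length is not None else 0.0
        foreground[i] = bool(getattr(nd, "foreground", False))
    root = ids[tree.tree.seed_node]
    return TreeStructure(
        n_leaves=n_leaves,
        n_nodes=n_nodes,
        postorder_internal=postorder_internal,
        edge_length=edge_length,
        foreground=foreground,
        root=root,
        taxa=list(taxa),
    )


@dataclass
class EigenSystem:
    """Spectral form of a reversible generator Q with stationary ``pi``.

    ``P(t) = (A * exp(lam t)) @ B`` with ``A = D^-1/2 U``, ``B = U.T D^1/2``.
    """

    A: np.ndarray
    lam: np.ndarray
    B: np.ndarray
    pi: np.ndarray

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self.A * np.exp(self.lam * t)) @ self.B
        # eigendecomposition round-off can produce tiny negatives
        np.clip(P, 0.0, None, out=P)
        return P


def eigen_reversible(Q: np.ndarray, pi: np.ndarray) -> EigenSystem:
    """Eigendecompose a reversible generator via its symmetrized form."""
    sq = np.sqrt(pi)
    S = Q * (sq[:, None] / sq[None, :])
    S = 0.5 * (S + S.T)
    lam, U = np.linalg.eigh(S)
    if not np.all(np.isfinite(lam)):
        raise NumericalError("non-finite eigenvalues in generator decomposition")
    A = U / sq[:, None]
    B = U.T * sq[None, :]
    return EigenSystem(A=A, lam=lam, B=B, pi=pi)


def leaf_state_matrix(
    rows: list[str], state_of: dict[str, int], n_states: int, width: int = 1
) -> np.ndarray:
    """Integer state per (taxon, site); -1 encodes a missing/ambiguous state.

    ``width`` is the number of characters per site (3 for codons, 1 for
    amino acids).
    """
    n_sites = len(rows[0]) // width
    out = np.full((len(rows), n_sites), -1, dtype=np.intp)
    for i, r in enumerate(rows):
        for j in range(n_sites):
            out[i, j] = state_of.get(r[width * j : width * (j + 1)], -1)
    return out


def compress_patterns(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical site columns.

    Returns ``(patterns, weights, site_to_pattern)`` where ``patterns`` is
    (n_taxa, n_patterns); per-site quantities are recovered by indexing with
    ``site_to_pattern``.
    """
    patterns, inverse = np.unique(states, axis=1, return_inverse=True)
    weights = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)
    return patterns, weights, np.asarray(inverse)


def site_log_likelihoods(
    struct: TreeStructure,
    states: np.ndarray,
    edge_P: dict[int, np.ndarray],
    root_freqs: np.ndarray,
) -> np.ndarray:
    """Per-site (or per-pattern) log-likelihoods by postorder pruning.

    ``states`` is (n_leaves, n_sites) with -1 for missing; gaps/N therefore
    contribute a partial likelihood of ones (sum over states).
    """
    if states.shape[0] != struct.n_leaves:
        raise TaxonMismatchError(
            f"state matrix has {states.shape[0]} rows, tree has "
            f"{struct.n_leaves} leaves"
        )
    n_sites = states.shape[1]
    n_states = root_freqs.shape[0]
    if not struct.postorder_internal:  # single-leaf tree: lnL = log pi(state)
        idx = states[struct.root]
        lik = np.where(idx >= 0, root_freqs[np.clip(idx, 0, None)], 1.0)
        return np.log(lik)
    partial: list[np.ndarray | None] = [None] * struct.n_nodes
    log_scale = np.zeros(n_sites)
    n_internal_done = 0
    for node, children in struct.postorder_internal:
        L = None
        for c in children:
            P = edge_P[c]
            if c < struct.n_leaves:
                idx = states[c]
                if idx.min() >= 0:
                    contrib = P.T[idx]
                else:
                    contrib = np.where((idx >= 0)[:, None],
                                       P.T[np.clip(idx, 0, None)], 1.0)
            else:
                contrib = partial[c] @ P.T
                partial[c] = None
            L = contrib if L is None else L.__imul__(contrib)
        n_internal_done += 1
        # periodic rescaling is enough: a few levels of un-rescaled products
        # stay far from double underflow
        if n_internal_done % 4 == 0:
            scale = L.max(axis=1)
            # an all-gap column scales to 1 (likelihood 1, lnL 0)
            safe = np.where(scale > 0, scale, 1.0)
            L /= safe[:, None]
            log_scale += np.log(safe)
        partial[node] = L
    site_lik = partial[struct.root] @ root_freqs
    with np.errstate(divide="ignore"):
        out = np.log(site_lik) + log_scale
    if not np.all(np.isfinite(out)):
        raise NumericalError("non-finite site log-likelihood")
    return out
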