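"""Site-wise log-likelihood support (SSLS) under two competing topologies.

For every residue of a protein alignment the log-likelihood is computed
under the species tree (H0) and under an alternative constraint topology
(H1, marine-mammal monophyly), with branch lengths optimized per gene and
per topology under JTT (+F: frequencies re-estimated from the gene's own
alignment).  The per-residue difference

    dSSLS = lnL(H0) - lnL(H1)

is positive where a site fits the species tree better (divergence) and
negative where it favours the alternative (convergence).  Residues in the
genome-wide top fraction (default 1%) of dSSLS define the divergent
substitution genes (DSGs).

Rate homogeneity across sites is the default; a 4-category discrete-gamma
model is available via ``gamma_categories``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from . import genetic_code as gc
from ._pruning import (
    build_structure,
    compress_patterns,
    eigen_reversible,
    leaf_state_matrix,
    site_log_likelihoods,
)
from .errors import InvalidParameterError, TaxonMismatchError
from .io_formats import LabeledTree, ProteinAlignment
from .jtt import JTT_FREQS, jtt_exchangeabilities

_FREQ_FLOOR = 1e-6


def protein_freqs(aln: ProteinAlignment, plus_f: bool = True) -> np.ndarray:
    """Amino-acid frequencies: empirical (+F, floored) or the JTT defaults."""
    if not plus_f:
        return JTT_FREQS / JTT_FREQS.sum()
    counts = np.zeros(20)
    for row in aln.rows:
        for a in row:
            i = gc.AA_INDEX.get(a)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise InvalidParameterError("alignment has no countable residues")
    f = np.clip(counts / counts.sum(), _FREQ_FLOOR, None)
    return f / f.sum()


def protein_rate_matrix(freqs: np.ndarray) -> np.ndarray:
    """JTT generator with the given frequencies, scaled to unit mean rate."""
    S = jtt_exchangeabilities()
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rho = -np.dot(freqs, np.diag(Q))
    return Q / rho


def _gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Median discrete-gamma rates (k categories), normalized to mean 1."""
    q = (2 * np.arange(k) + 1) / (2 * k)
    r = gamma_dist.ppf(q, alpha, scale=1.0 / alpha)
    return r / r.mean()


class ProteinLikelihood:
    """Per-gene JTT(+F) likelihood evaluator on a fixed topology."""

    def __init__(
        self,
        tree: LabeledTree,
        aln: ProteinAlignment,
        plus_f: bool = True,
        gamma_categories: int = 1,
        alpha: float = 0.5,
    ):
        self.struct = build_structure(tree, aln.taxa)
        states = leaf_state_matrix(aln.rows, gc.AA_INDEX, 20, width=1)
        self.patterns, self.weights, self.site_map = compress_patterns(states)
        self.freqs = protein_freqs(aln, plus_f=plus_f)
        self.eig = eigen_reversible(protein_rate_matrix(self.freqs), self.freqs)
        self.gamma_categories = gamma_categories
        self.alpha = alpha
        self.input_lengths = np.nan_to_num(self.struct.edge_length, nan=0.0)

    def _rates(self) -> np.ndarray:
        if self.gamma_categories <= 1:
            return np.array([1.0])
        return _gamma_rates(self.alpha, self.gamma_categories)

    def pattern_loglik(self, branch_lengths: np.ndarray) -> np.ndarray:
        rates = self._rates()
        comp = []
        for r in rates:
            edge_P = {
                b: self.eig.transition_matrix(r * branch_lengths[b])
                for b in self.struct.branch_ids
            }
            comp.append(
                site_log_likelihoods(self.struct, self.patterns, edge_P, self.freqs)
            )
        if len(comp) == 1:
            return comp[0]
        return logsumexp(np.vstack(comp), axis=0, b=1.0 / len(comp))

    def optimize_branch_lengths(
        self, maxiter: int = 200
    ) -> tuple[np.ndarray, float]:
        """ML branch lengths (per branch) for this gene; returns (lengths, lnL)."""
        ids = self.struct.branch_ids
        x0 = np.log(np.maximum(self.input_lengths[ids], 1e-3))
        bounds = [(-9.0, 2.5)] * len(ids)
        x0 = np.clip(x0, -9.0, 2.5)

        def nll(x: np.ndarray) -> float:
            blens = np.zeros_like(self.input_lengths)
            blens[ids] = np.exp(x)
            return -float(np.dot(self.weights, self.pattern_loglik(blens)))

        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter})
        blens = np.zeros_like(self.input_lengths)
        blens[ids] = np.exp(res.x)
        return blens, -float(res.fun)

    def site_loglik(self, branch_lengths: np.ndarray | None = None) -> np.ndarray:
        if branch_lengths is None:
            branch_lengths = self.input_lengths
        return self.pattern_loglik(branch_lengths)[self.site_map]


def site_loglik_protein(
    tree: LabeledTree,
    aln: ProteinAlignment,
    optimize_branch_lengths: bool = True,
    plus_f: bool = True,
    gamma_categories: int = 1,
) -> np.ndarray:
    """Per-site lnL of ``aln`` on ``tree`` under JTT(+F).

    Branch lengths are re-estimated for this gene on the fixed topology
    unless ``optimize_branch_lengths`` is False (then the tree's own lengths
    are used).  All-gap columns carry lnL = 0.
    """
    pl = ProteinLikelihood(tree, aln, plus_f=plus_f,
                           gamma_categories=gamma_categories)
    blens = pl.optimize_branch_lengths()[0] if optimize_branch_lengths else None
    return pl.site_loglik(blens)


@dataclass
class SSLSProfile:
    """Per-residue log-likelihoods under H0 and H1 and their difference."""

    gene_id: str
    site_lnL_h0: np.ndarray
    site_lnL_h1: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.site_lnL_h0 - self.site_lnL_h1

    @property
    def n_sites(self) -> int:
        return self.site_lnL_h0.shape[0]


def delta_ssls(
    tree_h0: LabeledTree,
    tree_h1: LabeledTree,
    aln: ProteinAlignment,
    optimize_branch_lengths: bool = True,
    gamma_categories: int = 1,
) -> SSLSProfile:
    """Site-wise likelihood support of H0 over H1 for one gene.

    Branch lengths are optimized independently under each topology.
    """
    if set(tree_h0.taxa) != set(tree_h1.taxa):
        raise TaxonMismatchError("H0 and H1 must cover the same taxa")
    l0 = site_loglik_protein(tree_h0, aln, optimize_branch_lengths,
                             gamma_categories=gamma_categories)
    l1 = site_loglik_protein(tree_h1, aln, optimize_branch_lengths,
                             gamma_categories=gamma_categories)
    return SSLSProfile(gene_id=aln.gene_id, site_lnL_h0=l0, site_lnL_h1=l1)


@dataclass
class TopSiteSet:
    """The top-fraction dSSLS residues across all genes."""

    fraction: float
    k_selected: int
    sites: list[tuple[str, int]]  # (gene_id, 1-based position), rank order
    dsg_genes: set[str]

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._site_set

    @property
    def _site_set(self) -> set[tuple[str, int]]:
        if not hasattr(self, "_cached_set"):
            self._cached_set = set(self.sites)
        return self._cached_set


def select_top_fraction(
    profiles: list[SSLSProfile], fraction: float = 0.01
) -> TopSiteSet:
    """Rank all residues by dSSLS and keep the top ``floor(fraction * N)``.

    Ties at the cut are broken lexicographically by (gene_id, position),
    so the selection is deterministic.
    """
    if not (0 < fraction <= 1):
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    entries = [
        (float(p.delta[i]), p.gene_id, i + 1)
        for p in profiles
        for i in range(p.n_sites)
    ]
    if not entries:
        raise InvalidParameterError("no residues to rank")
    k = math.floor(fraction * len(entries))
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    chosen = [(g, pos) for _, g, pos in entries[:k]]
    return TopSiteSet(
        fraction=fraction,
        k_selected=k,
        sites=chosen,
        dsg_genes={g for g, _ in chosen},
    )
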