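"""Simulation of codon/protein alignments along the 12-mammal study tree.

The default topology mirrors the species tree used throughout the package:
opossum outgroup; afrotherians (elephant, manatee); euarchontoglires
(human, mouse); laurasiatherians with carnivores (dog sister to the three
pinnipeds: spotted seal, northern fur seal, Steller sea lion) and
cetartiodactyls (cow sister to dolphin + minke whale).  Marine mammals fall
in three independent clades: pinnipeds, cetaceans (dolphin, minke whale),
and sirenians (manatee).

Sequences evolve site-independently under the GY94 machinery of
:mod:`pinnevo.codon_selection`: root codons are drawn from the stationary
frequencies and propagated along branches with transition matrices of the
chosen model (M0, branch, or branch-site A, whose site classes are drawn
per site).  Known amino-acid substitution patterns can then be *planted*:
a chosen residue is written (as the lexicographically first synonymous
codon) into every member of a chosen taxon set at a chosen site, giving
ground truth for the substitution-classification stages.

Default branch lengths are 0.05 within the pinniped and cetacean clades
and 0.2 on all deeper branches — informative but far from saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import genetic_code as gc
from ._pruning import build_structure
from .codon_selection import (
    BranchSiteParams,
    CodonFreqs,
    branch_site_rate_factors,
    codon_rate_matrix,
)
from .errors import InvalidParameterError
from .io_formats import CodonAlignment, LabeledTree, ProteinAlignment
from scipy.linalg import expm

PINNIPEDS = ("spotted_seal", "northern_fur_seal", "steller_sea_lion")
CETACEANS = ("dolphin", "minke_whale")
SIRENIANS = ("manatee",)
MARINE_CLADES = {
    "pinnipeds": PINNIPEDS,
    "cetaceans": CETACEANS,
    "sirenians": SIRENIANS,
}
TERRESTRIAL_SISTERS = {
    "pinnipeds": "dog",
    "cetaceans": "cow",
    "sirenians": "elephant",
}
ALL_TAXA = (
    "opossum", "elephant", "manatee", "human", "mouse", "dog",
) + PINNIPEDS + ("cow",) + CETACEANS

_H0_NEWICK = (
    "(opossum:{d},((elephant:{d},manatee:{d}):{d},((human:{d},mouse:{d}):{d},"
    "((dog:{d},(spotted_seal:{w},(northern_fur_seal:{w},"
    "steller_sea_lion:{w}):{w}):{d}):{d},"
    "(cow:{d},(dolphin:{w},minke_whale:{w}):{d}):{d}):{d}):{d}):{d});"
)

# marine monophyly: the pinniped + (cetacean, sirenian) group attached at the
# pinniped position inside the carnivores; all other relationships unchanged
_H1_NEWICK = (
    "(opossum:{d},(elephant:{d},((human:{d},mouse:{d}):{d},"
    "((dog:{d},((spotted_seal:{w},(northern_fur_seal:{w},"
    "steller_sea_lion:{w}):{w}):{h},((dolphin:{w},minke_whale:{w}):{h},"
    "manatee:{d}):{h}):{h}):{d},cow:{d}):{d}):{d}):{d});"
)


def species_tree(
    within: float = 0.05, deep: float = 0.2, foreground: str | None = None
) -> LabeledTree:
    """The 12-taxon species tree (H0).

    ``foreground`` may be ``"pinnipeds"`` (branch-site test), ``"marine"``
    (all three marine clades, branch test), or None.
    """
    tree = LabeledTree.from_newick(_H0_NEWICK.format(d=deep, w=within), name="H0")
    if foreground == "pinnipeds":
        tree.set_foreground_clade(PINNIPEDS)
    elif foreground == "marine":
        for clade in MARINE_CLADES.values():
            if len(clade) > 1:
                tree.set_foreground_clade(clade)
            else:  # single-taxon clade: its terminal branch is the foreground
                next(
                    lf for lf in tree.tree.leaf_node_iter()
                    if lf.taxon.label == clade[0]
                ).foreground = True
    elif foreground is not None:
        raise InvalidParameterError(f"unknown foreground spec {foreground!r}")
    return tree


def marine_monophyly_tree(within: float = 0.05, deep: float = 0.2) -> LabeledTree:
    """The alternative (H1) topology: marine mammals forced monophyletic."""
    return LabeledTree.from_newick(
        _H1_NEWICK.format(d=deep, w=within, h=deep / 2), name="H1"
    )


def uniform_codon_freqs() -> CodonFreqs:
    return CodonFreqs(
        pi=np.full(gc.N_CODONS, 1.0 / gc.N_CODONS),
        position_freqs=np.full((3, 4), 0.25),
    )


@dataclass
class Plant:
    """A post-hoc substitution: ``residue`` written into ``taxa`` at ``site``.

    ``site`` is a 0-based codon/residue index; reports are 1-based.
    """

    site: int
    residue: str
    taxa: tuple[str, ...]
    label: str = "unique"


@dataclass
class SimSpec:
    """Conditions for one simulated gene."""

    tree: LabeledTree
    n_codons: int
    model: str = "M0"  # M0 | branch | branch_site_A
    kappa: float = 2.0
    omega: float = 0.2  # M0 omega / background omega
    omega_fg: float = 0.2  # branch-model foreground omega
    p0: float = 0.75
    p1: float = 0.15
    omega0: float = 0.2
    omega2: float = 1.0  # branch-site foreground omega (1.0 = null)
    freqs: CodonFreqs = field(default_factory=uniform_codon_freqs)
    plants: list[Plant] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("M0", "branch", "branch_site_A"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        for pl in self.plants:
            if not (0 <= pl.site < self.n_codons):
                raise InvalidParameterError(
                    f"planted site {pl.site} outside [0, {self.n_codons})"
                )
            if pl.residue not in gc.AA_INDEX:
                raise InvalidParameterError(f"bad planted residue {pl.residue!r}")


@dataclass
class TruthRecord:
    """What the generator actually did, for recovery tests."""

    gene_id: str
    model: str
    params: dict
    site_classes: np.ndarray  # per-site class index (0 for single-class models)
    plants: list[Plant]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tkind\tsite_1based\tvalue\n")
            fh.write(f"{self.gene_id}\tmodel\t.\t{self.model}\n")
            for k, v in sorted(self.params.items()):
                fh.write(f"{self.gene_id}\tparam:{k}\t.\t{v}\n")
            for i, c in enumerate(self.site_classes):
                if c:
                    fh.write(f"{self.gene_id}\tsite_class\t{i + 1}\t{int(c)}\n")
            for pl in self.plants:
                fh.write(
                    f"{self.gene_id}\tplant:{pl.label}\t{pl.site + 1}\t"
                    f"{pl.residue}:{','.join(pl.taxa)}\n"
                )


def _class_omegas(spec: SimSpec) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Per-site class indices and the (bg, fg) omega of each class."""
    rng = np.random.default_rng(spec.seed + 1)
    if spec.model == "M0":
        return np.zeros(spec.n_codons, dtype=int), [(spec.omega, spec.omega)]
    if spec.model == "branch":
        return np.zeros(spec.n_codons, dtype=int), [(spec.omega, spec.omega_fg)]
    p2 = max(1.0 - spec.p0 - spec.p1, 0.0)
    tot = spec.p0 + spec.p1
    props = np.array([
        spec.p0, spec.p1, p2 * spec.p0 / tot, p2 * spec.p1 / tot,
    ])
    classes = rng.choice(4, size=spec.n_codons, p=props / props.sum())
    omegas = [
        (spec.omega0, spec.omega0),
        (1.0, 1.0),
        (spec.omega0, spec.omega2),
        (1.0, spec.omega2),
    ]
    return classes, omegas


def simulate_alignment(
    spec: SimSpec,
) -> tuple[CodonAlignment, ProteinAlignment, TruthRecord]:
    """Evolve one gene along the tree and apply any planted substitutions."""
    rng = np.random.default_rng(spec.seed)
    taxa = spec.tree.taxa
    struct = build_structure(spec.tree, taxa)
    classes, omegas = _class_omegas(spec)
    if spec.model == "branch_site_A":
        # one normalization shared by all site classes (mixture average)
        factors = branch_site_rate_factors(
            spec.freqs,
            BranchSiteParams(spec.kappa, spec.p0, spec.p1, spec.omega0,
                             max(spec.omega2, 1.0), np.zeros(1)),
        )
    else:
        factors = (np.ones(len(omegas)), np.ones(len(omegas)))
    mats: dict[tuple[int, bool], np.ndarray] = {}
    for c, (w_bg, w_fg) in enumerate(omegas):
        Q_bg = codon_rate_matrix(spec.freqs, spec.kappa, w_bg)
        Q_fg = (
            Q_bg if w_fg == w_bg
            else codon_rate_matrix(spec.freqs, spec.kappa, w_fg)
        )
        mats[(c, False)] = Q_bg
        mats[(c, True)] = Q_fg

    states = np.empty((struct.n_nodes, spec.n_codons), dtype=np.intp)
    states[struct.root] = rng.choice(gc.N_CODONS, size=spec.n_codons, p=spec.freqs.pi)
    # preorder: parents before children
    order = [(node, children) for node, children in struct.postorder_internal]
    pexp_cache: dict[tuple[int, bool, float], np.ndarray] = {}

    def transition(c: int, fg: bool, t: float) -> np.ndarray:
        key = (c, fg, t)
        if key not in pexp_cache:
            t_eff = t * factors[1 if fg else 0][c]
            pexp_cache[key] = expm(mats[(c, fg)] * t_eff)
        return pexp_cache[key]

    for node, children in reversed(order):
        for child in children:
            t = struct.edge_length[child]
            fg = bool(struct.foreground[child])
            child_states = np.empty(spec.n_codons, dtype=np.intp)
            for c in np.unique(classes):
                sel = classes == c
                P = transition(int(c), fg, float(t))
                rows = P[states[node][sel]]
                u = rng.random(sel.sum())
                child_states[sel] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
            states[child] = np.clip(child_states, 0, gc.N_CODONS - 1)

    rows = [
        "".join(gc.SENSE_CODONS[states[i, s]] for s in range(spec.n_codons))
        for i in range(len(taxa))
    ]
    aln = CodonAlignment(f"sim_seed{spec.seed}", taxa, rows)
    aln = _apply_plants(aln, spec, rng)
    truth = TruthRecord(
        gene_id=aln.gene_id,
        model=spec.model,
        params={
            "kappa": spec.kappa, "omega": spec.omega, "omega_fg": spec.omega_fg,
            "p0": spec.p0, "p1": spec.p1, "omega0": spec.omega0,
            "omega2": spec.omega2, "seed": spec.seed,
        },
        site_classes=classes,
        plants=list(spec.plants),
    )
    return aln, aln.translate(), truth


def _apply_plants(
    aln: CodonAlignment, spec: SimSpec, rng: np.random.Generator
) -> CodonAlignment:
    if not spec.plants:
        return aln
    rows = {t: list(gc.codons_of(r)) for t, r in zip(aln.taxa, aln.rows)}
    by_site: dict[int, list[Plant]] = {}
    for pl in spec.plants:
        for t in pl.taxa:
            if t not in rows:
                raise InvalidParameterError(f"plant names unknown taxon {t!r}")
        by_site.setdefault(pl.site, []).append(pl)
    for site, plants in by_site.items():
        planted_taxa = {t for pl in plants for t in pl.taxa}
        planted_res = {pl.residue for pl in plants}
        # a plant must create a substitution: redraw any unplanted taxon whose
        # wild-type residue coincides with a planted one
        for t in aln.taxa:
            if t in planted_taxa:
                continue
            tries = 0
            while gc.translate_codon(rows[t][site]) in planted_res:
                rows[t][site] = gc.SENSE_CODONS[
                    int(rng.choice(gc.N_CODONS, p=spec.freqs.pi))
                ]
                tries += 1
                if tries > 200:
                    raise InvalidParameterError(
                        f"cannot avoid residues {sorted(planted_res)} at site {site}"
                    )
        for pl in plants:
            codon = gc.synonymous_codons(pl.residue)[0]  # deterministic choice
            for t in pl.taxa:
                rows[t][site] = codon
    return CodonAlignment(
        aln.gene_id, list(aln.taxa), ["".join(rows[t]) for t in aln.taxa]
    )


def unique_pinniped_plant(site: int, residue: str) -> Plant:
    """Residue shared by all pinnipeds and (after simulation) nobody else."""
    return Plant(site=site, residue=residue, taxa=PINNIPEDS, label="unique")


def convergent_marine_plants(site: int, residue: str) -> list[Plant]:
    """The same residue planted independently in all three marine clades."""
    return [
        Plant(site=site, residue=residue, taxa=tuple(taxa), label="convergent")
        for taxa in MARINE_CLADES.values()
    ]


def simulate_null_batch(
    spec: SimSpec, n_genes: int
) -> list[tuple[CodonAlignment, ProteinAlignment, TruthRecord]]:
    """Independent replicate genes; per-gene seeds derive from ``spec.seed``."""
    out = []
    ss = np.random.SeedSequence(spec.seed)
    for i, child in enumerate(ss.spawn(n_genes)):
        sub = SimSpec(
            tree=spec.tree, n_codons=spec.n_codons, model=spec.model,
            kappa=spec.kappa, omega=spec.omega, omega_fg=spec.omega_fg,
            p0=spec.p0, p1=spec.p1, omega0=spec.omega0, omega2=spec.omega2,
            freqs=spec.freqs, plants=list(spec.plants),
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        aln, prot, truth = simulate_alignment(sub)
        aln.gene_id = f"gene{i:04d}"
        prot.gene_id = aln.gene_id
        truth.gene_id = aln.gene_id
        out.append((aln, prot, truth))
    return out
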