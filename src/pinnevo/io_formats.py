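"""Alignment and tree containers, FASTA/Newick readers, and alignment preparation.

Containers
----------
:class:`CodonAlignment`
    In-frame codon matrix over taxa.  Alphabet {A,C,G,T,N,-} in triplets;
    stop codons may appear (they are what :func:`trim_and_filter` rejects on).
:class:`ProteinAlignment`
    Amino-acid matrix (20 letters + '-' + 'X').
:class:`LabeledTree`
    Rooted phylogeny with per-branch lengths and a foreground/background
    label per branch.  Foreground marking uses PAML-style ``#1`` tags in the
    Newick string; a tag on an internal node marks the whole clade below it
    *including its stem branch* as foreground.

Coordinates are 0-based half-open internally and 1-based in every report.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

from . import genetic_code as gc
from .errors import (
    AlignmentFormatError,
    ConsistencyError,
    FrameError,
    TaxonMismatchError,
)

_CODON_ALPHABET = set("ACGTN-")
_PROTEIN_ALPHABET = set(gc.AMINO_ACIDS) | {"-", "X"}

_TAG_RE = re.compile(r"\s*#(\d+)$")


def _check_rows(taxa: Sequence[str], rows: Sequence[str], what: str) -> None:
    if len(taxa) != len(rows):
        raise AlignmentFormatError(f"{what}: {len(taxa)} taxa but {len(rows)} rows")
    if len(set(taxa)) != len(taxa):
        raise AlignmentFormatError(f"{what}: duplicate taxon names")
    if not rows:
        raise AlignmentFormatError(f"{what}: empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"{what}: ragged row lengths {sorted(lengths)}")


@dataclass
class CodonAlignment:
    """An in-frame, gap-aware codon alignment."""

    gene_id: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.rows = [r.upper() for r in self.rows]
        _check_rows(self.taxa, self.rows, f"codon alignment {self.gene_id!r}")
        n = len(self.rows[0])
        if n % 3:
            raise FrameError(
                f"codon alignment {self.gene_id!r}: length {n} not divisible by 3"
            )
        bad = set("".join(self.rows)) - _CODON_ALPHABET
        if bad:
            raise AlignmentFormatError(
                f"codon alignment {self.gene_id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise TaxonMismatchError(f"taxon {taxon!r} not in alignment") from None

    def codon(self, taxon: str, i: int) -> str:
        return self.row(taxon)[3 * i : 3 * i + 3]

    def codon_column(self, i: int) -> list[str]:
        return [r[3 * i : 3 * i + 3] for r in self.rows]

    def translate(self) -> "ProteinAlignment":
        """Codon-wise translation; codon i maps to residue i."""
        prot = [gc.translate(r).replace("*", "X") for r in self.rows]
        return ProteinAlignment(self.gene_id, list(self.taxa), prot)

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.taxa, self.rows)


@dataclass
class ProteinAlignment:
    """An amino-acid alignment paired (by convention) with a codon alignment."""

    gene_id: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.rows = [r.upper() for r in self.rows]
        _check_rows(self.taxa, self.rows, f"protein alignment {self.gene_id!r}")
        bad = set("".join(self.rows)) - _PROTEIN_ALPHABET
        if bad:
            raise AlignmentFormatError(
                f"protein alignment {self.gene_id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise TaxonMismatchError(f"taxon {taxon!r} not in alignment") from None

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.taxa, self.rows)


def write_fasta(path: str | Path, taxa: Sequence[str], rows: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for t, r in zip(taxa, rows):
            fh.write(f">{t}\n{r}\n")


def read_alignment(
    path: str | Path, kind: str, gene_id: str | None = None
) -> CodonAlignment | ProteinAlignment:
    """Read an aligned FASTA file as a codon or protein alignment.

    Parameters
    ----------
    kind
        ``"codon"`` or ``"protein"``.
    gene_id
        Defaults to the file stem.
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    taxa = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    if kind == "codon":
        return CodonAlignment(gene_id, taxa, rows)
    if kind == "protein":
        return ProteinAlignment(gene_id, taxa, rows)
    raise ValueError(f"kind must be 'codon' or 'protein', got {kind!r}")


# ---------------------------------------------------------------------------
# trees


@dataclass
class LabeledTree:
    """Rooted phylogeny whose branches are labeled foreground or background.

    Wraps a :class:`dendropy.Tree`; every node carries a boolean attribute
    ``foreground`` on its edge (stored here as ``node.foreground`` for the
    branch above the node).  The root's own "branch" is never foreground.
    """

    tree: dendropy.Tree
    name: str = ""

    def __post_init__(self) -> None:
        for nd in self.tree:
            if not hasattr(nd, "foreground"):
                nd.foreground = False
            if nd.edge.length is not None and nd.edge.length < 0:
                raise ValueError("negative branch length")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path, name: str = "") -> "LabeledTree":
        """Parse a Newick string or file, honouring ``#<int>`` clade tags."""
        if isinstance(source, Path):
            text = source.read_text()
        elif "(" not in source and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = source
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise AlignmentFormatError(f"malformed Newick: {exc}") from exc
        tree.is_rooted = True
        for nd in tree:
            nd.foreground = False
        # leaf tags: "taxon#1"
        for leaf in tree.leaf_node_iter():
            m = _TAG_RE.search(leaf.taxon.label)
            if m:
                leaf.taxon.label = leaf.taxon.label[: m.start()]
                leaf.foreground = True
        # internal tags: ")#1" parsed as node label; mark clade incl. stem
        for nd in tree.preorder_node_iter():
            if nd.label and _TAG_RE.search(nd.label.strip()):
                nd.label = None
                for sub in nd.preorder_iter():
                    sub.foreground = True
        out = cls(tree=tree, name=name)
        out._validate_labels()
        return out

    def _validate_labels(self) -> None:
        edges = list(self.branches())
        fg = [e for e in edges if e.foreground]
        if fg and len(fg) == len(edges):
            raise ValueError(
                "all branches foreground; at least one background branch required"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def branches(self) -> Iterable[dendropy.Node]:
        """Non-root nodes; each stands for the branch above it."""
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None:
                yield nd

    @property
    def n_foreground(self) -> int:
        return sum(1 for nd in self.branches() if nd.foreground)

    def copy(self) -> "LabeledTree":
        return _copy.deepcopy(self)

    def check_taxa(self, taxa: Iterable[str]) -> None:
        mine, theirs = set(self.taxa), set(taxa)
        if mine != theirs:
            raise TaxonMismatchError(
                f"tree/alignment taxa differ: only-tree={sorted(mine - theirs)}, "
                f"only-other={sorted(theirs - mine)}"
            )

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        taxa = list(taxa)
        missing = set(taxa) - set(self.taxa)
        if missing:
            raise TaxonMismatchError(f"taxa not in tree: {sorted(missing)}")
        return self.tree.mrca(taxon_labels=taxa)

    # -- labeling ----------------------------------------------------------
    def clear_foreground(self) -> None:
        for nd in self.tree:
            nd.foreground = False

    def set_foreground_clade(self, taxa: Iterable[str]) -> None:
        """Mark the clade spanned by ``taxa`` (including its stem) foreground."""
        node = self.mrca(taxa)
        if node.parent_node is None:
            raise ValueError("cannot mark the entire tree foreground")
        for sub in node.preorder_iter():
            sub.foreground = True

    def scaled(self, factor: float) -> "LabeledTree":
        out = self.copy()
        for nd in out.branches():
            if nd.edge.length is not None:
                nd.edge.length *= factor
        return out

    # -- serialization -----------------------------------------------------
    def to_newick(self, with_tags: bool = True) -> str:
        t = _copy.deepcopy(self.tree)
        if with_tags:
            # tag maximal foreground subtrees whose parent branch is background
            for nd in t.preorder_node_iter():
                par = nd.parent_node
                if getattr(nd, "foreground", False) and (
                    par is None or not getattr(par, "foreground", False)
                ):
                    if nd.is_leaf():
                        nd.taxon.label += "#1"
                    else:
                        nd.label = "#1"
        s = t.as_string(schema="newick", suppress_rooting=True,
                        unquoted_underscores=True)
        return s.strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def read_labeled_tree(path: str | Path, name: str = "") -> LabeledTree:
    """Read a Newick file with optional ``#1`` foreground clade tags."""
    return LabeledTree.from_newick(Path(path), name=name)


# ---------------------------------------------------------------------------
# alignment preparation


def back_translate(
    protein_aln: ProteinAlignment, cds: Mapping[str, str]
) -> CodonAlignment:
    """Thread unaligned coding sequences onto a protein alignment.

    Each taxon's CDS must translate (standard code) to its ungapped protein
    row; a trailing stop codon on the CDS is tolerated and dropped.  Gap
    residues expand to ``---`` so that residue *i* corresponds to codon *i*.
    """
    rows = []
    for taxon in protein_aln.taxa:
        if taxon not in cds:
            raise ConsistencyError(f"no CDS provided for taxon {taxon!r}")
        seq = cds[taxon].upper().replace("U", "T")
        if len(seq) % 3:
            raise FrameError(f"{taxon!r}: CDS length {len(seq)} not divisible by 3")
        codons = gc.codons_of(seq)
        if codons and codons[-1] in gc.STOP_CODONS:
            codons = codons[:-1]
        for i, c in enumerate(codons):
            if c in gc.STOP_CODONS:
                raise FrameError(f"{taxon!r}: internal stop codon {c} at codon {i + 1}")
        prow = protein_aln.row(taxon)
        n_res = sum(1 for a in prow if a != "-")
        if n_res != len(codons):
            raise ConsistencyError(
                f"{taxon!r}: protein row has {n_res} residues but CDS has "
                f"{len(codons)} codons"
            )
        out, k = [], 0
        for aa in prow:
            if aa == "-":
                out.append("---")
            else:
                c = codons[k]
                k += 1
                if aa != "X" and gc.translate_codon(c) != aa:
                    raise ConsistencyError(
                        f"{taxon!r}: codon {c} translates to "
                        f"{gc.translate_codon(c)!r}, protein says {aa!r}"
                    )
                out.append(c)
        rows.append("".join(out))
    return CodonAlignment(protein_aln.gene_id, list(protein_aln.taxa), rows)


@dataclass
class FilterResult:
    """Outcome of :func:`trim_and_filter`; rejection is a state, not an error."""

    alignment: CodonAlignment | None
    accepted: bool
    reason: str = ""


def trim_and_filter(
    aln: CodonAlignment,
    min_len_nt: int = 100,
    trim: bool = True,
    length_before_trim: bool = False,
) -> FilterResult:
    """Trim gappy codon columns and apply the length / internal-stop filters.

    Trimming drops every codon column in which any taxon has a gap or N.
    The alignment is rejected when its length (after trimming by default;
    before, if ``length_before_trim``) is below ``min_len_nt`` nucleotides,
    or when any row contains an internal stop codon (a stop at any codon
    before the last one, checked on the untrimmed rows).
    """
    for t, row in zip(aln.taxa, aln.rows):
        for i in range(aln.n_codons - 1):
            if row[3 * i : 3 * i + 3] in gc.STOP_CODONS:
                return FilterResult(None, False,
                                    f"internal stop codon in {t!r} at codon {i + 1}")
    if trim:
        keep = [
            i
            for i in range(aln.n_codons)
            if not any(("-" in c) or ("N" in c) for c in aln.codon_column(i))
        ]
        rows = ["".join(r[3 * i : 3 * i + 3] for i in keep) for r in aln.rows]
    else:
        rows = list(aln.rows)
    length = len(aln.rows[0]) if length_before_trim else len(rows[0])
    if length < min_len_nt:
        return FilterResult(None, False,
                            f"alignment length {length} nt < {min_len_nt} nt")
    if not rows[0]:
        return FilterResult(None, False, "no columns left after trimming")
    return FilterResult(CodonAlignment(aln.gene_id, list(aln.taxa), rows), True)
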