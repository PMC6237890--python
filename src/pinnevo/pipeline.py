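"""End-to-end orchestration: filters, branch test, dSSLS, unique substitutions.

The main flow (:func:`run_full`) mirrors the candidate-gene screen for
lineage-specific adaptation in a clade nested inside a convergent group
(pinnipeds within marine mammals):

1. length / internal-stop filtering of the per-gene codon alignments;
2. branch-model dN/dS test (marine foreground vs background) with
   post-fit saturation filters and Bonferroni correction -> REGs;
3. per-residue dSSLS between the species tree (H0) and the marine-
   monophyly tree (H1); top-fraction residues -> DSGs;
4. joint ancestral reconstruction and pinniped-unique substitution calls
   -> USGs;
5. the final candidate set: REGs carrying a top-fraction dSSLS residue at
   the same position as a unique substitution.

A separate flow (:func:`run_branch_site`) runs the branch-site test of
positive selection on the pinniped foreground and reports BEB-selected
sites per significant gene.

All stages are deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ancestral_substitutions import (
    CladeMap,
    classify_substitutions,
    intersect_rdu,
    joint_reconstruct,
)
from .codon_selection import (
    BranchRates,
    FitConfig,
    beb_site_posteriors,
    bonferroni,
    branch_rates,
    fit_model,
    lrt,
)
from .errors import InvalidParameterError, PinnevoError
from .io_formats import (
    CodonAlignment,
    LabeledTree,
    ProteinAlignment,
    read_alignment,
    read_labeled_tree,
    trim_and_filter,
)
from .sitewise_support import delta_ssls, select_top_fraction

logger = logging.getLogger("pinnevo")


@dataclass
class FilterThresholds:
    """Post-fit gene filters (saturation and degenerate-LRT screens)."""

    max_ds: float = 3.0
    max_dnds: float = 5.0
    min_lrt: float = 0.0
    min_len_nt: int = 100

    def __post_init__(self) -> None:
        if self.max_ds <= 0 or self.max_dnds <= 0 or self.min_len_nt <= 0:
            raise InvalidParameterError("filter thresholds must be positive")


@dataclass
class RunSettings:
    """Analysis parameters shared by both flows."""

    df: int = 1
    n_tests: int | None = None  # Bonferroni N; default: genes entering the test
    fraction: float = 0.01
    alpha: float = 0.05
    beb_threshold: float = 0.95
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise InvalidParameterError("fraction must be in (0, 1]")


@dataclass
class RunConfig:
    """File-based run description (the YAML the CLI consumes)."""

    alignment_paths: list[str]
    tree_h0_path: str
    tree_h1_path: str | None = None
    foreground: str | None = None  # clade tag already in the Newick if None
    settings: RunSettings = field(default_factory=RunSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        settings = RunSettings(
            **{
                **raw.get("settings", {}),
                "thresholds": FilterThresholds(**raw.get("thresholds", {})),
                "fit": FitConfig(**raw.get("fit", {})),
            }
        )
        cfg = cls(
            alignment_paths=raw["alignments"],
            tree_h0_path=raw["tree_h0"],
            tree_h1_path=raw.get("tree_h1"),
            foreground=raw.get("foreground"),
            settings=settings,
        )
        for p in cfg.alignment_paths + [cfg.tree_h0_path] + (
            [cfg.tree_h1_path] if cfg.tree_h1_path else []
        ):
            if not Path(p).exists():
                raise InvalidParameterError(f"configured path missing: {p}")
        return cfg


@dataclass
class GeneData:
    """One gene's alignments; the protein rows track the codon rows."""

    codon: CodonAlignment
    protein: ProteinAlignment | None = None

    @property
    def gene_id(self) -> str:
        return self.codon.gene_id


@dataclass
class PipelineReport:
    """Per-gene table plus self-consistent summary counts."""

    per_gene: pd.DataFrame
    summary: dict
    top_sites: list[tuple[str, int]] = field(default_factory=list)
    matched_sites: dict[str, list[int]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_gene.to_csv(
            outdir / "per_gene.tsv", sep="\t", index=False, float_format="%.6g"
        )
        (outdir / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True) + "\n"
        )


def apply_post_fit_filters(
    gene_stats: dict[str, tuple[float, BranchRates]],
    thresholds: FilterThresholds | None = None,
) -> set[str]:
    """Genes surviving the saturation/LRT screens.

    ``gene_stats`` maps gene id to (raw LRT statistic before clamping,
    per-branch rates of the alternative fit).  A gene is removed iff its
    maximum branch dS exceeds ``max_ds``, its maximum branch dN/dS exceeds
    ``max_dnds``, or its raw LRT falls below ``min_lrt``.
    """
    thresholds = thresholds or FilterThresholds()
    retained = set()
    for gene, (raw_lrt, rates) in gene_stats.items():
        if rates is None:
            raise InvalidParameterError(f"gene {gene!r} lacks branch rates")
        if rates.max_dS > thresholds.max_ds:
            continue
        if rates.max_dNdS > thresholds.max_dnds:
            continue
        if raw_lrt < thresholds.min_lrt:
            continue
        retained.add(gene)
    return retained


def _stage(name: str):
    logger.info("stage %s", name)
    return time.time()


def run_full(
    genes: list[GeneData],
    tree_h0: LabeledTree,
    tree_h1: LabeledTree,
    clade_map: CladeMap | None = None,
    settings: RunSettings | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Execute the complete candidate-gene screen.

    ``tree_h0`` must carry the foreground marking used for the branch test
    (all marine clades for the REG screen).  Intermediate tables are written
    under ``outdir`` when given.
    """
    settings = settings or RunSettings()
    clade_map = clade_map or CladeMap()
    if tree_h0.n_foreground == 0:
        raise InvalidParameterError("H0 tree has no foreground branches")
    rows: dict[str, dict] = {}

    # stage 1: alignment filters ------------------------------------------
    t0 = _stage("filter")
    kept: list[GeneData] = []
    for g in genes:
        res = trim_and_filter(g.codon, min_len_nt=settings.thresholds.min_len_nt)
        rows[g.gene_id] = {"gene": g.gene_id, "included": res.accepted,
                           "exclusion_reason": res.reason}
        if res.accepted:
            kept.append(GeneData(codon=res.alignment,
                                 protein=res.alignment.translate()))
    logger.info("filter: %d/%d genes kept (%.1fs)", len(kept), len(genes),
                time.time() - t0)
    if not kept:
        raise PinnevoError("stage filter: no genes left to analyze")

    # stage 2: branch-model test ------------------------------------------
    t0 = _stage("branch-test")
    fit_cfg = settings.fit
    gene_stats: dict[str, tuple[float, BranchRates]] = {}
    for g in kept:
        try:
            m0 = fit_model(tree_h0, g.codon, "M0", fit_cfg)
            alt = fit_model(tree_h0, g.codon, "branch", fit_cfg,
                            start_params=m0.params, evaluator=m0.evaluator)
        except PinnevoError as exc:
            raise PinnevoError(f"stage branch-test: gene {g.gene_id}: {exc}")
        raw = 2.0 * (alt.lnL - m0.lnL)
        rates = branch_rates(alt)
        test = lrt(m0, alt, df=settings.df)
        p = alt.params
        rows[g.gene_id].update(
            lnL_h0=m0.lnL, lnL_h1=alt.lnL, lrt=test.statistic, p_value=test.p_value,
            omega_bg=p.omega_background, omega_fg=p.omega_foreground,
            delta_omega=p.omega_foreground - p.omega_background,
            max_ds=rates.max_dS, max_dnds=rates.max_dNdS,
        )
        gene_stats[g.gene_id] = (raw, rates)
    passing = apply_post_fit_filters(gene_stats, settings.thresholds)
    for g in kept:
        rows[g.gene_id]["passed_post_fit"] = g.gene_id in passing
    logger.info("branch-test: %d/%d genes pass post-fit filters (%.1fs)",
                len(passing), len(kept), time.time() - t0)

    # stage 3: Bonferroni and REG flags -----------------------------------
    tested = [g for g in kept if g.gene_id in passing]
    n_tests = settings.n_tests if settings.n_tests is not None else len(tested)
    pvals = np.array([rows[g.gene_id]["p_value"] for g in tested])
    padj = bonferroni(pvals, n_tests) if len(tested) else np.array([])
    regs = set()
    for g, pa in zip(tested, padj):
        rows[g.gene_id]["p_adjusted"] = float(pa)
        if pa < settings.alpha:
            regs.add(g.gene_id)
    for g in kept:
        rows[g.gene_id]["reg"] = g.gene_id in regs

    # stage 4: dSSLS -------------------------------------------------------
    t0 = _stage("ssls")
    profiles = []
    for g in kept:
        prof = delta_ssls(tree_h0, tree_h1, g.protein)
        profiles.append(prof)
        rows[g.gene_id]["max_delta_ssls"] = float(prof.delta.max())
    top = select_top_fraction(profiles, settings.fraction)
    for g in kept:
        rows[g.gene_id]["dsg"] = g.gene_id in top.dsg_genes
    logger.info("ssls: %d residues selected over %d genes (%.1fs)",
                top.k_selected, len(kept), time.time() - t0)

    # stage 5: ancestral reconstruction and unique substitutions ----------
    t0 = _stage("ancestral")
    unique_calls = []
    for g in kept:
        recon = joint_reconstruct(tree_h0, g.protein)
        unique_calls.extend(classify_substitutions(recon, g.protein, clade_map))
    logger.info("ancestral: done (%.1fs)", time.time() - t0)

    # stage 6: intersection ------------------------------------------------
    inter = intersect_rdu(regs, top, unique_calls)
    for g in kept:
        gid = g.gene_id
        rows[gid]["n_unique"] = inter.unique_counts.get(gid, 0)
        rows[gid]["usg"] = rows[gid]["n_unique"] > 0
        rows[gid]["final"] = gid in inter.final_genes

    per_gene = pd.DataFrame(
        [rows[g.gene_id] for g in genes]
    ).sort_values("gene").reset_index(drop=True)
    summary = {
        "n_input": len(genes),
        "n_filtered": len(kept),
        "n_post_fit": len(passing),
        "n_tests": int(n_tests),
        "n_reg": len(regs),
        "n_top_sites": top.k_selected,
        "n_dsg": len(top.dsg_genes),
        "n_usg": int(sum(1 for g in kept if rows[g.gene_id]["usg"])),
        "n_final": len(inter.final_genes),
        "final_genes": inter.final_genes,
        "seed": settings.seed,
    }
    report = PipelineReport(
        per_gene=per_gene,
        summary=summary,
        top_sites=top.sites,
        matched_sites=inter.matched_sites,
    )
    if outdir is not None:
        report.write(outdir)
        top_df = pd.DataFrame(top.sites, columns=["gene", "site"])
        top_df.to_csv(Path(outdir) / "top_sites.tsv", sep="\t", index=False)
    return report


def run_branch_site(
    genes: list[GeneData],
    tree: LabeledTree,
    settings: RunSettings | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Branch-site test of positive selection on the labeled foreground.

    For each gene passing the alignment filters: branch-site model A
    alternative vs its omega2=1 null, chi-square LRT (df from settings),
    Bonferroni adjustment, and — for significant genes — BEB posteriors
    with the selected sites (posterior above the configured threshold).
    An M0 fit supplies the per-branch saturation screen.
    """
    settings = settings or RunSettings()
    if tree.n_foreground == 0:
        raise InvalidParameterError("tree has no foreground branches")
    fit_cfg = settings.fit
    recs = []
    for g in genes:
        res = trim_and_filter(g.codon, min_len_nt=settings.thresholds.min_len_nt)
        if not res.accepted:
            logger.info("branch-site: %s excluded (%s)", g.gene_id, res.reason)
            recs.append({"gene": g.gene_id, "included": False,
                         "exclusion_reason": res.reason})
            continue
        aln = res.alignment
        m0 = fit_model(tree, aln, "M0", fit_cfg)
        null = fit_model(tree, aln, "branch_site_null", fit_cfg,
                         evaluator=m0.evaluator)
        alt = fit_model(tree, aln, "branch_site_alt", fit_cfg,
                        start_params=null.params, evaluator=m0.evaluator)
        raw = 2.0 * (alt.lnL - null.lnL)
        rates = branch_rates(m0)
        test = lrt(null, alt, df=settings.df)
        p = alt.params
        recs.append({
            "gene": g.gene_id, "included": True, "exclusion_reason": "",
            "fg_omega2": p.omega2,
            "prop_2a_2b": float(p.class_proportions[2] + p.class_proportions[3]),
            "lnL_h0": null.lnL, "lnL_h1": alt.lnL,
            "lrt": test.statistic, "p_value": test.p_value,
            "max_ds": rates.max_dS, "max_dnds": rates.max_dNdS,
            "passed_post_fit": (
                rates.max_dS <= settings.thresholds.max_ds
                and rates.max_dNdS <= settings.thresholds.max_dnds
                and raw >= settings.thresholds.min_lrt
            ),
            "_alt_fit": alt,
        })
    tested = [r for r in recs if r.get("passed_post_fit")]
    n_tests = settings.n_tests if settings.n_tests is not None else len(tested)
    if tested:
        padj = bonferroni([r["p_value"] for r in tested], n_tests)
        for r, pa in zip(tested, padj):
            r["p_adjusted"] = float(pa)
            r["significant"] = pa < settings.alpha
            if r["significant"]:
                beb = beb_site_posteriors(r["_alt_fit"],
                                          threshold=settings.beb_threshold)
                r["n_selected_sites"] = len(beb.selected_sites)
                r["selected_sites"] = ",".join(map(str, beb.selected_sites))
    for r in recs:
        r.pop("_alt_fit", None)
    df = pd.DataFrame(recs)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(outdir) / "branch_site.tsv", sep="\t", index=False,
                  float_format="%.6g")
    return df


def load_genes(paths: list[str | Path]) -> list[GeneData]:
    """Read per-gene codon FASTA files into GeneData records."""
    return [GeneData(codon=read_alignment(p, "codon")) for p in paths]


def run_full_from_config(cfg: RunConfig, outdir: str | Path | None = None):
    genes = load_genes(cfg.alignment_paths)
    tree_h0 = read_labeled_tree(cfg.tree_h0_path)
    if cfg.tree_h1_path is None:
        raise InvalidParameterError("run_full requires an H1 topology")
    tree_h1 = read_labeled_tree(cfg.tree_h1_path)
    if cfg.foreground:
        tree_h0.set_foreground_clade(cfg.foreground.split(","))
    return run_full(genes, tree_h0, tree_h1, settings=cfg.settings, outdir=outdir)
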