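# Methods

`pinnevo` implements a screen for lineage-specific molecular adaptation in
a clade nested inside a convergent group — concretely, pinnipeds (seals,
sea lions) within the three independently marine mammal lineages
(pinnipeds, cetaceans, sirenians) on a 12-taxon mammal phylogeny.  The
screen combines three signals computed per single-copy ortholog:

1. **Rapid evolution (REG)** — a two-ratio branch model in which dN/dS
   (omega) differs between designated foreground branches (the marine
   clades) and the background, tested against the one-ratio model by a
   likelihood-ratio test with Bonferroni correction.
2. **Divergent residues (DSG)** — per-residue log-likelihood support
   (dSSLS) for the species tree (H0) over a marine-monophyly constraint
   tree (H1); residues in the genome-wide top 1% of dSSLS = lnL(H0) −
   lnL(H1) are "divergent" sites.
3. **Pinniped-unique substitutions (USG)** — residues shared by all
   pinnipeds, absent from the reconstructed pinniped+dog ancestor and from
   every other mammal in the alignment, via joint ancestral
   reconstruction.

The final candidate set is the REGs carrying a top-1% dSSLS residue at the
same position as a unique substitution.  A separate flow runs the
branch-site test of positive selection (model A) on the pinniped
foreground with Bayes empirical Bayes (BEB) site posteriors.

## Codon models

The substitution process is the Goldman–Yang codon model on the 61 sense
codons of the universal code.  Off-diagonal rates for single-nucleotide
changes are

    q_ij ∝ pi_j · kappa^[transition] · omega^[nonsynonymous],

zero for multi-nucleotide changes.  Codon frequencies are F3X4: products
of position-specific nucleotide frequencies estimated from each gene's own
alignment (gaps/N excluded), renormalized over sense codons; zero
positional frequencies are floored at 1e-6 to keep every sense codon
reachable.  Each generator is scaled to one expected substitution per
codon per unit time, so branch lengths are in substitutions per codon.

Three model families are fitted by maximum likelihood (Felsenstein pruning
with per-site rescaling; transition matrices from the eigendecomposition
of the symmetrized reversible generator):

* **M0** — single omega;
* **branch** — omega_background and omega_foreground;
* **branch-site model A** — site classes 0 (omega0 ≤ 1 everywhere), 1
  (neutral), 2a/2b (omega2 ≥ 1 on the foreground, omega0 / 1 on the
  background), proportions p0, p1, with the class-2 mass 1 − p0 − p1 split
  p0 : p1.  The null fixes omega2 = 1 (one degree of freedom between the
  models; both LRTs here use a plain chi-square with df = 1, which
  reproduces the published worked-example p-values).

For the mixture, one rate normalization is shared across site classes
(the mixture-average rate at the current parameters), so class-2 sites
genuinely accumulate more substitutions on the foreground — the same
convention as the reference ML implementations of these models.  This
matters for power: normalizing each class separately would reduce the
selected class's signal to a composition shift.

**Optimization.** Bounded L-BFGS-B on transformed parameters (log kappa,
log omega, softmax class proportions, logit omega0, log(omega2 − 1)).
Each fit runs a fixed start (kappa = 2, omega = 0.5) plus `n_restarts`
seeded random restarts (default 3), and alternative models are
additionally warm-started from their null's MLE, which guarantees the
nested-likelihood ordering up to optimizer tolerance.  Branch lengths are
re-estimated for every model fit, by default as a single proportional
scale factor applied to the input tree (`branch_length_mode="scale"`);
per-branch re-estimation (`"full"`) is available but is much
higher-dimensional per gene.  The scale default reflects that the
topology and relative branch lengths come from a genome-wide tree, while
per-gene rate variation is captured by the scale — and it keeps null and
alternative strictly nested.

**Per-branch rates.** dN and dS per branch come from splitting the
generator's stationary flux into synonymous and nonsynonymous parts
(a_S, omega·a_N), converting branch lengths to time via the total rate and
normalizing by the corresponding proportions of synonymous and
nonsynonymous sites; dN/dS equals the branch's omega by construction, and
zero-length branches report dN = dS = 0 with an undefined ratio.  These
feed the post-fit filters (remove a gene when max branch dS > 3, max
branch dN/dS > 5, or the raw LRT is negative).

**BEB.** Site posteriors for the positively selected classes average the
empirical-Bayes posterior over a uniform-prior grid on (p0, p1, omega0,
omega2), holding kappa, branch lengths and the per-class rate calibration
at their MLEs.  The (p0, p1) simplex is parameterized by s = p0 + p1 and
r = p0/s, each on `n_grid` midpoints of (0, 1) (default 10); omega0 on
midpoints of (0, 1); omega2 on midpoints of (1, 11).  Sites with posterior
P(class 2a or 2b) > 0.95 are reported as positively selected.

## Protein-level analyses

dSSLS and ancestral reconstruction use JTT with frequencies re-estimated
from each gene's alignment (+F).  Branch lengths are optimized per gene
and — for dSSLS — independently under each topology (L-BFGS-B on log
lengths, all branches free; the 20-state problem is cheap).  Rate
homogeneity across sites is the default; an optional 4-category
median-discretized gamma model is available but not used by the standard
screen (the CAT-style approximation used for the original tree search is
out of scope).  All-gap columns carry site lnL = 0.

The top-fraction rule selects exactly floor(fraction × N) residues over
all genes, ranked by dSSLS descending with deterministic (gene, position)
tie-breaking.

Joint ancestral states are the single assignment of residues to all
internal nodes maximizing the joint probability per site (max-product
dynamic programming with backtracking).  Gapped leaves are free (the DP
maximizes over their state); ties break in alphabetical residue order.
The "ancestral node" of a marine clade is always the MRCA of the clade
with its terrestrial sister (dog for pinnipeds, cow for cetaceans,
elephant for sirenians); this applies both to the unique-substitution
definition and to the parallel-substitution definition, which for the
single-taxon sirenian clade is the only well-defined reading.  Leaves with
gap/X neither support nor veto a call by default; `strict` mode requires
every taxon observed.

## Synthetic data

The generator evolves codon alignments site-independently along the
12-taxon tree (default branch lengths 0.05 within the pinniped and
cetacean clades, 0.2 on deeper branches — informative but unsaturated;
uniform codon frequencies): root codons from the stationary distribution,
then transition matrices per branch, with branch-site class assignments
drawn per site and the shared-normalization convention above.  Known
substitution patterns are then *planted*: a chosen residue (encoded by its
lexicographically first codon) overwrites a chosen taxon set at a chosen
site, and any unplanted taxon whose wild-type residue collides with a
planted one is redrawn from the stationary distribution so the plant is a
genuine substitution.  Truth records carry site classes and plants.

What the generator does not emulate: indels and alignment error,
among-site rate variation, codon-usage bias beyond F3X4, selection
heterogeneity along branches, and orthology errors.  Passing recovery
tests therefore demonstrates correctness of the inference machinery under
the model's own assumptions, not robustness to real-data violations.

## Validation studies and problem sizes

All studies run on one core; sizes were chosen to keep the complete suite
within minutes while leaving the tested contrasts decisive.

* **Oracle equivalence** — pruning likelihoods (codon and amino acid)
  against explicit enumeration over internal states on 3-taxon stars and a
  two-internal-node tree (tolerance 1e-8); joint reconstruction against
  exhaustive search on a 5-taxon tree with gaps.
* **Type-I error** — 200 null replicates (branch-site model A with
  omega2 = 1; kappa 2, p0 0.75, p1 0.15, omega0 0.2) of 300-codon genes on
  a 6-taxon subtree (pinnipeds + dog + cow + human, pinniped foreground);
  fits use the fixed start plus null-to-alternative warm starts.  The
  empirical rejection rate at the nominal chi-square(1) 5% cutoff must not
  exceed 0.10 (the boundary null makes the test conservative, so the
  observed rate is typically well below 5%).
* **Effect-direction recovery** — 50 replicates of 500-codon genes under
  the branch model (omega_fg 4, omega_bg 0.2, marine foreground, full
  12-taxon tree); the fitted foreground omega must exceed the background
  in at least 95%.
* **End-to-end recovery** — a 30-gene screen: 25 background genes under
  M0 (omega 0.2) and 5 planted genes under the branch model (marine
  foreground omega 1.5) emulating conserved candidate genes (branch
  lengths scaled by 0.8 — real candidates such as inner-ear and
  channel genes are slowly evolving).  Each planted gene carries three
  fully specified columns combining a pinniped-unique residue with
  cetartiodactyl and afrotherian synapomorphies over a uniform terrestrial
  background — clades present on H0 but broken under H1, so the columns
  score high dSSLS; rare, weakly exchangeable residues (C/M/W, rotated
  across sites) keep the H1-side extra changes expensive.  Exact recovery
  means the pipeline's final set equals the planted set.  The planted
  columns sit near the top-1% boundary by construction, so recovery is
  exact for typical seeds but can drop a gene for an unlucky one; the
  acceptance script reports the realized Jaccard overlap.

## Other design choices

* The Bonferroni N defaults to the number of genes entering each test
  (per-analysis N) and is overridable in config, since the effective N of
  a published analysis is generally not recoverable from its outputs.
* The H1 (marine monophyly) topology is an explicit input: the pinniped
  clade's sister position is replaced by (pinnipeds, (cetaceans,
  sirenians)), all other relationships unchanged.
* Reports use 1-based residue coordinates; everything internal is 0-based
  half-open.
* Every stochastic routine takes an explicit seed; replicate batches
  derive per-gene seeds from a master seed via `SeedSequence`.  Pipeline
  reruns with the same config and seed are byte-identical.

## Known limitations

Only the joint (not marginal) reconstruction is provided; NSsites models
other than branch-site A are out of scope; the dSSLS model is fixed to
JTT+F rather than per-gene model selection; the branch-site saturation
screen uses an auxiliary M0 fit for per-branch rates.  The LRT p-values
use chi-square(1) rather than the boundary-corrected 50:50 mixture, which
is conservative for the branch-site test.
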