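"""GY94-style codon models, likelihood fitting, LRTs, and BEB site posteriors.

The model family is the Goldman–Yang codon substitution process on the 61
sense codons with F3X4 frequencies: instantaneous rates are zero for
multi-nucleotide changes and otherwise proportional to the target codon
frequency, multiplied by kappa for transitions and by omega for
nonsynonymous changes.  Three fits are supported:

``M0``
    one omega shared by every branch and site (the one-ratio model);
``branch``
    two omegas, foreground vs background branches;
``branch_site_alt`` / ``branch_site_null``
    branch-site model A: site classes 0 (omega0 <= 1 everywhere), 1
    (neutral everywhere), 2a/2b (omega2 on foreground branches, omega0 or 1
    on background), with class proportions p0, p1 and the class-2 mass
    1 - p0 - p1 split p0:p1 between 2a and 2b.  The null fixes omega2 = 1.

Each generator is scaled to one expected substitution per codon per unit
time at its own (kappa, omega), so branch lengths are in expected
substitutions per codon.  Branch lengths are re-estimated for every model
fit, by default as a single proportional scaling of the input tree
(``branch_length_mode="scale"``); per-branch re-estimation is available
with ``branch_length_mode="full"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from . import genetic_code as gc
from ._pruning import (
    EigenSystem,
    TreeStructure,
    build_structure,
    compress_patterns,
    eigen_reversible,
    leaf_state_matrix,
    site_log_likelihoods,
)
from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    NumericalError,
    UnconvergedFitError,
)
from .io_formats import CodonAlignment, LabeledTree

# ---------------------------------------------------------------------------
# codon-pair structure (built once at import)


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ii, jj, ts, ns = [], [], [], []
    for i, j in itertools.combinations(range(gc.N_CODONS), 2):
        ci, cj = gc.SENSE_CODONS[i], gc.SENSE_CODONS[j]
        diff = [k for k in range(3) if ci[k] != cj[k]]
        if len(diff) != 1:
            continue
        k = diff[0]
        ii.append(i)
        jj.append(j)
        ts.append(gc.is_transition(ci[k], cj[k]))
        ns.append(gc.CODON_AA[i] != gc.CODON_AA[j])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_NONSYN = _pair_structure()

_FREQ_FLOOR = 1e-6  # positional nucleotide frequencies are floored at this


# ---------------------------------------------------------------------------
# F3X4 frequencies


@dataclass
class CodonFreqs:
    """F3X4 codon frequencies over the 61 sense codons."""

    pi: np.ndarray  # (61,)
    position_freqs: np.ndarray  # (3, 4), nucleotide order ACGT

    def __post_init__(self) -> None:
        if self.pi.shape != (gc.N_CODONS,) or np.any(self.pi < 0):
            raise InvalidParameterError("pi must be 61 non-negative frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise InvalidParameterError("pi must sum to 1")


def build_f3x4(aln: CodonAlignment) -> CodonFreqs:
    """Position-specific nucleotide counts -> F3X4 codon frequencies.

    Gaps and N are excluded from the counts.  Zero positional frequencies
    are floored at 1e-6 and renormalized so no sense codon gets probability
    exactly zero.
    """
    counts = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate(gc.NUCLEOTIDES)}
    for row in aln.rows:
        for c in range(aln.n_codons):
            codon = row[3 * c : 3 * c + 3]
            if "-" in codon or "N" in codon:
                continue
            for k in range(3):
                counts[k, nt_index[codon[k]]] += 1
    if counts.sum() == 0:
        raise DegenerateInputError("no countable codons in alignment")
    f = counts / counts.sum(axis=1, keepdims=True)
    f = np.clip(f, _FREQ_FLOOR, None)
    f /= f.sum(axis=1, keepdims=True)
    pi = np.empty(gc.N_CODONS)
    for i, codon in enumerate(gc.SENSE_CODONS):
        pi[i] = f[0, nt_index[codon[0]]] * f[1, nt_index[codon[1]]] * f[2, nt_index[codon[2]]]
    pi /= pi.sum()
    return CodonFreqs(pi=pi, position_freqs=f)


# ---------------------------------------------------------------------------
# rate matrix


def codon_rate_matrix(
    freqs: CodonFreqs, kappa: float, omega: float, scale: bool = True
) -> np.ndarray:
    """GY94 generator; rows sum to zero.

    With ``scale=True`` the generator is normalized so the expected number
    of substitutions per codon per unit time is 1 at stationarity.
    """
    if not (np.isfinite(kappa) and kappa > 0):
        raise InvalidParameterError(f"kappa must be > 0, got {kappa}")
    if not (np.isfinite(omega) and omega >= 0):
        raise InvalidParameterError(f"omega must be >= 0, got {omega}")
    pi = freqs.pi
    Q = np.zeros((gc.N_CODONS, gc.N_CODONS))
    rate = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_NONSYN, omega, 1.0)
    Q[_PAIR_I, _PAIR_J] = rate * pi[_PAIR_J]
    Q[_PAIR_J, _PAIR_I] = rate * pi[_PAIR_I]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rho = -np.dot(pi, np.diag(Q))
        if rho <= 0:
            raise NumericalError("degenerate generator: zero total rate")
        Q /= rho
    return Q


def branch_site_rate_factors(
    freqs: CodonFreqs, p: "BranchSiteParams"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class relative substitution rates under a shared normalization.

    Each class generator is stored with unit mean rate; multiplying a
    mixture-average branch length by these factors recovers the codeml-style
    convention in which all classes share one normalization (the mixture
    average), so class-2 sites evolve faster on the foreground.
    Returns (background factors, foreground factors), each length 4.
    """
    a_s, a_n = syn_nonsyn_flux(freqs, p.kappa)

    def rho(w: float) -> float:
        return a_s + w * a_n

    rho_bg = np.array([rho(p.omega0), rho(1.0), rho(p.omega0), rho(1.0)])
    rho_fg = np.array([rho(p.omega0), rho(1.0), rho(p.omega2), rho(p.omega2)])
    props = p.class_proportions
    return rho_bg / np.dot(props, rho_bg), rho_fg / np.dot(props, rho_fg)


def syn_nonsyn_flux(freqs: CodonFreqs, kappa: float) -> tuple[float, float]:
    """Stationary synonymous and nonsynonymous flux of the omega-free generator.

    Returns (a_S, a_N): expected synonymous / nonsynonymous substitutions per
    codon per unit time with omega factored out (i.e. at omega = 1 for the
    nonsynonymous part).  The total rate at omega is a_S + omega * a_N.
    """
    pi = freqs.pi
    rate = np.where(_PAIR_TS, kappa, 1.0) * pi[_PAIR_I] * pi[_PAIR_J]
    flux = 2.0 * rate  # both directions of each unordered pair
    a_s = float(flux[~_PAIR_NONSYN].sum())
    a_n = float(flux[_PAIR_NONSYN].sum())
    return a_s, a_n


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class BranchModelParams:
    """Parameters of the one-ratio (M0) or two-ratio branch model."""

    kappa: float
    omega_background: float
    omega_foreground: float
    branch_lengths: np.ndarray  # per structure node id; nan at root

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and np.isfinite(self.kappa)):
            raise InvalidParameterError("kappa must be positive and finite")
        for w in (self.omega_background, self.omega_foreground):
            if not (w >= 0 and np.isfinite(w)):
                raise InvalidParameterError("omega must be non-negative and finite")


@dataclass
class BranchSiteParams:
    """Parameters of branch-site model A (alternative or null)."""

    kappa: float
    p0: float
    p1: float
    omega0: float
    omega2: float
    branch_lengths: np.ndarray

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and np.isfinite(self.kappa)):
            raise InvalidParameterError("kappa must be positive and finite")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-9:
            raise InvalidParameterError("need p0, p1 >= 0 and p0 + p1 <= 1")
        if not (0 <= self.omega0 <= 1):
            raise InvalidParameterError("omega0 must lie in [0, 1]")
        if self.omega2 < 1 - 1e-9:
            raise InvalidParameterError("omega2 must be >= 1")

    @property
    def class_proportions(self) -> np.ndarray:
        """(p0, p1, p2a, p2b); class-2 mass splits p0:p1 between 2a and 2b."""
        p2 = max(1.0 - self.p0 - self.p1, 0.0)
        tot = self.p0 + self.p1
        if tot <= 0:
            return np.array([0.0, 0.0, p2 / 2, p2 / 2])
        return np.array(
            [self.p0, self.p1, p2 * self.p0 / tot, p2 * self.p1 / tot]
        )


@dataclass
class ModelFit:
    """A fitted codon model: parameters plus total and per-site lnL."""

    model_name: str
    params: BranchModelParams | BranchSiteParams
    lnL: float
    site_lnL: np.ndarray
    converged: bool
    n_restarts_used: int
    gene_id: str = ""
    freqs: CodonFreqs | None = None
    evaluator: "CodonLikelihood | None" = field(default=None, repr=False)


@dataclass
class LrtResult:
    """A likelihood-ratio test between nested fits."""

    statistic: float
    df: int
    p_value: float
    p_adjusted: float | None = None


@dataclass
class BebResult:
    """Bayes empirical Bayes site posteriors for branch-site model A."""

    site_posteriors: np.ndarray  # P(class 2a or 2b) per site
    class_posteriors: np.ndarray  # (n_sites, 4)
    selected_sites: list[int]  # 1-based, posterior > threshold
    threshold: float


@dataclass
class BranchRates:
    """Per-branch expected substitution rates from a fitted model."""

    node_ids: np.ndarray
    foreground: np.ndarray
    t: np.ndarray
    dN: np.ndarray
    dS: np.ndarray
    omega: np.ndarray  # dN/dS; nan where dS == 0

    @property
    def max_dS(self) -> float:
        return float(np.max(self.dS)) if self.dS.size else 0.0

    @property
    def max_dNdS(self) -> float:
        finite = self.omega[np.isfinite(self.omega)]
        return float(np.max(finite)) if finite.size else 0.0


# ---------------------------------------------------------------------------
# likelihood evaluator


class CodonLikelihood:
    """Caches tree structure, site patterns, and eigensystems for one gene."""

    def __init__(
        self,
        tree: LabeledTree,
        aln: CodonAlignment,
        freqs: CodonFreqs | None = None,
    ):
        self.tree = tree
        self.aln = aln
        self.struct: TreeStructure = build_structure(tree, aln.taxa)
        states = leaf_state_matrix(aln.rows, gc.CODON_INDEX, gc.N_CODONS, width=3)
        self.patterns, self.weights, self.site_map = compress_patterns(states)
        self.freqs = freqs if freqs is not None else build_f3x4(aln)
        self.input_lengths = np.nan_to_num(self.struct.edge_length, nan=0.0)
        self._eig_cache: dict[tuple[float, float], EigenSystem] = {}
        self._p_cache: dict[tuple[float, float, float], np.ndarray] = {}

    def eigensystem(self, kappa: float, omega: float) -> EigenSystem:
        key = (float(kappa), float(omega))
        if key not in self._eig_cache:
            if len(self._eig_cache) > 64:
                self._eig_cache.clear()
            Q = codon_rate_matrix(self.freqs, kappa, omega)
            self._eig_cache[key] = eigen_reversible(Q, self.freqs.pi)
        return self._eig_cache[key]

    def pattern_loglik(
        self,
        kappa: float,
        omega_bg: float,
        omega_fg: float,
        branch_lengths: np.ndarray,
    ) -> np.ndarray:
        """Per-pattern lnL with one omega per branch class."""
        if len(self._p_cache) > 4096:
            self._p_cache.clear()
        edge_P = {}
        for b in self.struct.branch_ids:
            omega = omega_fg if self.struct.foreground[b] else omega_bg
            key = (float(kappa), float(omega), float(branch_lengths[b]))
            P = self._p_cache.get(key)
            if P is None:
                P = self.eigensystem(kappa, omega).transition_matrix(
                    branch_lengths[b]
                )
                self._p_cache[key] = P
            edge_P[b] = P
        return site_log_likelihoods(
            self.struct, self.patterns, edge_P, self.freqs.pi
        )

    def expand(self, pattern_values: np.ndarray) -> np.ndarray:
        """Map per-pattern values back to per-site values."""
        return pattern_values[self.site_map]

    def total(self, pattern_loglik: np.ndarray) -> float:
        return float(np.dot(self.weights, pattern_loglik))

    # -- model-level site log-likelihoods ---------------------------------
    def branch_site_pattern_loglik(
        self, p: BranchSiteParams, branch_lengths: np.ndarray
    ) -> np.ndarray:
        """Mixture per-pattern lnL under branch-site model A.

        Branch lengths are expected substitutions per codon *averaged over
        site classes*: one normalization is shared by all classes, so
        higher-omega classes genuinely accumulate more substitutions.
        """
        comps = self.branch_site_class_logliks(
            p.kappa, p.omega0, p.omega2, branch_lengths,
            rate_factors=branch_site_rate_factors(self.freqs, p),
        )
        props = p.class_proportions
        keep = props > 0
        return logsumexp(
            comps[keep] + np.log(props[keep])[:, None], axis=0
        )

    def branch_site_class_logliks(
        self,
        kappa: float,
        omega0: float,
        omega2: float,
        branch_lengths: np.ndarray,
        rate_factors: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> np.ndarray:
        """(4, n_patterns): per-class lnL for classes 0, 1, 2a, 2b.

        ``rate_factors`` holds per-class relative rates (background,
        foreground) converting mixture-average branch lengths into
        class-specific ones; identity when omitted.
        """
        fg = self.struct.foreground
        omegas = [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]
        if rate_factors is None:
            f_bg = f_fg = np.ones(4)
        else:
            f_bg, f_fg = rate_factors
        out = []
        for c, (w_bg, w_fg) in enumerate(omegas):
            t_eff = branch_lengths * np.where(fg, f_fg[c], f_bg[c])
            out.append(self.pattern_loglik(kappa, w_bg, w_fg, t_eff))
        return np.vstack(out)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit_model`."""

    branch_length_mode: str = "scale"  # "scale" | "full" | "fixed"
    n_restarts: int = 3  # random restarts in addition to the fixed start
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-9


_BOUND_LOG_KAPPA = (-4.0, 4.0)
_BOUND_LOG_OMEGA = (-9.0, 4.0)
_BOUND_SOFTMAX = (-12.0, 12.0)
_BOUND_LOGIT_W0 = (-12.0, 8.0)
_BOUND_U_W2 = (-12.0, 5.0)
_BOUND_LOG_SCALE = (-5.0, 4.0)
_BOUND_LOG_BLEN = (-9.0, 2.5)

_MODELS = ("M0", "branch", "branch_site_alt", "branch_site_null")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


class _Parameterization:
    """Packs/unpacks model parameters to an unconstrained optimizer vector."""

    def __init__(self, model: str, cl: CodonLikelihood, config: FitConfig):
        self.model = model
        self.cl = cl
        self.config = config
        self.n_branches = len(cl.struct.branch_ids)
        if config.branch_length_mode == "full":
            self.n_blen = self.n_branches
        elif config.branch_length_mode == "scale":
            self.n_blen = 1
        elif config.branch_length_mode == "fixed":
            self.n_blen = 0
        else:
            raise InvalidParameterError(
                f"unknown branch_length_mode {config.branch_length_mode!r}"
            )
        if model == "M0":
            self.theta_spec = [("log_kappa", _BOUND_LOG_KAPPA),
                               ("log_omega", _BOUND_LOG_OMEGA)]
        elif model == "branch":
            self.theta_spec = [("log_kappa", _BOUND_LOG_KAPPA),
                               ("log_omega_bg", _BOUND_LOG_OMEGA),
                               ("log_omega_fg", _BOUND_LOG_OMEGA)]
        elif model in ("branch_site_alt", "branch_site_null"):
            self.theta_spec = [("log_kappa", _BOUND_LOG_KAPPA),
                               ("sm_a", _BOUND_SOFTMAX),
                               ("sm_b", _BOUND_SOFTMAX),
                               ("logit_w0", _BOUND_LOGIT_W0)]
            if model == "branch_site_alt":
                self.theta_spec.append(("u_w2", _BOUND_U_W2))
        else:
            raise InvalidParameterError(f"unknown model {model!r}")

    @property
    def bounds(self) -> list[tuple[float, float]]:
        b = [bd for _, bd in self.theta_spec]
        if self.config.branch_length_mode == "full":
            b += [_BOUND_LOG_BLEN] * self.n_blen
        elif self.config.branch_length_mode == "scale":
            b += [_BOUND_LOG_SCALE]
        return b

    def branch_lengths(self, x: np.ndarray) -> np.ndarray:
        k = len(self.theta_spec)
        out = np.zeros_like(self.cl.input_lengths)
        if self.config.branch_length_mode == "full":
            vals = np.exp(x[k:])
            for v, b in zip(vals, self.cl.struct.branch_ids):
                out[b] = v
        elif self.config.branch_length_mode == "scale":
            out = self.cl.input_lengths * np.exp(x[k])
        else:
            out = self.cl.input_lengths.copy()
        return out

    def unpack(self, x: np.ndarray):
        d = {name: x[i] for i, (name, _) in enumerate(self.theta_spec)}
        blens = self.branch_lengths(x)
        if self.model == "M0":
            w = float(np.exp(d["log_omega"]))
            return BranchModelParams(float(np.exp(d["log_kappa"])), w, w, blens)
        if self.model == "branch":
            return BranchModelParams(
                float(np.exp(d["log_kappa"])),
                float(np.exp(d["log_omega_bg"])),
                float(np.exp(d["log_omega_fg"])),
                blens,
            )
        z = np.array([d["sm_a"], d["sm_b"], 0.0])
        p = np.exp(z - logsumexp(z))
        w2 = 1.0 + np.exp(d["u_w2"]) if self.model == "branch_site_alt" else 1.0
        return BranchSiteParams(
            kappa=float(np.exp(d["log_kappa"])),
            p0=float(p[0]),
            p1=float(p[1]),
            omega0=float(_sigmoid(d["logit_w0"])),
            omega2=float(w2),
            branch_lengths=blens,
        )

    def pack(self, params, blen_scale: float | None = None) -> np.ndarray:
        """Build a start vector from a parameter object (for warm starts)."""
        if blen_scale is None:
            ids = self.cl.struct.branch_ids
            denom = float(np.sum(self.cl.input_lengths[ids]))
            numer = float(np.sum(params.branch_lengths[ids]))
            blen_scale = numer / denom if denom > 0 and numer > 0 else 1.0
        vals = []
        for name, bound in self.theta_spec:
            if name == "log_kappa":
                v = np.log(params.kappa)
            elif name == "log_omega":
                v = np.log(max(params.omega_background, 1e-4))
            elif name == "log_omega_bg":
                v = np.log(max(params.omega_background, 1e-4))
            elif name == "log_omega_fg":
                v = np.log(max(params.omega_foreground, 1e-4))
            elif name == "sm_a":
                p2 = max(1 - params.p0 - params.p1, 1e-4)
                v = np.log(max(params.p0, 1e-4) / p2)
            elif name == "sm_b":
                p2 = max(1 - params.p0 - params.p1, 1e-4)
                v = np.log(max(params.p1, 1e-4) / p2)
            elif name == "logit_w0":
                w0 = np.clip(params.omega0, 1e-5, 1 - 1e-5)
                v = np.log(w0 / (1 - w0))
            elif name == "u_w2":
                v = np.log(max(params.omega2 - 1.0, 1e-5))
            vals.append(np.clip(v, bound[0] + 1e-6, bound[1] - 1e-6))
        if self.config.branch_length_mode == "full":
            lens = [
                max(params.branch_lengths[b], 1e-4)
                for b in self.cl.struct.branch_ids
            ]
            vals += list(np.clip(np.log(lens), *_BOUND_LOG_BLEN))
        elif self.config.branch_length_mode == "scale":
            vals.append(np.clip(np.log(blen_scale), *_BOUND_LOG_SCALE))
        return np.array(vals)

    def default_start(self) -> np.ndarray:
        """The fixed start: kappa=2, omega=0.5 (and moderate class weights)."""
        start = {
            "log_kappa": np.log(2.0),
            "log_omega": np.log(0.5),
            "log_omega_bg": np.log(0.5),
            "log_omega_fg": np.log(0.5),
            "sm_a": np.log(0.7 / 0.1),
            "sm_b": np.log(0.2 / 0.1),
            "logit_w0": np.log(0.2 / 0.8),
            "u_w2": 0.0,
        }
        vals = [start[name] for name, _ in self.theta_spec]
        if self.config.branch_length_mode == "full":
            vals += list(
                np.clip(
                    np.log(np.maximum(
                        self.cl.input_lengths[self.cl.struct.branch_ids], 1e-3
                    )),
                    *_BOUND_LOG_BLEN,
                )
            )
        elif self.config.branch_length_mode == "scale":
            vals.append(0.0)
        return np.array(vals)

    def pattern_loglik(self, x: np.ndarray) -> np.ndarray:
        params = self.unpack(x)
        blens = params.branch_lengths
        if isinstance(params, BranchSiteParams):
            return self.cl.branch_site_pattern_loglik(params, blens)
        return self.cl.pattern_loglik(
            params.kappa, params.omega_background, params.omega_foreground, blens
        )


def fit_model(
    tree: LabeledTree,
    aln: CodonAlignment,
    model: str,
    config: FitConfig | None = None,
    start_params=None,
    evaluator: CodonLikelihood | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one codon model.

    Runs a fixed start (kappa=2, omega=0.5), ``config.n_restarts`` seeded
    random restarts, and optionally a warm start from ``start_params``
    (typically the matching null or M0 fit); returns the best.  Models other
    than M0 require at least one foreground branch on ``tree``.
    """
    if model not in _MODELS:
        raise InvalidParameterError(f"model must be one of {_MODELS}, got {model!r}")
    config = config or FitConfig()
    cl = evaluator if evaluator is not None else CodonLikelihood(tree, aln)
    if model != "M0" and cl.struct.foreground.sum() == 0:
        raise InvalidParameterError(f"model {model!r} needs a labeled foreground")
    par = _Parameterization(model, cl, config)

    def nll(x: np.ndarray) -> float:
        try:
            return -cl.total(par.pattern_loglik(x))
        except NumericalError:
            return 1e12

    starts = [par.default_start()]
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_restarts):
        starts.append(par.default_start() + rng.normal(0.0, 0.7, len(starts[0])))
    if start_params is not None:
        starts.append(par.pack(start_params))
    bounds = par.bounds
    starts = [np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
              for s in starts]

    best = None
    any_success = False
    for s in starts:
        res = minimize(
            nll, s, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = par.unpack(best.x)
    pattern_lnl = par.pattern_loglik(best.x)
    site_lnl = cl.expand(pattern_lnl)
    return ModelFit(
        model_name=model,
        params=params,
        lnL=cl.total(pattern_lnl),
        site_lnL=site_lnl,
        converged=any_success and np.isfinite(best.fun),
        n_restarts_used=len(starts),
        gene_id=aln.gene_id,
        freqs=cl.freqs,
        evaluator=cl,
    )


# ---------------------------------------------------------------------------
# tests and corrections


def lrt(fit_null: ModelFit, fit_alt: ModelFit, df: int = 1,
        tol: float = 0.05) -> LrtResult:
    """Likelihood-ratio test of nested fits; statistic clamped at zero.

    Raises if the alternative lnL falls below the null by more than ``tol``
    (an optimization failure, not a statistical result).
    """
    if df < 1:
        raise InvalidParameterError("df must be >= 1")
    stat = 2.0 * (fit_alt.lnL - fit_null.lnL)
    if stat < -2.0 * tol:
        raise UnconvergedFitError(
            f"alternative lnL {fit_alt.lnL:.6f} below null {fit_null.lnL:.6f}; "
            "refit with more restarts"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LrtResult(statistic=stat, df=df, p_value=p)


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * n_tests)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if n_tests is None:
        n_tests = p.size
    if n_tests < p.size:
        raise InvalidParameterError("n_tests must be >= number of p-values")
    return np.minimum(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# BEB site posteriors


def beb_site_posteriors(
    fit_alt: ModelFit,
    n_grid: int = 10,
    threshold: float = 0.95,
    omega2_max: float = 11.0,
) -> BebResult:
    """Bayes empirical Bayes posteriors for the positively selected classes.

    Empirical-Bayes averaging over a discrete grid on (p0, p1, omega0,
    omega2) with uniform prior weights, holding kappa and the branch lengths
    at their MLEs (Yang–Wong–Nielsen scheme).  The (p0, p1) simplex is
    gridded through s = p0 + p1 and r = p0 / s, each on ``n_grid`` midpoints
    of (0, 1); omega0 on midpoints of (0, 1); omega2 on midpoints of
    (1, omega2_max).
    """
    if fit_alt.model_name != "branch_site_alt":
        raise InvalidParameterError("BEB requires a branch-site alternative fit")
    if not fit_alt.converged:
        raise UnconvergedFitError("BEB refused: fit did not converge")
    cl = fit_alt.evaluator
    params: BranchSiteParams = fit_alt.params
    blens = params.branch_lengths
    mids = (2 * np.arange(n_grid) + 1) / (2 * n_grid)
    w0_grid = mids
    w2_grid = 1.0 + mids * (omega2_max - 1.0)
    s_grid, r_grid = mids, mids

    # per-class pattern logliks over the (w0, w2) grid; the per-class rate
    # calibration is held at the MLE mixture
    f_bg, f_fg = branch_site_rate_factors(cl.freqs, params)
    fgmask = cl.struct.foreground

    def t_eff(c: int) -> np.ndarray:
        return blens * np.where(fgmask, f_fg[c], f_bg[c])

    n_pat = cl.patterns.shape[1]
    l1 = cl.pattern_loglik(params.kappa, 1.0, 1.0, t_eff(1))
    l0 = np.empty((n_grid, n_pat))
    l2a = np.empty((n_grid, n_grid, n_pat))
    l2b = np.empty((n_grid, n_pat))
    for i, w0 in enumerate(w0_grid):
        l0[i] = cl.pattern_loglik(params.kappa, w0, w0, t_eff(0))
        for j, w2 in enumerate(w2_grid):
            l2a[i, j] = cl.pattern_loglik(params.kappa, w0, w2, t_eff(2))
    for j, w2 in enumerate(w2_grid):
        l2b[j] = cl.pattern_loglik(params.kappa, 1.0, w2, t_eff(3))

    # class proportions over the (s, r) grid
    W = np.empty((n_grid * n_grid, 4))
    k = 0
    for s in s_grid:
        for r in r_grid:
            p0, p1 = s * r, s * (1 - r)
            p2 = 1 - s
            W[k] = [p0, p1, p2 * r, p2 * (1 - r)]
            k += 1
    logW = np.log(np.clip(W, 1e-300, None))

    # accumulate grid-point data log-likelihoods and per-site class posteriors
    log_post = np.empty((n_grid, n_grid, n_grid * n_grid))
    numer = np.zeros((4, n_pat))  # unnormalized E[class indicator]
    cache_f = {}
    for i in range(n_grid):
        for j in range(n_grid):
            comps = np.stack([l0[i], l1, l2a[i, j], l2b[j]])  # (4, n_pat)
            f = logsumexp(logW[:, :, None] + comps[None, :, :], axis=1)
            cache_f[(i, j)] = (comps, f)
            log_post[i, j] = f @ cl.weights
    flat = log_post.reshape(-1)
    post = np.exp(flat - logsumexp(flat)).reshape(log_post.shape)
    for i in range(n_grid):
        for j in range(n_grid):
            comps, f = cache_f[(i, j)]
            # (grid_sr, 4, n_pat) conditional class posteriors
            cond = np.exp(logW[:, :, None] + comps[None, :, :] - f[:, None, :])
            numer += np.einsum("g,gcp->cp", post[i, j], cond)
    class_post_pat = numer / numer.sum(axis=0, keepdims=True)
    class_post = class_post_pat[:, cl.site_map].T  # (n_sites, 4)
    pos = class_post[:, 2] + class_post[:, 3]
    selected = [int(i) + 1 for i in np.nonzero(pos > threshold)[0]]
    return BebResult(
        site_posteriors=pos,
        class_posteriors=class_post,
        selected_sites=selected,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# per-branch rates


def branch_rates(fit: ModelFit) -> BranchRates:
    """Per-branch dN and dS from the Goldman–Yang decomposition.

    The generator on each branch splits into synonymous and nonsynonymous
    flux; normalizing each by the corresponding proportion of sites gives
    dN and dS with dN/dS equal to the branch's omega.  Zero-length branches
    report dN = dS = 0 with an undefined (nan) ratio.
    """
    if not fit.converged:
        raise UnconvergedFitError("branch rates require a converged fit")
    if not isinstance(fit.params, BranchModelParams):
        raise InvalidParameterError(
            "branch rates are defined for M0/branch fits with per-branch omega"
        )
    cl = fit.evaluator
    p = fit.params
    a_s, a_n = syn_nonsyn_flux(fit.freqs, p.kappa)
    frac_n = a_n / (a_s + a_n)  # proportion of nonsynonymous "sites"
    frac_s = 1.0 - frac_n
    ids = np.array(cl.struct.branch_ids)
    fg = cl.struct.foreground[ids]
    t = p.branch_lengths[ids]
    omega_branch = np.where(fg, p.omega_foreground, p.omega_background)
    rho = a_s + omega_branch * a_n  # total rate before unit scaling
    tau = np.where(rho > 0, t / rho, 0.0)
    syn_subs = tau * a_s
    nonsyn_subs = tau * omega_branch * a_n
    dS = syn_subs / (3.0 * frac_s)
    dN = nonsyn_subs / (3.0 * frac_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(dS > 0, dN / dS, np.nan)
    return BranchRates(
        node_ids=ids, foreground=fg, t=t, dN=dN, dS=dS, omega=ratio
    )
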