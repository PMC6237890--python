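import numpy as np
import pytest
from scipy.special import logsumexp

from pinnevo import genetic_code as gc
from pinnevo.codon_selection import (
    FitConfig,
    beb_site_posteriors,
    fit_model,
)
from pinnevo.errors import UnconvergedFitError
from pinnevo.io_formats import CodonAlignment, LabeledTree
from pinnevo.studies import SMALL_TREE_NEWICK
from pinnevo.synthetic_data import SimSpec, simulate_alignment


@pytest.fixture(scope="module")
def toy_fit():
    """Branch-site alternative fit on a small 4-taxon alignment."""
    tree = LabeledTree.from_newick("((A:0.2,B:0.3):0.1,(C#1:0.25,D:0.15):0.1);")
    rng = np.random.default_rng(77)
    rows = [
        "".join(gc.SENSE_CODONS[j] for j in rng.integers(0, 61, size=6))
        for _ in range(4)
    ]
    rows = ["ATG" + r[3:] for r in rows]  # site 0 invariant across taxa
    aln = CodonAlignment("toybeb", ["A", "B", "C", "D"], rows)
    return fit_model(tree, aln, "branch_site_alt", FitConfig(n_restarts=0))


class TestBebPosteriors:
    def test_class_posteriors_normalized(self, toy_fit):
        beb = beb_site_posteriors(toy_fit, n_grid=4)
        np.testing.assert_allclose(beb.class_posteriors.sum(axis=1), 1.0,
                                   atol=1e-8)

    def test_invariant_site_not_selected(self, toy_fit):
        beb = beb_site_posteriors(toy_fit, n_grid=4)
        assert beb.site_posteriors[0] < 0.5

    def test_matches_direct_grid_sum(self, toy_fit):
        """Oracle: the empirical-Bayes average recomputed by a plain loop
        over every grid point with explicit normalization."""
        n_grid = 4
        beb = beb_site_posteriors(toy_fit, n_grid=n_grid)
        cl = toy_fit.evaluator
        p = toy_fit.params
        blens = p.branch_lengths
        mids = (2 * np.arange(n_grid) + 1) / (2 * n_grid)
        w2_grid = 1.0 + mids * 10.0
        pts = []
        for s in mids:
            for r in mids:
                for w0 in mids:
                    for w2 in w2_grid:
                        pts.append((s * r, s * (1 - r), w0, w2))
        from pinnevo.codon_selection import syn_nonsyn_flux

        a_s, a_n = syn_nonsyn_flux(cl.freqs, p.kappa)

        def rho(w):
            return a_s + w * a_n

        props = p.class_proportions
        rho_bg = np.array([rho(p.omega0), rho(1.0), rho(p.omega0), rho(1.0)])
        rho_fg = np.array([rho(p.omega0), rho(1.0), rho(p.omega2),
                           rho(p.omega2)])
        fb = rho_bg / props.dot(rho_bg)
        ff = rho_fg / props.dot(rho_fg)
        fgmask = cl.struct.foreground

        def t_eff(c):
            return blens * np.where(fgmask, ff[c], fb[c])

        site_like = {}

        def class_logliks(w0, w2):
            key = (w0, w2)
            if key not in site_like:
                l0 = cl.pattern_loglik(p.kappa, w0, w0, t_eff(0))
                l1 = cl.pattern_loglik(p.kappa, 1.0, 1.0, t_eff(1))
                l2a = cl.pattern_loglik(p.kappa, w0, w2, t_eff(2))
                l2b = cl.pattern_loglik(p.kappa, 1.0, w2, t_eff(3))
                site_like[key] = np.vstack([l0, l1, l2a, l2b])
            return site_like[key]

        n_sites = toy_fit.site_lnL.shape[0]
        log_marg = []
        per_point = []
        for p0, p1, w0, w2 in pts:
            comps = class_logliks(w0, w2)[:, cl.site_map]
            p2 = 1 - p0 - p1
            tot = p0 + p1
            w = np.array([p0, p1, p2 * p0 / tot, p2 * p1 / tot])
            f = logsumexp(np.log(np.clip(w, 1e-300, None))[:, None] + comps,
                          axis=0)
            log_marg.append(f.sum())
            per_point.append(np.exp(
                np.log(np.clip(w, 1e-300, None))[:, None] + comps - f
            ))
        log_marg = np.array(log_marg)
        weights = np.exp(log_marg - logsumexp(log_marg))
        post = sum(wt * pp for wt, pp in zip(weights, per_point))
        post /= post.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(
            beb.site_posteriors, post[2] + post[3], atol=1e-8
        )

    def test_refuses_unconverged(self, toy_fit):
        import copy

        bad = copy.copy(toy_fit)
        bad.converged = False
        with pytest.raises(UnconvergedFitError):
            beb_site_posteriors(bad)


class TestBebRecovery:
    def test_selected_class_sites_have_higher_posterior(self):
        """Mean BEB posterior at simulated omega2 sites exceeds the rest."""
        tree = LabeledTree.from_newick(SMALL_TREE_NEWICK)
        spec = SimSpec(tree=tree, n_codons=200, model="branch_site_A",
                       p0=0.7, p1=0.2, omega0=0.1, omega2=8.0, seed=314)
        aln, _, truth = simulate_alignment(spec)
        fit = fit_model(tree, aln, "branch_site_alt", FitConfig(n_restarts=0))
        beb = beb_site_posteriors(fit)
        sel = np.isin(truth.site_classes, (2, 3))
        assert sel.any() and (~sel).any()
        assert beb.site_posteriors[sel].mean() > beb.site_posteriors[~sel].mean()
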