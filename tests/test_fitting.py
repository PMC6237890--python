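import numpy as np
import pytest

from pinnevo.codon_selection import (
    BranchModelParams,
    CodonLikelihood,
    FitConfig,
    ModelFit,
    bonferroni,
    branch_rates,
    fit_model,
    lrt,
    syn_nonsyn_flux,
)
from pinnevo.errors import InvalidParameterError, UnconvergedFitError
from pinnevo.io_formats import LabeledTree
from pinnevo.studies import SMALL_TREE_NEWICK
from pinnevo.synthetic_data import SimSpec, simulate_alignment


def _fit_dummy(lnl: float) -> ModelFit:
    params = BranchModelParams(2.0, 0.2, 0.2, np.zeros(1))
    return ModelFit("m", params, lnl, np.array([lnl]), True, 1)


class TestLrt:
    def test_equal_lnls_give_zero_and_p_one(self):
        r = lrt(_fit_dummy(-100.0), _fit_dummy(-100.0))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_chi_square_tail(self):
        # statistic 3.8415 with df 1 sits exactly at the 5% point
        r = lrt(_fit_dummy(-101.92075), _fit_dummy(-100.0), df=1)
        assert r.p_value == pytest.approx(0.05, abs=5e-4)

    def test_alt_below_null_raises(self):
        with pytest.raises(UnconvergedFitError):
            lrt(_fit_dummy(-100.0), _fit_dummy(-101.0))

    def test_small_negative_clamped(self):
        r = lrt(_fit_dummy(-100.0), _fit_dummy(-100.00001))
        assert r.statistic == 0.0

    def test_df_validated(self):
        with pytest.raises(InvalidParameterError):
            lrt(_fit_dummy(-1.0), _fit_dummy(-1.0), df=0)


class TestBonferroni:
    def test_simple_product(self):
        assert bonferroni([0.001], 10)[0] == pytest.approx(0.01)

    def test_capped_at_one(self):
        assert bonferroni([0.5], 10)[0] == 1.0

    def test_vector_elementwise(self, rng):
        p = rng.uniform(size=5)
        np.testing.assert_allclose(bonferroni(p, 7), np.minimum(1.0, p * 7))

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            bonferroni([1.5], 2)
        with pytest.raises(InvalidParameterError):
            bonferroni([0.1, 0.2], 1)


@pytest.fixture(scope="module")
def small_tree() -> LabeledTree:
    return LabeledTree.from_newick(SMALL_TREE_NEWICK)


@pytest.fixture(scope="module")
def m0_gene(small_tree):
    spec = SimSpec(tree=small_tree, n_codons=500, model="M0", omega=0.3,
                   kappa=2.0, seed=424242)
    aln, _, _ = simulate_alignment(spec)
    return aln


class TestFitModel:
    def test_m0_parameter_recovery(self, small_tree, m0_gene):
        """Fitting M0 to M0 data recovers omega within +-0.1 at 500 codons."""
        fit = fit_model(small_tree, m0_gene, "M0", FitConfig(n_restarts=1))
        assert fit.converged
        assert fit.params.omega_background == pytest.approx(0.3, abs=0.1)
        assert fit.params.kappa == pytest.approx(2.0, abs=0.6)

    def test_site_lnl_sums_to_total(self, small_tree, m0_gene):
        fit = fit_model(small_tree, m0_gene, "M0", FitConfig(n_restarts=0))
        assert fit.lnL == pytest.approx(fit.site_lnL.sum(), abs=1e-6)

    def test_nested_models_never_lose_likelihood(self, small_tree, m0_gene):
        cfg = FitConfig(n_restarts=0)
        cl = CodonLikelihood(small_tree, m0_gene)
        m0 = fit_model(small_tree, m0_gene, "M0", cfg, evaluator=cl)
        br = fit_model(small_tree, m0_gene, "branch", cfg,
                       start_params=m0.params, evaluator=cl)
        bs0 = fit_model(small_tree, m0_gene, "branch_site_null", cfg,
                        evaluator=cl)
        bs1 = fit_model(small_tree, m0_gene, "branch_site_alt", cfg,
                        start_params=bs0.params, evaluator=cl)
        assert br.lnL >= m0.lnL - 1e-4
        assert bs1.lnL >= bs0.lnL - 1e-4

    def test_unknown_model_rejected(self, small_tree, m0_gene):
        with pytest.raises(InvalidParameterError):
            fit_model(small_tree, m0_gene, "M8")

    def test_foreground_required(self, m0_gene):
        unlabeled = LabeledTree.from_newick(
            SMALL_TREE_NEWICK.replace("#1", "")
        )
        with pytest.raises(InvalidParameterError):
            fit_model(unlabeled, m0_gene, "branch")


class TestBranchRates:
    def test_neutral_branch_ratio_one_and_decomposition(self, small_tree, m0_gene):
        cfg = FitConfig(n_restarts=0)
        fit = fit_model(small_tree, m0_gene, "M0", cfg)
        rates = branch_rates(fit)
        # M0: every branch shares omega, so dN/dS == fitted omega everywhere
        w = fit.params.omega_background
        finite = rates.omega[np.isfinite(rates.omega)]
        np.testing.assert_allclose(finite, w, rtol=1e-6)
        # oracle: dS from the flux decomposition directly
        a_s, a_n = syn_nonsyn_flux(fit.freqs, fit.params.kappa)
        ids = rates.node_ids
        t = fit.params.branch_lengths[ids]
        tau = t / (a_s + w * a_n)
        frac_s = a_s / (a_s + a_n)
        np.testing.assert_allclose(rates.dS, tau * a_s / (3 * frac_s), rtol=1e-9)

    def test_zero_length_branch(self, small_tree, m0_gene):
        fit = fit_model(small_tree, m0_gene, "M0", FitConfig(n_restarts=0))
        fit.params.branch_lengths[:] = 0.0
        rates = branch_rates(fit)
        assert np.all(rates.dN == 0) and np.all(rates.dS == 0)
        assert np.all(~np.isfinite(rates.omega))

    def test_refuses_unconverged(self, small_tree, m0_gene):
        fit = fit_model(small_tree, m0_gene, "M0", FitConfig(n_restarts=0))
        fit.converged = False
        with pytest.raises(UnconvergedFitError):
            branch_rates(fit)
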