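import math

import numpy as np
import pytest

from codonsel.sfs_selection import (
    DEFAULT_BOUNDS,
    ModelFit,
    SelectionParams,
    expected_sfs_equilibrium,
    expected_sfs_expansion,
    fit_model,
    lrt,
    fit_binned,
    sfs_loglik,
)

from oracles import equilibrium_sfs_quadrature, wf_expansion_sfs


def tv(a, b):
    return 0.5 * float(np.abs(np.asarray(a) - np.asarray(b)).sum())


class TestEquilibriumSFS:
    def test_symmetry_when_neutral_and_unbiased(self):
        p = expected_sfs_equilibrium(SelectionParams(0.01, 0.01, 0.0), 12)
        np.testing.assert_allclose(p, p[::-1], rtol=1e-10)

    def test_small_sample_against_quadrature(self):
        p = expected_sfs_equilibrium(SelectionParams(0.01, 0.01, 0.0), 2)
        assert p[1] == pytest.approx(0.0098, abs=2e-4)
        q = equilibrium_sfs_quadrature(0.01, 0.01, 0.0, 2)
        np.testing.assert_allclose(p, q, rtol=1e-8)

    def test_strong_selection_fixes_focal_state(self):
        p = expected_sfs_equilibrium(SelectionParams(0.005, 0.005, 40.0), 10)
        assert p[-1] > 0.99

    def test_normalisation_and_positivity(self):
        for gamma in (-3.0, 0.0, 2.5):
            p = expected_sfs_equilibrium(SelectionParams(0.003, 0.02, gamma), 47)
            assert p.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(p >= 0)

    def test_focal_relabel_duality(self):
        # reversing the spectrum is the same as swapping theta01/theta10 and
        # flipping the sign of gamma
        p = expected_sfs_equilibrium(SelectionParams(0.004, 0.015, 1.3), 20)
        q = expected_sfs_equilibrium(SelectionParams(0.015, 0.004, -1.3), 20)
        np.testing.assert_allclose(p, q[::-1], rtol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            SelectionParams(0.0, 0.01)
        with pytest.raises(ValueError):
            expected_sfs_equilibrium(SelectionParams(0.01, 0.01), 1)


class TestExpansionSFS:
    def test_g_one_reduces_to_equilibrium(self):
        params = SelectionParams(0.01, 0.02, 1.0, g=1.0, tau=0.7)
        p = expected_sfs_expansion(params, 10)
        q = expected_sfs_equilibrium(params, 10)
        assert tv(p, q) < 1e-8

    def test_tau_zero_is_initial_equilibrium(self):
        params = SelectionParams(0.01, 0.02, 1.0, g=4.0, tau=0.0)
        p = expected_sfs_expansion(params, 10)
        q = expected_sfs_equilibrium(params, 10)
        assert tv(p, q) < 1e-8

    def test_matches_wright_fisher_oracle(self):
        # the spec's reference point: theta=0.01, gamma=1, g=4, tau=0.1, n=10
        p = expected_sfs_expansion(SelectionParams(0.01, 0.01, 1.0, 4.0, 0.1), 10)
        w = wf_expansion_sfs(0.01, 0.01, 1.0, 4.0, 0.1, 10)
        assert tv(p, w) < 5e-3

    def test_duality_under_expansion(self):
        params = SelectionParams(0.004, 0.012, 0.9, g=3.0, tau=0.2)
        swapped = SelectionParams(0.012, 0.004, -0.9, g=3.0, tau=0.2)
        p = expected_sfs_expansion(params, 14)
        q = expected_sfs_expansion(swapped, 14)
        np.testing.assert_allclose(p, q[::-1], atol=1e-8)

    def test_normalisation(self):
        p = expected_sfs_expansion(SelectionParams(0.005, 0.011, 0.8, 3.7, 0.026), 47)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(p >= 0)


class TestLoglik:
    def test_direct_value(self):
        ll = sfs_loglik(np.array([2.0, 1.0, 1.0]), np.array([0.5, 0.25, 0.25]))
        assert ll == pytest.approx(2 * math.log(0.5) + 2 * math.log(0.25))

    def test_maximised_at_empirical_frequencies(self, rng):
        c = rng.integers(1, 50, size=6).astype(float)
        p_hat = c / c.sum()
        best = sfs_loglik(c, p_hat)
        for _ in range(30):
            q = rng.dirichlet(np.ones(6))
            assert sfs_loglik(c, q) <= best + 1e-9

    def test_zero_probability_with_counts(self):
        assert sfs_loglik(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == -math.inf

    def test_single_class(self):
        ll = sfs_loglik(np.array([0.0, 7.0, 0.0]), np.array([0.3, 0.5, 0.2]))
        assert ll == pytest.approx(7 * math.log(0.5))


class TestFitting:
    def test_symmetric_neutral_data_recovers_neutrality(self):
        truth = SelectionParams(0.008, 0.008, 0.0)
        counts = expected_sfs_equilibrium(truth, 20) * 2e5
        fit = fit_model(counts, model="L0", n_starts=6, seed=3)
        assert abs(fit.params.gamma) < 0.05
        assert fit.params.kappa == pytest.approx(1.0, abs=0.05)

    def test_l0_recovers_generating_parameters(self):
        truth = SelectionParams(0.006, 0.012, 1.2)
        counts = expected_sfs_equilibrium(truth, 24) * 1e6
        fit = fit_model(counts, model="L0", n_starts=6, seed=5)
        assert fit.params.gamma == pytest.approx(1.2, rel=0.02)
        assert fit.params.kappa == pytest.approx(2.0, rel=0.02)

    def test_nested_model_ordering(self):
        truth = SelectionParams(0.005, 0.011, 0.8, 3.7, 0.026)
        counts = expected_sfs_expansion(truth, 12) * 1e5
        l1 = fit_model(counts, model="L1", n_starts=4, seed=11)
        ns = fit_model(counts, model="NS", n_starts=4, seed=11)
        l0 = fit_model(counts, model="L0", n_starts=4, seed=11)
        assert ns.loglik <= l1.loglik + 1e-6
        assert l0.loglik <= l1.loglik + 1e-6

    def test_fixed_parameters_respected(self):
        counts = expected_sfs_equilibrium(SelectionParams(0.01, 0.01, 0.5), 10) * 1e4
        fit = fit_model(counts, model="L0", n_starts=3, seed=2, fixed={"gamma": 0.0})
        assert fit.params.gamma == 0.0

    def test_empty_sfs_errors(self):
        with pytest.raises(ValueError):
            fit_model(np.zeros(11), model="L0", n_starts=2, seed=1)


class TestLRT:
    def test_printed_loglikelihood_arithmetic(self):
        chi2, p = lrt(-1643574.0, -1647996.0, df=2)
        assert chi2 == pytest.approx(8844.0)
        assert p < 1e-300 or p == 0.0
        chi2b, _ = lrt(-1223811.0, -1224835.0, df=1)
        assert chi2b == pytest.approx(2048.0)

    def test_identical_fits(self):
        chi2, p = lrt(-100.0, -100.0, df=1)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_inverted_ordering_errors(self):
        with pytest.raises(ValueError):
            lrt(-101.0, -100.0, df=1)


class TestFitBinned:
    def test_bins_of_equal_size_and_ordering(self):
        rng = np.random.default_rng(42)
        gammas = [0.2, 0.2, 1.0, 1.0, 2.5, 2.5, 4.0, 4.0]
        spectra = []
        for gm in gammas:
            p = expected_sfs_equilibrium(SelectionParams(0.008, 0.016, gm), 16)
            spectra.append(p * 2e5)
        cov = np.array(gammas) + rng.normal(0, 1e-3, len(gammas))
        df = fit_binned(spectra, cov, k=4, model="L0", n_boot=0, seed=1, n_starts=4)
        assert (df.n_genes == 2).all()
        fitted = df.gamma.to_numpy()
        assert np.all(np.diff(fitted) > 0)

    def test_identical_genes_identical_gamma(self):
        p = expected_sfs_equilibrium(SelectionParams(0.01, 0.02, 1.0), 12) * 1e5
        spectra = [p.copy() for _ in range(8)]
        cov = np.arange(8.0)
        df = fit_binned(spectra, cov, k=4, model="L0", n_boot=0, seed=2, n_starts=3)
        np.testing.assert_allclose(df.gamma, df.gamma.iloc[0], atol=0.02)

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            fit_binned([np.ones(5)] * 3, [1.0, 2.0, 3.0], k=4)
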