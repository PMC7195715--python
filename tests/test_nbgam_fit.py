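import numpy as np
import pytest

from nbgam import nbgam_fit as fm
from nbgam._likelihood import nb_deviance
from nbgam.inference import build_design_matrices
from nbgam.io_design import parse_design
from nbgam.simulate import SimulationConfig, simulate_dataset


def poisson_irls(y, X, offset, tol=1e-12, max_iter=200):
    """Independent unpenalized Poisson GLM solver (log link)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() + 0.5)
    for _ in range(max_iter):
        eta = offset + X @ beta
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        W = mu
        A = X.T @ (X * W[:, None])
        beta_new = np.linalg.solve(A, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


@pytest.fixture(scope="module")
def gene_setup(small_scenario1, smooth_design):
    ds, dm = small_scenario1, smooth_design
    off = np.zeros(ds.counts.n_samples)
    return ds, dm, off


class TestPirls:
    def test_poisson_limit_matches_independent_solver(self, gene_setup):
        ds, dm, off = gene_setup
        X = np.column_stack([np.ones(len(ds.x)), ds.x])
        for i in [0, 5, 17]:
            y = ds.counts.counts[i].astype(float)
            beta, *_ = fm.pirls_fit(y, X, [], np.empty(0), 1e-8, off)
            oracle = poisson_irls(y, X, off)
            np.testing.assert_allclose(beta, oracle, atol=1e-4)

    def test_infinite_penalty_reduces_to_linear_fit(self, gene_setup):
        ds, dm, off = gene_setup
        y = ds.counts.counts[3].astype(float)
        alpha = 0.1
        _, mu_smooth, *_ = fm.pirls_fit(
            y, dm.X, dm.penalties, np.array([1e9]), alpha, off
        )
        Xlin = np.column_stack([np.ones(len(ds.x)), ds.x])
        _, mu_lin, *_ = fm.pirls_fit(y, Xlin, [], np.empty(0), alpha, off)
        np.testing.assert_allclose(mu_smooth, mu_lin, rtol=1e-4)

    def test_constant_counts_intercept_closed_form(self, gene_setup):
        _, dm, off = gene_setup
        m = dm.X.shape[0]
        y = np.full(m, 7.0)
        X = np.ones((m, 1))
        beta, mu, *_ = fm.pirls_fit(y, X, [], np.empty(0), 0.3, off)
        assert beta[0] == pytest.approx(np.log(7.0), abs=1e-8)
        np.testing.assert_allclose(mu, 7.0, rtol=1e-8)

    def test_penalized_deviance_non_increasing(self, gene_setup):
        # re-run PIRLS manually, tracking accepted penalized deviance
        ds, dm, off = gene_setup
        rng = np.random.default_rng(7)
        for i in rng.choice(ds.counts.n_genes, size=25, replace=False):
            y = ds.counts.counts[i].astype(float)
            lam = np.array([rng.uniform(0.01, 100)])
            beta, mu, eta, dev, pdev, conv, it = fm.pirls_fit(
                y, dm.X, dm.penalties, lam, 0.2, off
            )
            # final penalized deviance must not exceed that of the
            # least-squares initialization
            z0 = np.log(y + 0.5) - off
            beta0 = np.linalg.lstsq(dm.X, z0, rcond=None)[0]
            mu0 = np.exp(off + dm.X @ beta0)
            pdev0 = nb_deviance(y, mu0, 0.2) + lam[0] * beta0 @ dm.penalties[0] @ beta0
            assert pdev <= pdev0 + 1e-8

    def test_sample_permutation_equivariance(self, gene_setup):
        ds, dm, off = gene_setup
        rng = np.random.default_rng(5)
        perm = rng.permutation(ds.counts.n_samples)
        y = ds.counts.counts[2].astype(float)
        fit = fm.fit_gene(y, dm.X, dm.penalties, 0.15, off,
                          slices=dm.slices, smooth_slices=dm.smooth_slices)
        fit_p = fm.fit_gene(y[perm], dm.X[perm], dm.penalties, 0.15, off[perm],
                            slices=dm.slices, smooth_slices=dm.smooth_slices)
        np.testing.assert_allclose(fit_p.mu_hat, fit.mu_hat[perm], atol=1e-8)
        np.testing.assert_allclose(fit_p.beta, fit.beta, atol=1e-8)
        np.testing.assert_allclose(fit_p.lam, fit.lam, rtol=1e-3)
        assert fit_p.edf_total == pytest.approx(fit.edf_total, abs=1e-6)


class TestAffineInvariance:
    def test_rescaled_covariate_gives_same_fitted_means(self, gene_setup):
        # mapping x to [0,1] reparameterizes the basis; the selected fit's
        # means must be unchanged
        ds, _, off = gene_setup
        from nbgam.smooth_basis import build_smooth

        y = ds.counts.counts[6].astype(float)
        mus = []
        for xv in (ds.x, (ds.x - ds.x.min()) / np.ptp(ds.x)):
            sb = build_smooth(xv, k=10)
            X = np.column_stack([np.ones(len(xv)), sb.X_s])
            S = np.zeros((10, 10))
            S[1:, 1:] = sb.S
            fit = fm.fit_gene(y, X, [S], 0.12, off,
                              slices={"x": slice(1, 10)},
                              smooth_slices={"x": slice(1, 10)})
            mus.append(fit.mu_hat)
        np.testing.assert_allclose(mus[0], mus[1], rtol=1e-6)


class TestEdf:
    def _fit(self, gene_setup, lam):
        ds, dm, off = gene_setup
        y = ds.counts.counts[1].astype(float)
        return ds, dm, off, fm.finalize_fit(
            y, dm.X, dm.penalties, np.array([lam]), 0.1, off,
            dm.slices, dm.smooth_slices,
        )

    def test_unpenalized_edf_is_column_count(self, gene_setup):
        _, dm, _, fit = self._fit(gene_setup, 1e-12)
        k_minus_1 = dm.smooth_kminus1["x"]
        assert fit.edf_term["x"] == pytest.approx(k_minus_1, abs=1e-6)

    def test_infinite_penalty_edf_is_one(self, gene_setup):
        *_, fit = self._fit(gene_setup, 1e12)
        assert fit.edf_term["x"] == pytest.approx(1.0, abs=1e-4)

    def test_trace_formula_matches_dense_hat_matrix(self, gene_setup):
        ds, dm, off, fit = self._fit(gene_setup, 3.7)
        from nbgam._likelihood import nb_weights

        w = nb_weights(fit.mu_hat, fit.alpha)
        XtWX = dm.X.T @ (dm.X * w[:, None])
        A = XtWX + 3.7 * dm.penalties[0]
        # dense hat matrix on the working data scale
        sw = np.sqrt(w)
        Xs = dm.X * sw[:, None]
        H = Xs @ np.linalg.solve(A, Xs.T)
        assert fit.edf_total == pytest.approx(np.trace(H), abs=1e-8)

    def test_edf_within_bounds(self, gene_setup):
        ds, dm, off = gene_setup
        for lam in [1e-4, 1.0, 1e3, 1e8]:
            *_, fit = self._fit(gene_setup, lam)
            assert 1 - 1e-6 <= fit.edf_term["x"] <= dm.smooth_kminus1["x"] + 1e-6


class TestSmoothingSelection:
    def test_gamma_monotone_model_size(self, gene_setup):
        ds, dm, off = gene_setup
        de_idx = np.where(ds.truth_de)[0]
        edf25, edf1 = [], []
        for i in list(de_idx) + [0, 1, 2, 3]:
            y = ds.counts.counts[i].astype(float)
            for gamma, store in ((2.5, edf25), (1.0, edf1)):
                lam = fm.select_smoothing(
                    y, dm.X, dm.penalties, 0.1, off, gamma=gamma,
                    smooth_slices=dm.smooth_slices,
                )
                fit = fm.finalize_fit(y, dm.X, dm.penalties, lam, 0.1, off,
                                      dm.slices, dm.smooth_slices)
                store.append(fit.edf_term["x"])
        assert np.mean(edf25) <= np.mean(edf1) + 1e-6

    def test_linear_truth_selects_small_edf(self):
        # genes with a purely linear mean trend should shrink to ~1 edf
        rng = np.random.default_rng(21)
        m = 200
        x = rng.uniform(20, 80, m)
        from nbgam.smooth_basis import build_smooth

        sb = build_smooth(x, k=10)
        X = np.column_stack([np.ones(m), sb.X_s])
        S = np.zeros((10, 10))
        S[1:, 1:] = sb.S
        off = np.zeros(m)
        edfs = []
        for _ in range(12):
            mu = np.exp(3.0 + 0.01 * (x - 50))
            y = rng.poisson(rng.gamma(10.0, mu / 10.0)).astype(float)
            lam = fm.select_smoothing(y, X, [S], 0.1, off, gamma=2.5,
                                      smooth_slices={"x": slice(1, 10)})
            fit = fm.finalize_fit(y, X, [S], lam, 0.1, off,
                                  {"x": slice(1, 10)}, {"x": slice(1, 10)})
            edfs.append(fit.edf_term["x"])
        assert np.median(edfs) <= 1.2

    def test_nonlinear_signal_selects_larger_edf(self, gene_setup):
        ds, dm, off = gene_setup
        de_idx = np.where(ds.truth_type == "nonlinear")[0]
        edfs = []
        for i in de_idx:
            y = ds.counts.counts[i].astype(float)
            lam = fm.select_smoothing(y, dm.X, dm.penalties, 0.1, off,
                                      gamma=2.5, smooth_slices=dm.smooth_slices)
            fit = fm.finalize_fit(y, dm.X, dm.penalties, lam, 0.1, off,
                                  dm.slices, dm.smooth_slices)
            edfs.append(fit.edf_term["x"])
        assert max(edfs) >= 2.0


class TestInformationCriteria:
    def test_monotone_in_edf_at_equal_loglik(self):
        aic1, bic1 = fm.information_criteria(-100.0, 2.0, 30)
        aic2, bic2 = fm.information_criteria(-100.0, 5.0, 30)
        assert aic1 < aic2 and bic1 < bic2

    def test_bic_penalizes_harder_for_m_at_least_8(self):
        for m in [8, 30, 500]:
            aic, bic = fm.information_criteria(-50.0, 3.0, m)
            assert bic > aic

    def test_definition_recomputable_from_fields(self, gene_setup):
        ds, dm, off = gene_setup
        y = ds.counts.counts[0].astype(float)
        fit = fm.fit_gene(y, dm.X, dm.penalties, 0.1, off,
                          slices=dm.slices, smooth_slices=dm.smooth_slices)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.edf_total, abs=1e-10)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + np.log(len(y)) * fit.edf_total, abs=1e-10
        )
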