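"""Covariance assembly, BLUP, prediction covariance and REML."""

import numpy as np
import pytest

import metsel as ms
from metsel.mge_model import predictor_matrix, restricted_loglik

from conftest import make_grm


def small_vc(t=2, sg=1.0, tau0=0.5, se=1.0):
    return ms.VarianceComponents(np.full(t, sg), tau0 if t > 1 else 0.0, np.full(t, se))


def random_phenotypes(design, rng, mu=(100.0, 150.0, 200.0)):
    return ms.PhenotypeSet(
        [mu[j] + rng.normal(size=n) for j, n in enumerate(design.sizes)]
    )


class TestTypes:
    def test_design_rejects_duplicates_within_environment(self):
        with pytest.raises(ValueError, match="duplicate"):
            ms.TrainingDesign([np.array([0, 0, 1])])

    def test_design_allows_overlap_across_environments(self):
        d = ms.TrainingDesign([np.array([0, 1]), np.array([0, 1])])
        assert d.sizes == (2, 2) and d.n_train == 4

    def test_design_csv_roundtrip(self, tmp_path, small_grm):
        d = ms.TrainingDesign([np.array([0, 3]), np.array([2, 5, 7])])
        f = tmp_path / "design.csv"
        d.to_frame(small_grm.genotype_ids).to_csv(f, index=False)
        back = ms.TrainingDesign.from_csv(f, small_grm.genotype_ids)
        assert back.key() == d.key()

    def test_vc_rejects_non_psd_omega(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            ms.VarianceComponents([1.0, 1.0], 1.5, [1.0, 1.0])

    def test_vc_heritability_split(self):
        vc = ms.VarianceComponents.from_heritability([20.0, 10.0], 5.0, 0.5)
        np.testing.assert_allclose(vc.sigma_e, [20.0, 10.0])


class TestBuildCovariances:
    def test_single_environment_degeneration(self, small_grm):
        d = ms.TrainingDesign([np.array([1, 4, 6])])
        vc = ms.VarianceComponents([2.5], 0.0, [1.0])
        b = ms.build_covariances(small_grm, d, vc)
        np.testing.assert_allclose(b.G_tr, 2.5 * small_grm.K[np.ix_([1, 4, 6], [1, 4, 6])])

    def test_kronecker_structure(self):
        K = make_grm(3, 200, seed=2)
        d = ms.TrainingDesign([np.array([0, 1]), np.array([1, 2])])
        b = ms.build_covariances(K, d, small_vc())
        expected = np.block([[K.K, 0.5 * K.K], [0.5 * K.K, K.K]])
        np.testing.assert_allclose(b.G_cp, expected, atol=1e-12)
        # cross-covariance blocks slice the same Kronecker matrix
        cols = d.flat_columns(3)
        np.testing.assert_allclose(b.G_cp_tr, expected[:, cols], atol=1e-12)

    def test_centering_annihilates_constants(self, small_grm):
        d = ms.TrainingDesign([np.array([0, 1, 2]), np.array([3, 4])])
        b = ms.build_covariances(small_grm, d, small_vc())
        const = np.concatenate([np.full(3, 4.2), np.full(2, -1.1)])
        np.testing.assert_allclose(b.M_tr @ const, 0, atol=1e-12)

    def test_centering_block_idempotent_up_to_residual_factor(self, small_grm):
        d = ms.TrainingDesign([np.array([0, 1, 2])])
        vc = ms.VarianceComponents([1.0], 0.0, [2.0])
        b = ms.build_covariances(small_grm, d, vc)
        np.testing.assert_allclose(b.M_tr @ b.M_tr, b.M_tr / 2.0, atol=1e-12)

    def test_out_of_range_index_rejected(self, small_grm):
        d = ms.TrainingDesign([np.array([0, 99])])
        with pytest.raises(ValueError, match="out of range"):
            ms.build_covariances(small_grm, d, ms.VarianceComponents([1.0], 0.0, [1.0]))


class TestBlup:
    def test_constant_phenotypes_give_zero_blup(self, small_grm):
        d = ms.TrainingDesign([np.array([0, 1, 2]), np.array([2, 3, 4])])
        b = ms.build_covariances(small_grm, d, small_vc())
        y = ms.PhenotypeSet([np.full(3, 7.0), np.full(3, -3.0)])
        np.testing.assert_allclose(ms.blup_training(b, y), 0, atol=1e-10)
        pred = ms.predict_candidates(b, y)
        np.testing.assert_allclose(pred.h_hat_cp, 0, atol=1e-10)

    def test_matches_henderson_equations_with_explicit_fixed_effects(self, rng):
        # independent oracle: solve the full mixed-model equations with the
        # environment-mean incidence matrix written out
        K = make_grm(4, 300, seed=4)
        d = ms.TrainingDesign([np.array([0, 2])])
        vc = ms.VarianceComponents([1.7], 0.0, [0.9])
        b = ms.build_covariances(K, d, vc)
        y = random_phenotypes(d, rng)
        X = np.ones((2, 1))
        Rinv = np.eye(2) / 0.9
        Ginv = np.linalg.inv(b.G_tr)
        lhs = np.block(
            [[X.T @ Rinv @ X, X.T @ Rinv], [Rinv @ X, Rinv + Ginv]]
        )
        rhs = np.concatenate([X.T @ Rinv @ y.stacked, Rinv @ y.stacked])
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(ms.blup_training(b, y), sol[1:], atol=1e-8)

    def test_joint_scaling_invariance(self, small_grm, rng):
        d = ms.TrainingDesign([np.array([0, 1, 5]), np.array([2, 3])])
        y = random_phenotypes(d, rng)
        g1 = ms.blup_training(ms.build_covariances(small_grm, d, small_vc()), y)
        doubled = ms.VarianceComponents([2.0, 2.0], 1.0, [2.0, 2.0])
        g2 = ms.blup_training(ms.build_covariances(small_grm, d, doubled), y)
        np.testing.assert_allclose(g1, g2, atol=1e-9)

    def test_environment_mean_invariance(self, small_grm, rng):
        d = ms.TrainingDesign([np.array([0, 1, 5]), np.array([2, 3, 6])])
        b = ms.build_covariances(small_grm, d, small_vc())
        y = random_phenotypes(d, rng)
        y_shift = ms.PhenotypeSet([y.values[0] + 55.0, y.values[1] - 12.0])
        np.testing.assert_allclose(
            ms.blup_training(b, y), ms.blup_training(b, y_shift), atol=1e-9
        )
        p1 = ms.predict_candidates(b, y)
        p2 = ms.predict_candidates(b, y_shift)
        np.testing.assert_allclose(p1.h_hat_cp, p2.h_hat_cp, atol=1e-9)


class TestPredictionCovariance:
    def test_two_printed_forms_agree(self, small_grm, rng):
        d = ms.TrainingDesign([np.array([0, 1, 2, 3]), np.array([2, 4, 6, 7])])
        b = ms.build_covariances(small_grm, d, small_vc())
        y = random_phenotypes(d, rng)
        pred = ms.predict_candidates(b, y)
        g_hat = ms.blup_training(b, y)
        h_via_gtr = b.G_cp_tr @ np.linalg.solve(b.G_tr, g_hat)
        np.testing.assert_allclose(pred.h_hat_cp, h_via_gtr, atol=1e-8)

    def test_all_singleton_design_gives_zero_covariance(self, small_grm):
        d = ms.TrainingDesign([np.array([0]), np.array([5])])
        b = ms.build_covariances(small_grm, d, small_vc())
        np.testing.assert_allclose(ms.prediction_covariance(b), 0, atol=1e-12)

    def test_blup_shrinkage_and_cd_bounds(self, small_grm):
        d = ms.TrainingDesign([np.array([0, 1, 2, 3]), np.array([2, 4, 6, 7])])
        b = ms.build_covariances(small_grm, d, small_vc())
        A = ms.prediction_covariance(b)
        assert np.abs(A - A.T).max() < 1e-10
        # Var(h_hat) <= G_cp in the PSD order
        assert np.linalg.eigvalsh(b.G_cp - A).min() > -1e-6
        diag_b = np.diag(b.G_cp)
        ok = diag_b > 0
        cd = np.diag(A)[ok] / diag_b[ok]
        assert cd.min() >= -1e-10 and cd.max() < 1.0

    def test_monte_carlo_covariance_small(self, small_grm, rng):
        # light simulation check of Var(h_hat); the stringent version runs in
        # the acceptance suite
        d = ms.TrainingDesign([np.array([0, 1, 2, 3]), np.array([4, 5, 6, 7])])
        vc = small_vc()
        b = ms.build_covariances(small_grm, d, vc)
        A = ms.prediction_covariance(b)
        C = predictor_matrix(b)
        cfg = ms.SimulationConfig([100.0, 150.0], vc, n_replicates=1, master_seed=0)
        from metsel.evaluation import _genetic_factor

        L = _genetic_factor(small_grm, vc)
        n = 60_000
        H = (L @ rng.standard_normal((16, n))).T
        cols = d.flat_columns(8)
        E = rng.standard_normal((n, 8))
        Y = H[:, cols] + E
        S = np.cov(Y @ C.T, rowvar=False)
        se = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S**2) / (n - 1))
        assert (np.abs(S - A) <= 4 * se + 1e-12).all()


class TestReml:
    def test_t1_matches_grid_search(self, rng):
        # single-environment GBLUP: refine a 2-D grid over (sigma2_G,
        # sigma2_E) on the same restricted likelihood
        K = make_grm(25, 400, seed=15, n_subpops=2, fst=0.3)
        truth = ms.VarianceComponents([4.0], 0.0, [2.0])
        cfg = ms.SimulationConfig([100.0], truth, n_replicates=1, master_seed=11)
        trial = ms.simulate_truth(K, cfg, 0)
        d = ms.TrainingDesign([np.sort(rng.choice(25, 15, replace=False))])
        y = ms.PhenotypeSet([trial.phenotypes[d.subsets[0], 0]])
        fit = ms.fit_reml(K, d, y)
        assert fit.converged

        lo = np.array([0.05, 0.05])
        hi = np.array([40.0, 40.0])
        for _ in range(6):
            g1 = np.linspace(lo[0], hi[0], 21)
            g2 = np.linspace(lo[1], hi[1], 21)
            ll = np.array(
                [
                    [
                        restricted_loglik(K, d, y, ms.VarianceComponents([a], 0.0, [b]))
                        for b in g2
                    ]
                    for a in g1
                ]
            )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            best = np.array([g1[i], g2[j]])
            step = np.array([g1[1] - g1[0], g2[1] - g2[0]])
            lo = np.maximum(best - step, 1e-3)
            hi = best + step
        est = np.array([fit.vc.sigma_gxe[0], fit.vc.sigma_e[0]])
        np.testing.assert_allclose(est, best, rtol=2e-3)

    def test_null_tau0_recovery(self):
        # data generated with tau0 = 0: the mean estimate over replicates
        # stays within 2 standard errors of zero
        K = make_grm(60, 600, seed=16, n_subpops=3, fst=0.3)
        truth = ms.VarianceComponents.from_heritability([10.0, 10.0], 0.0, 0.5)
        cfg = ms.SimulationConfig([100.0, 150.0], truth, n_replicates=50, master_seed=31)
        rng = np.random.default_rng(8)
        d = ms.TrainingDesign(
            [rng.choice(60, 30, replace=False), rng.choice(60, 30, replace=False)]
        )
        estimates = []
        for r in range(50):
            trial = ms.simulate_truth(K, cfg, r)
            y = ms.PhenotypeSet([trial.phenotypes[s, j] for j, s in enumerate(d.subsets)])
            estimates.append(ms.fit_reml(K, d, y).vc.tau0)
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean()) < 2 * se

    def test_rejects_degenerate_designs(self, small_grm):
        y = ms.PhenotypeSet([np.array([1.0]), np.array([2.0])])
        with pytest.raises(ValueError):
            ms.fit_reml(small_grm, ms.TrainingDesign([np.array([0]), np.array([1])]), y)
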