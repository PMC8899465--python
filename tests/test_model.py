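"""Centering, design assembly, penalties, the penalized solver and LOOCV."""

import numpy as np
import pytest

from lfdat import (
    FunctionOnFunctionRegression,
    GenotypeRegion,
    LongitudinalPhenotype,
    ScenarioConfig,
    SingularSystemError,
    build_design,
    build_penalties,
    center_data,
    make_bspline_basis,
    penalized_solve,
    simulate_dataset,
)
from lfdat.basis import BetaSurface, genotype_functional_weights


def _toy(n=6, L=4, n_times=5, seed=0):
    rng = np.random.default_rng(seed)
    geno = GenotypeRegion(
        subject_ids=np.arange(n),
        positions=(np.arange(L) + 0.5) / L,
        G=rng.integers(0, 3, (n, L)),
    )
    pheno = LongitudinalPhenotype(
        subject_ids=np.arange(n),
        time_grid=np.arange(1.0, n_times + 1),
        Y=rng.standard_normal((n, n_times)),
    )
    return geno, pheno


class TestCentering:
    def test_hand_centering(self):
        geno, pheno = _toy(n=2, L=2, n_times=2)
        pheno.Y = np.array([[1.0, 3.0], [3.0, 1.0]])
        _, Yc, mean_curve, _ = center_data(geno, pheno)
        np.testing.assert_array_equal(Yc, [[-1, 1], [1, -1]])
        np.testing.assert_array_equal(mean_curve, [2, 2])

    def test_constant_phenotype(self):
        geno, pheno = _toy()
        pheno.Y = np.ones_like(pheno.Y)
        _, Yc, mean_curve, _ = center_data(geno, pheno)
        np.testing.assert_array_equal(Yc, 0.0)
        np.testing.assert_array_equal(mean_curve, 1.0)

    def test_idempotent(self):
        geno, pheno = _toy()
        Xc, Yc, _, _ = center_data(geno, pheno)
        np.testing.assert_allclose(Xc.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Yc.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Yc - Yc.mean(axis=0), Yc, atol=1e-12)

    def test_single_subject_rejected(self):
        geno, pheno = _toy(n=1)
        with pytest.raises(ValueError):
            center_data(geno, pheno)


class TestDesign:
    def test_matches_dense_quadrature_oracle(self):
        # Psi[(i,q),(j,k)] must equal integral x_i*(s) phi_j(s) ds * phi_k(t_q)
        geno, pheno = _toy(n=5, L=3, n_times=4, seed=1)
        model = FunctionOnFunctionRegression(
            geno, pheno, m_s=4, m_t=4, order_s=4, order_t=4
        )
        Psi = model.design()
        assert Psi.shape == (5 * 4, 16)
        Xc = geno.G - geno.G.mean(axis=0)
        mids = (geno.positions[:-1] + geno.positions[1:]) / 2
        left = np.concatenate([[0.0], mids])
        right = np.concatenate([mids, [1.0]])
        Bt = model.t_basis.evaluate(pheno.time_norm)
        for i in range(5):
            integrals = np.zeros(4)
            for l in range(3):
                grid = np.linspace(left[l], right[l], 4001)
                B = model.s_basis.evaluate(grid)
                integrals += Xc[i, l] * np.trapezoid(B, grid, axis=0)
            for q in range(4):
                for j in range(4):
                    for k in range(4):
                        assert Psi[i * 4 + q, j * 4 + k] == pytest.approx(
                            integrals[j] * Bt[q, k], abs=1e-7
                        )

    def test_zero_genotypes_give_zero_design_and_coefficients(self):
        geno, pheno = _toy(n=5, L=3)
        geno.G[:] = 1.0  # constant -> centered zero
        model = FunctionOnFunctionRegression(geno, pheno, m_s=4, m_t=4)
        assert np.all(model.design() == 0.0)
        res = model.fit(lambda1=10.0, lambda2=10.0)
        np.testing.assert_allclose(res.surface.coef, 0.0, atol=1e-12)


class TestPenalties:
    def setup_method(self):
        self.sb = make_bspline_basis(0, 1, 7, 4)
        self.tb = make_bspline_basis(0, 1, 6, 4)
        self.pen = build_penalties(self.sb, self.tb)

    def _greville(self, basis):
        k = basis.order
        return np.array(
            [basis.knots[j + 1 : j + k].mean() for j in range(basis.n_basis)]
        )

    def test_linear_in_s_annihilated(self, rng):
        # coefficients at Greville abscissae reproduce linear functions
        xi = self._greville(self.sb)
        coef = np.outer(1.5 + 2.0 * xi, rng.standard_normal(6))
        b = coef.ravel()
        assert b @ self.pen.R1 @ b == pytest.approx(0.0, abs=1e-10)

    def test_linear_in_t_annihilated(self, rng):
        xi = self._greville(self.tb)
        coef = np.outer(rng.standard_normal(7), -0.5 + 3.0 * xi)
        b = coef.ravel()
        assert b @ self.pen.R2 @ b == pytest.approx(0.0, abs=1e-10)

    def test_quadratic_form_matches_dense_integration(self, rng):
        from scipy.integrate import simpson

        coef = rng.standard_normal((7, 6))
        b = coef.ravel()
        s = np.linspace(0, 1, 4001)
        t = np.linspace(0, 1, 4001)
        d2s = self.sb.evaluate_derivative(s, 2)
        Bt = self.tb.evaluate(t)
        vals = d2s @ coef @ Bt.T  # d2 beta / ds2 on the grid
        inner = simpson(vals**2, x=t, axis=1)
        dense = simpson(inner, x=s)
        assert b @ self.pen.R1 @ b == pytest.approx(dense, rel=1e-6)

    def test_psd(self):
        for R in (self.pen.R1, self.pen.R2):
            assert np.min(np.linalg.eigvalsh((R + R.T) / 2)) >= -1e-10

    def test_low_order_rejected(self):
        sb = make_bspline_basis(0, 1, 4, 2)
        with pytest.raises(ValueError):
            build_penalties(sb, self.tb)


class TestPenalizedSolve:
    def test_zero_response(self, rng):
        Psi = rng.standard_normal((20, 6))
        R = np.eye(6)
        b = penalized_solve(Psi, np.zeros(20), R, R, 1.0, 1.0)
        np.testing.assert_allclose(b, 0.0, atol=1e-12)

    def test_matches_direct_inverse(self, rng):
        Psi = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        R1 = rng.standard_normal((6, 6))
        R1 = R1 @ R1.T
        R2 = np.eye(6)
        b = penalized_solve(Psi, y, R1, R2, 0.7, 1.3)
        expected = np.linalg.inv(Psi.T @ Psi + 0.7 * R1 + 1.3 * R2) @ Psi.T @ y
        np.testing.assert_allclose(b, expected, atol=1e-8)

    def test_singular_system_raises_with_remedy(self):
        geno, pheno = _toy(n=5, L=3, n_times=3)
        model = FunctionOnFunctionRegression(geno, pheno, m_s=6, m_t=6)
        with pytest.raises(SingularSystemError, match="lambda"):
            model.fit(lambda1=0.0, lambda2=0.0)

    def test_penalty_limit_smooths_surface(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        model = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8)
        pen = model.penalties
        roughness = []
        for lam in [1e0, 1e4, 1e8, 1e12]:
            b = model.fit(lambda1=lam, lambda2=lam).surface.coef.ravel()
            roughness.append(b @ pen.R1 @ b + b @ pen.R2 @ b)
        assert all(a >= b_ - 1e-12 for a, b_ in zip(roughness, roughness[1:]))
        assert roughness[-1] < 1e-6 * (roughness[0] + 1e-30) + 1e-10


class TestFitInvariants:
    def test_normal_equation_residual(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        model = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8)
        res = model.fit(lambda1=1e2, lambda2=1e3)
        A = model._system(res.lambda1, res.lambda2)
        b = res.surface.coef.ravel()
        rhs = model._rhs
        assert np.linalg.norm(A @ b - rhs) / np.linalg.norm(rhs) <= 1e-8

    def test_fitted_plus_residuals_identity(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        res = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8).fit(
            lambda1=1.0, lambda2=1.0
        )
        Yc = pheno.Y - pheno.Y.mean(axis=0)
        np.testing.assert_allclose(res.fitted + res.residuals, Yc, atol=1e-12)
        np.testing.assert_allclose(
            res.rss1_by_time, (res.residuals**2).sum(axis=0), atol=1e-12
        )

    def test_training_rss_nondecreasing_in_lambda(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        model = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8)
        for other in (1e2, 1e5):
            rss = [
                model.fit(lambda1=lam, lambda2=other).rss1_by_time.sum()
                for lam in (1e1, 1e3, 1e5, 1e7)
            ]
            assert all(a <= b + 1e-9 for a, b in zip(rss, rss[1:]))

    def test_constant_shift_equivariance(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        res1 = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8).fit(
            lambda1=10.0, lambda2=10.0
        )
        shifted = LongitudinalPhenotype(
            subject_ids=pheno.subject_ids, time_grid=pheno.time_grid, Y=pheno.Y + 7.5
        )
        res2 = FunctionOnFunctionRegression(geno, shifted, m_s=8, m_t=8).fit(
            lambda1=10.0, lambda2=10.0
        )
        np.testing.assert_allclose(res2.mean_curve, res1.mean_curve + 7.5, atol=1e-10)
        np.testing.assert_allclose(res2.surface.coef, res1.surface.coef, atol=1e-10)
        np.testing.assert_allclose(res2.fitted, res1.fitted, atol=1e-10)

    def test_refit_with_selected_lambdas_is_deterministic(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        model = FunctionOnFunctionRegression(geno, pheno, m_s=6, m_t=6)
        res = model.fit(cv_grid=(1e2, 1e4))
        res2 = model.fit(lambda1=res.lambda1, lambda2=res.lambda2)
        np.testing.assert_array_equal(res.surface.coef, res2.surface.coef)


class TestLoocv:
    def test_single_element_grid(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        model = FunctionOnFunctionRegression(geno, pheno, m_s=6, m_t=6)
        l1, l2, table = model.loocv_select(grid=(1e3,))
        assert (l1, l2) == (1e3, 1e3)
        assert len(table) == 1

    def test_default_grid_has_25_pairs(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        model = FunctionOnFunctionRegression(geno, pheno, m_s=6, m_t=6)
        _, _, table = model.loocv_select()
        assert len(table) == 25

    def test_block_identity_matches_explicit_refit(self):
        # 10 subjects: leave-one-subject-out by hat-matrix blocks vs refitting
        cfg = ScenarioConfig(n=10, L=6, region_class="common", c=5.0, seed=23)
        geno, pheno, _, _ = simulate_dataset(cfg)
        model = FunctionOnFunctionRegression(geno, pheno, m_s=5, m_t=5)
        lam1, lam2 = 5.0, 2.0
        fast = model.loocv_score(lam1, lam2)
        Yc = pheno.Y - pheno.Y.mean(axis=0)
        Psi = model.design()
        ystack = Yc.ravel()
        Q1 = pheno.n_times
        A_pen = lam1 * model.penalties.R1 + lam2 * model.penalties.R2
        total = 0.0
        for i in range(10):
            keep = np.ones(10 * Q1, dtype=bool)
            keep[i * Q1 : (i + 1) * Q1] = False
            Pk, yk = Psi[keep], ystack[keep]
            b = np.linalg.solve(Pk.T @ Pk + A_pen, Pk.T @ yk)
            pred = Psi[i * Q1 : (i + 1) * Q1] @ b
            total += np.sum((ystack[i * Q1 : (i + 1) * Q1] - pred) ** 2)
        assert fast == pytest.approx(total, rel=1e-8)

    def test_tie_breaks_toward_smoother(self):
        # all-zero design: every lambda pair has identical CV score
        geno, pheno = _toy(n=8, L=3, n_times=4, seed=3)
        geno.G[:] = 2.0
        model = FunctionOnFunctionRegression(geno, pheno, m_s=4, m_t=4)
        l1, l2, _ = model.loocv_select(grid=(1e2, 1e3))
        assert (l1, l2) == (1e3, 1e3)

    def test_too_few_subjects_rejected(self):
        geno, pheno = _toy(n=2, L=3)
        model = FunctionOnFunctionRegression(geno, pheno, m_s=4, m_t=4)
        with pytest.raises(ValueError):
            model.loocv_select()


class TestPredict:
    def test_in_sample_identity(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        res = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8).fit(
            lambda1=1.0, lambda2=1.0
        )
        np.testing.assert_allclose(
            res.predict(geno), res.fitted + res.mean_curve, atol=1e-10
        )

    def test_mean_genotype_predicts_mean_curve(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        res = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8).fit(
            lambda1=1.0, lambda2=1.0
        )
        avg = GenotypeRegion(
            subject_ids=np.array([0, 1]),
            positions=geno.positions,
            G=np.vstack([geno.G.mean(axis=0)] * 2),
        )
        np.testing.assert_allclose(
            res.predict(avg), np.vstack([res.mean_curve] * 2), atol=1e-10
        )

    def test_matches_dense_quadrature(self):
        geno, pheno = _toy(n=6, L=4, n_times=5, seed=9)
        model = FunctionOnFunctionRegression(geno, pheno, m_s=5, m_t=5)
        res = model.fit(lambda1=0.5, lambda2=0.5)
        new = GenotypeRegion(
            subject_ids=np.array([0]),
            positions=geno.positions,
            G=np.array([[2.0, 0.0, 1.0, 2.0]]),
        )
        got = res.predict(new)[0]
        # direct: mu(t) + integral (x - xbar)(s) beta(s, t) ds by dense quadrature
        xc = new.G[0] - geno.G.mean(axis=0)
        mids = (geno.positions[:-1] + geno.positions[1:]) / 2
        left = np.concatenate([[0.0], mids])
        right = np.concatenate([mids, [1.0]])
        for q, tn in enumerate(pheno.time_norm):
            acc = 0.0
            for l in range(4):
                grid = np.linspace(left[l], right[l], 2001)
                from lfdat import eval_surface

                beta_vals = eval_surface(res.surface, grid, [tn])[:, 0]
                acc += xc[l] * np.trapezoid(beta_vals, grid)
            assert got[q] == pytest.approx(res.mean_curve[q] + acc, abs=1e-6)

    def test_position_mismatch_rejected(self, small_dataset):
        _, geno, pheno, _, _ = small_dataset
        res = FunctionOnFunctionRegression(geno, pheno, m_s=8, m_t=8).fit(
            lambda1=1.0, lambda2=1.0
        )
        other = GenotypeRegion(
            subject_ids=geno.subject_ids,
            positions=np.linspace(0.05, 0.9, geno.L),
            G=geno.G,
        )
        with pytest.raises(ValueError):
            res.predict(other)
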