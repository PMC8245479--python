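"""RR-BLUP core: mixed-model equations, REML, GEBV prediction."""

import numpy as np
import pytest

from harvestgs.rrblup import (
    MarkerEffects,
    MixedModelSpec,
    VarianceComponents,
    estimate_variance_components,
    predict_gebv,
    solve_mme,
)


def _vc(ridge, m=50):
    """Variance components with a prescribed ridge, for solver tests."""
    s2e = 1.0
    s2g = s2e * m / ridge
    return VarianceComponents(
        sigma2_m=s2g / m, sigma2_g=s2g, sigma2_e=s2e,
        sigma2_a=s2g, sigma2_p=s2g + s2e, ridge=ridge, n_markers=m,
    )


def _instance(rng, n=30, m=50, p=2):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    Z = rng.standard_normal((n, m))
    Z = (Z - Z.mean(0)) / Z.std(0)
    y = rng.standard_normal(n)
    return MixedModelSpec(y=y, X=X, Z=Z)


class TestSolveMME:
    def test_matches_absorbed_ridge_closed_form(self, rng):
        """Independent oracle: absorb X, then plain ridge regression."""
        spec = _instance(rng, n=30, m=50)
        eff = solve_mme(spec, _vc(2.0))
        X, Z, y = spec.X, spec.Z, spec.y
        M = np.eye(30) - X @ np.linalg.pinv(X.T @ X) @ X.T
        a_oracle = np.linalg.solve(Z.T @ M @ Z + 2.0 * np.eye(50), Z.T @ M @ y)
        np.testing.assert_allclose(eff.a_hat, a_oracle, atol=1e-8)

    def test_block_equations_reproduce_rhs(self, rng):
        spec = _instance(rng)
        eff = solve_mme(spec, _vc(3.0))
        X, Z, y = spec.X, spec.Z, spec.y
        sol = np.concatenate([eff.beta_hat, eff.a_hat])
        C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + 3.0 * np.eye(50)]])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        rel = np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs)
        assert rel < 1e-8

    def test_infinite_shrinkage_kills_effects(self, rng):
        spec = _instance(rng)
        eff = solve_mme(spec, _vc(1e12))
        assert np.max(np.abs(eff.a_hat)) < 1e-6

    def test_constant_phenotype_gives_zero_effects(self, rng):
        spec = _instance(rng)
        spec.y = np.full_like(spec.y, 3.25)
        eff = solve_mme(spec, _vc(1.0))
        np.testing.assert_allclose(eff.a_hat, 0.0, atol=1e-10)
        assert eff.beta_hat[0] == pytest.approx(3.25)

    def test_shrinkage_monotone_in_ridge(self, rng):
        spec = _instance(rng)
        norms = [
            float(np.sum(solve_mme(spec, _vc(lam)).a_hat ** 2))
            for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_rank_deficient_fixed_design_names_columns(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        spec = MixedModelSpec(
            y=rng.standard_normal(n), X=X, Z=rng.standard_normal((n, 5)),
            fixed_names=["intercept", "dup"],
        )
        with pytest.raises(ValueError, match="aliased"):
            solve_mme(spec, _vc(1.0, m=5))


class TestPredictGEBV:
    def test_zero_effects_zero_gebv(self, rng):
        eff = MarkerEffects(beta_hat=np.zeros(1), a_hat=np.zeros(10))
        out = predict_gebv(rng.standard_normal((5, 10)), eff)
        np.testing.assert_array_equal(out.gebv.to_numpy(), 0.0)

    def test_single_marker_identity(self):
        eff = MarkerEffects(beta_hat=np.zeros(1), a_hat=np.array([1.0]))
        out = predict_gebv(np.array([[-1.0], [0.0], [1.0]]), eff)
        np.testing.assert_allclose(out.gebv.to_numpy(), [-1.0, 0.0, 1.0])

    def test_matches_elementwise_double_loop(self, rng):
        Z = rng.standard_normal((20, 40))
        a = rng.standard_normal(40)
        eff = MarkerEffects(beta_hat=np.zeros(1), a_hat=a)
        out = predict_gebv(Z, eff)
        brute = np.array([sum(Z[i, j] * a[j] for j in range(40)) for i in range(20)])
        np.testing.assert_allclose(out.gebv.to_numpy(), brute, atol=1e-10)

    def test_marker_order_aligned_by_id(self, rng):
        Z = rng.standard_normal((8, 4))
        ids = np.array(["m1", "m2", "m3", "m4"])
        a = rng.standard_normal(4)
        eff = MarkerEffects(beta_hat=np.zeros(1), a_hat=a, marker_ids=ids)
        direct = predict_gebv(Z, eff, marker_ids=ids)
        perm = np.array([2, 0, 3, 1])
        shuffled = predict_gebv(Z[:, perm], eff, marker_ids=ids[perm])
        np.testing.assert_allclose(direct.gebv.to_numpy(), shuffled.gebv.to_numpy())

    def test_marker_mismatch_lists_difference(self, rng):
        eff = MarkerEffects(
            beta_hat=np.zeros(1), a_hat=np.zeros(3), marker_ids=np.array(["a", "b", "c"])
        )
        with pytest.raises(ValueError, match="d"):
            predict_gebv(rng.standard_normal((2, 3)), eff, marker_ids=["a", "b", "d"])


def _gblup_gebv(spec, vc):
    """Individual-level BLUP with G = ZZ' sigma2_m (the equivalent model)."""
    Z, X, y = spec.Z, spec.X, spec.y
    G = Z @ Z.T * vc.sigma2_m
    V = G + vc.sigma2_e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return G @ Vi @ (y - X @ beta)


class TestEquivalence:
    def test_rrblup_equals_gblup(self, rng):
        spec = _instance(rng, n=50, m=100, p=3)
        vc = _vc(7.5, m=100)
        eff = solve_mme(spec, vc)
        np.testing.assert_allclose(spec.Z @ eff.a_hat, _gblup_gebv(spec, vc), atol=1e-6)

    def test_gebv_invariant_to_row_and_column_order(self, rng):
        spec = _instance(rng, n=25, m=30)
        vc = _vc(4.0, m=30)
        g = spec.Z @ solve_mme(spec, vc).a_hat
        rp = rng.permutation(25)
        cp = rng.permutation(30)
        spec2 = MixedModelSpec(y=spec.y[rp], X=spec.X[rp], Z=spec.Z[rp][:, cp])
        g2 = spec2.Z @ solve_mme(spec2, vc).a_hat
        np.testing.assert_allclose(g2, g[rp], atol=1e-8)


class TestREML:
    def test_noise_free_limit(self, rng):
        n, m = 200, 80
        Z = rng.standard_normal((n, m))
        Z = (Z - Z.mean(0)) / Z.std(0)
        y = Z @ rng.standard_normal(m) * 0.3
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), Z=Z)
        vc = estimate_variance_components(spec)
        assert vc.sigma2_e / vc.sigma2_p < 0.05

    def test_pure_noise_limit(self, rng):
        n, m = 500, 100
        Z = rng.standard_normal((n, m))
        Z = (Z - Z.mean(0)) / Z.std(0)
        spec = MixedModelSpec(y=rng.standard_normal(n), X=np.ones((n, 1)), Z=Z)
        vc = estimate_variance_components(spec)
        assert vc.sigma2_g / vc.sigma2_p < 0.1

    def test_ridge_consistent_with_components(self, rng):
        spec = _instance(rng, n=100, m=60)
        spec.y = spec.Z @ rng.standard_normal(60) * 0.2 + rng.standard_normal(100)
        vc = estimate_variance_components(spec)
        assert vc.ridge == pytest.approx(vc.sigma2_e * vc.n_markers / vc.sigma2_g)
        assert vc.sigma2_m == pytest.approx(vc.sigma2_g / vc.n_markers)
        assert vc.reml_trace is not None and len(vc.reml_trace) > 0
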