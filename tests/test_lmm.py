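"""Mixed-model core: REML, GLS plug-in, random-effect test, smoothing and
rescaling."""

import numpy as np
import pytest

from trajdecon import StateDesign, build_trajectory_weights, normalize_abundances, smooth_abundances
from trajdecon import test_random_effect as random_effect_lrt
from trajdecon.lmm import (
    NullModelWorkspace,
    VarianceComponents,
    estimate_state_abundances,
    estimate_state_abundances_exact,
    restricted_loglik,
)

from _oracles import build_dense_V, dense_restricted_loglik, naive_gls_excluding_state


def _manual_vc(n, lambda2, sigma_e2, U=None, s=None):
    """VarianceComponents with a hand-chosen covariance (for GLS-only tests)."""
    if U is None:
        U = np.zeros((n, 1))
        s = np.zeros(1)
    return VarianceComponents(
        theta=0.0, lambda2=lambda2, sigma_e2=sigma_e2,
        loglik_reml=0.0, loglik_no_random=0.0, n_genes=n, _U=U, _s=s,
    )


def _simple_design(X, C=None, Z=None):
    n, m = X.shape
    C = np.empty((n, 0)) if C is None else C
    Z = X if Z is None else Z
    k = Z.shape[1]
    return StateDesign(
        m_states=m,
        state_members=[np.array([i]) for i in range(m)] if k == m else
        [np.array_split(np.arange(k), m)[i] for i in range(m)],
        state_pseudotime=np.linspace(0, 1, m),
        X=X, C=C, Z=Z,
        signature_genes=np.array([f"g{i}" for i in range(n)]),
        cell_pseudotime=np.linspace(0, 1, k),
        cell_ids=np.array([f"c{i}" for i in range(k)]),
        other_types=[],
    )


class TestGls:
    def test_identity_covariance_reduces_to_ols(self, rng):
        X = rng.normal(1, 0.3, (40, 3))
        y = rng.normal(0, 1, 40)
        design = _simple_design(X)
        vc = _manual_vc(40, lambda2=0.0, sigma_e2=2.5)
        raw, se, _ = estimate_state_abundances(y, design, vc)
        for i in range(3):
            x = X[:, i]
            np.testing.assert_allclose(raw[i], (x @ y) / (x @ x), rtol=1e-12)

    def test_exact_profile_recovered_without_noise(self):
        x = np.linspace(1, 3, 25)
        design = _simple_design(x[:, None] * np.ones((1, 1)))
        vc = _manual_vc(25, lambda2=0.0, sigma_e2=1.0)
        raw, se, _ = estimate_state_abundances(x.copy(), design, vc)
        assert raw[0] == pytest.approx(1.0, rel=1e-12)

    def test_fast_path_matches_naive_dense_inverse(self, tiny_design, rng):
        design, weights, workspace = tiny_design
        y = design.X @ np.array([0.1, 0.3, 0.2, 0.25, 0.15]) * 5 + rng.normal(0, 1, design.n_genes)
        vc = workspace.fit(y)
        raw, _, _ = estimate_state_abundances(y, design, vc, workspace=workspace)
        for i in range(design.m_states):
            oracle = naive_gls_excluding_state(y, design, weights, vc, i)
            assert abs(raw[i] - oracle) < 1e-8

    def test_singular_state_gives_nan_not_failure(self, rng):
        X = rng.normal(1, 0.3, (30, 3))
        X[:, 1] = 0.0  # degenerate profile
        design = _simple_design(X)
        vc = _manual_vc(30, lambda2=0.0, sigma_e2=1.0)
        with pytest.warns(UserWarning, match="singular"):
            raw, se, _ = estimate_state_abundances(rng.normal(0, 1, 30), design, vc)
        assert np.isnan(raw[1]) and np.isfinite(raw[0]) and np.isfinite(raw[2])


class TestReml:
    def test_loglik_matches_dense_reference_formula(self, tiny_design, rng):
        design, weights, workspace = tiny_design
        y = rng.normal(0, 1, design.n_genes) + design.Z.mean(axis=1)
        vc = workspace.fit(y)
        V = build_dense_V(design.Z, weights.W, weights.d, vc.theta, vc.lambda2, vc.sigma_e2)
        ll = dense_restricted_loglik(y, design.C, V)
        assert vc.loglik_reml == pytest.approx(ll, abs=1e-8)
        # package's own dense reference agrees too
        assert restricted_loglik(y, design.C, vc.V) == pytest.approx(ll, abs=1e-8)

    def test_zero_variance_truth_hits_boundary(self, tiny_design, rng):
        design, _, workspace = tiny_design
        # pure noise around the covariate mean: no random-effect signal
        y = design.C @ np.array([1.0]) + rng.normal(0, 1, design.n_genes) \
            if design.C.size else rng.normal(0, 1, design.n_genes)
        vc = workspace.fit(y)
        assert vc.lambda2 == pytest.approx(0.0, abs=5e-2)

    def test_V_is_symmetric_positive_definite(self, tiny_design, rng):
        design, _, workspace = tiny_design
        y = design.Z @ rng.normal(0, 0.2, design.k_cells) + rng.normal(0, 1, design.n_genes)
        vc = workspace.fit(y)
        V = vc.V
        np.testing.assert_allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > 0

    def test_plugin_approximation_tracks_full_refit(self, rng):
        # fast path (one null V-hat) vs per-state full REML refit
        from trajdecon import build_states, cp10k, filter_genes, generate_synthetic_reference
        from trajdecon.reference import ReferenceSet

        ref, _ = generate_synthetic_reference(250, 120, 2, 120, seed=8, focal_frac=0.9)
        refn = filter_genes(
            ReferenceSet(cp10k(ref.expr), ref.gene_ids, ref.cell_ids, ref.cell_type,
                         ref.pseudotime, ref.focal_type), 0.1)
        from trajdecon import select_signature_genes

        sig = select_signature_genes(refn, 150)
        design = build_states(refn, 30, sig)
        scale = design.Z.mean(axis=1)
        design.X /= scale[:, None]
        design.Z /= scale[:, None]
        if design.C.size:
            design.C /= scale[:, None]
        weights = build_trajectory_weights(design.cell_pseudotime)
        workspace = NullModelWorkspace(design, weights)
        truth = np.exp(-((np.linspace(0, 1, 30) - 0.4) ** 2) / 0.05)
        y = design.X @ (truth / truth.sum()) * 10 + rng.normal(0, 0.3, design.n_genes)
        vc = workspace.fit(y)
        fast, _, _ = estimate_state_abundances(y, design, vc, workspace=workspace)
        slow = estimate_state_abundances_exact(y, design, workspace)
        r = np.corrcoef(fast, slow)[0, 1]
        assert r > 0.99


class TestRandomEffectTest:
    def test_zero_statistic_gives_half(self):
        vc = _manual_vc(10, 0.0, 1.0)
        vc.loglik_reml = vc.loglik_no_random = -12.0
        assert random_effect_lrt(vc) == pytest.approx(0.5)

    def test_null_calibration_and_power(self):
        """Mixture LRT: conservative under lambda^2 = 0, powerful when the
        random-effect variance dominates."""
        rng = np.random.default_rng(42)
        n, k = 80, 20
        Z = np.abs(rng.normal(1, 0.4, (n, k)))
        pt = np.sort(rng.uniform(0, 1, k))
        weights = build_trajectory_weights(pt, bandwidth=8.0)
        design = _simple_design(Z[:, :2], Z=Z)
        workspace = NullModelWorkspace(design, weights)
        Pinv = np.linalg.inv(weights.precision(0.5))
        L = np.linalg.cholesky(Pinv)

        null_hits = 0
        n_null = 400
        for _ in range(n_null):
            y = rng.normal(0, 1, n)
            null_hits += random_effect_lrt(workspace.fit(y)) < 0.05
        # binomial upper bound at p=0.05, n=400: ~0.05 + 2.6 sd
        assert null_hits / n_null <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_null)

        power_hits = 0
        n_alt = 100
        for _ in range(n_alt):
            alpha = np.sqrt(5.0) * (L @ rng.standard_normal(k))
            y = Z @ alpha + rng.normal(0, 1, n)
            power_hits += random_effect_lrt(workspace.fit(y)) < 0.05
        assert power_hits / n_alt >= 0.95


class TestSmoothing:
    @pytest.mark.parametrize("method", ["loess", "knn"])
    def test_constant_profile_unchanged(self, method):
        t = np.linspace(0, 1, 20)
        out = smooth_abundances(np.full(20, 3.3), t, method=method)
        np.testing.assert_allclose(out, 3.3, rtol=1e-9)

    def test_none_is_identity(self, rng):
        raw = rng.normal(0, 1, 15)
        out = smooth_abundances(raw, np.linspace(0, 1, 15), method="none")
        np.testing.assert_array_equal(out, raw)

    @pytest.mark.parametrize("method", ["loess", "knn"])
    def test_noise_reduced_on_smooth_truth(self, method):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 1, 50)
        truth = np.sin(2 * np.pi * t)
        noisy = truth + rng.normal(0, 0.3, 50)
        sm = smooth_abundances(noisy, t, method=method)
        rmsd_before = np.sqrt(np.mean((noisy - truth) ** 2))
        rmsd_after = np.sqrt(np.mean((sm - truth) ** 2))
        assert rmsd_after < rmsd_before

    def test_invalid_span_and_q_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            smooth_abundances(np.ones(10), t, method="loess", span=0.0)
        with pytest.raises(ValueError):
            smooth_abundances(np.ones(10), t, method="knn", q=11)
        with pytest.raises(ValueError):
            smooth_abundances(np.ones(10), t, method="median")


class TestNormalize:
    def test_truncate_then_scale(self):
        np.testing.assert_allclose(
            normalize_abundances(np.array([-1.0, 1.0, 3.0])), [0.0, 0.25, 0.75]
        )

    def test_uniform_profile(self):
        np.testing.assert_allclose(normalize_abundances(np.full(4, 2.0)), 0.25)

    def test_already_normalized_unchanged(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(normalize_abundances(v), v)

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_abundances(np.array([-1.0, 0.0, -2.0]))

    def test_output_in_simplex(self, rng):
        for _ in range(20):
            raw = rng.normal(0, 1, 30)
            if np.any(raw > 0):
                out = normalize_abundances(raw)
                assert out.min() >= 0 and out.max() <= 1
                assert out.sum() == pytest.approx(1.0)


def test_car_covariance_pd_for_theta_in_unit_interval(rng):
    """(D - theta W)^-1 lambda^2 is symmetric PD across random weight graphs."""
    for _ in range(5):
        pt = rng.uniform(0, 1, 10)
        w = build_trajectory_weights(pt)
        for theta in (0.0, 0.3, 0.7, 0.95):
            Sigma = np.linalg.inv(w.precision(theta))
            np.testing.assert_allclose(Sigma, Sigma.T, atol=1e-10)
            assert np.linalg.eigvalsh(Sigma).min() > 0
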