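"""Matrix-comparison statistics: exact identities, independent oracles,
resampling behavior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from shapevar._geometry import nearest_psd, vech
from shapevar.compare import (
    bca_interval,
    krzanowski_compare,
    random_skewers,
    reference_basis,
    reml_mvn_resample,
    vector_angle,
    vector_correlation,
)
from shapevar.varcomp import CovarianceMatrix


def _psd(rng, p, rank=None):
    a = rng.standard_normal((p, rank or p))
    return a @ a.T


class TestReferenceBasis:
    def test_diagonal_matrix_gives_axis_vectors(self):
        k = reference_basis(np.diag([3.0, 2.0, 1.0]), 2)
        np.testing.assert_allclose(np.abs(k), np.eye(3)[:, :2], atol=1e-12)
        assert k[0, 0] > 0 and k[1, 1] > 0  # sign convention

    def test_sign_convention_independent_of_decomposition_sign(self, rng):
        m = _psd(rng, 6)
        k1 = reference_basis(m, 3)
        # rebuilding M from negated eigenvectors must give the same basis
        vals, vecs = np.linalg.eigh(m)
        m2 = (-vecs * vals) @ (-vecs).T
        k2 = reference_basis(m2, 3)
        np.testing.assert_allclose(k1, k2, atol=1e-8)

    def test_q_exceeding_rank_raises(self, rng):
        m = _psd(rng, 16, rank=12)
        with pytest.raises(ValueError, match="rank"):
            reference_basis(m, 13)
        k = reference_basis(m, 6)
        np.testing.assert_allclose(k.T @ k, np.eye(6), atol=1e-10)


class TestKrzanowski:
    def test_self_comparison_exact(self, rng):
        a = _psd(rng, 8)
        k = reference_basis(a, 5)
        out = krzanowski_compare(a, a, k)
        assert out.r == pytest.approx(1.0, abs=1e-12)
        assert out.b == pytest.approx(1.0, abs=1e-12)

    def test_squared_eigenvalues_give_slope_two(self, rng):
        vals = np.array([4.0, 3.0, 2.0, 1.5, 1.0, 0.5])
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        a = (q * vals) @ q.T
        b = (q * vals**2) @ q.T
        out = krzanowski_compare(a, b, q)
        assert out.r == pytest.approx(1.0, abs=1e-10)
        assert out.b == pytest.approx(2.0, abs=1e-10)

    def test_degenerate_constant_log_variance_flagged(self):
        out = krzanowski_compare(np.diag([4.0, 2.0, 1.0]), 2 * np.eye(3), np.eye(3))
        assert out.degenerate
        assert out.r == 0.0

    def test_non_orthonormal_basis_rejected(self, rng):
        a = _psd(rng, 4)
        with pytest.raises(ValueError, match="orthonormal"):
            krzanowski_compare(a, a, rng.standard_normal((4, 2)))

    def test_few_axes_warns(self, rng):
        a = _psd(rng, 5)
        with pytest.warns(UserWarning, match="unstable"):
            krzanowski_compare(a, a, reference_basis(a, 2))


class TestBca:
    def test_symmetric_samples_reduce_to_percentile(self, rng):
        samples = np.concatenate([rng.normal(0, 1, 5000), -rng.normal(0, 1, 5000)])
        lo, hi = bca_interval(samples, observed=np.median(samples), level=0.9)
        assert lo == pytest.approx(np.quantile(samples, 0.05), abs=0.03)
        assert hi == pytest.approx(np.quantile(samples, 0.95), abs=0.03)

    def test_identical_samples_degenerate(self):
        lo, hi = bca_interval(np.full(200, 0.7), observed=0.7)
        assert lo == hi == 0.7

    def test_matches_independent_textbook_formula_on_skewed_samples(self, rng):
        samples = rng.exponential(1.0, 4000)
        observed = 0.9
        jack = rng.exponential(1.0, 50)
        lo, hi = bca_interval(samples, observed, jackknife_values=jack, level=0.95)

        # independent reference implementation, written from the standard formula
        z0 = stats.norm.ppf((samples < observed).mean())
        d = jack.mean() - jack
        a = (d**3).sum() / (6.0 * ((d**2).sum()) ** 1.5)
        ref = []
        for z in (stats.norm.ppf(0.025), stats.norm.ppf(0.975)):
            adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
            ref.append(np.quantile(samples, adj))
        assert lo == pytest.approx(ref[0], rel=1e-9)
        assert hi == pytest.approx(ref[1], rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            bca_interval(np.arange(10.0), 5.0)


class TestVectorCorrelation:
    def test_identities(self):
        v = np.array([1.0, 2.0, -3.0])
        assert vector_correlation(v, v) == pytest.approx(1.0)
        assert vector_angle(v, v) == pytest.approx(0.0)
        assert vector_correlation(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert vector_correlation(
            np.array([1.0, 0.0]), np.array([1.0, 1.0])
        ) == pytest.approx(0.70711, abs=1e-5)
        assert vector_angle(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(
            45.0, abs=1e-3
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            vector_correlation(np.zeros(3), np.ones(3))

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=0.01, max_value=100.0),
        st.booleans(),
    )
    def test_scaling_invariance(self, seed, c1, c2, flip):
        r = np.random.default_rng(seed)
        v1, v2 = r.standard_normal(8), r.standard_normal(8)
        sign = -1.0 if flip else 1.0
        assert vector_correlation(c1 * v1, sign * c2 * v2) == pytest.approx(
            vector_correlation(v1, v2), abs=1e-12
        )


class TestRandomSkewers:
    def test_self_comparison_is_one(self, rng):
        a = _psd(rng, 10)
        out = random_skewers(a, a, n_vectors=500, seed=1)
        assert out.mean_response_correlation == pytest.approx(1.0, abs=1e-12)
        out_i = random_skewers(np.eye(7), np.eye(7), n_vectors=200, seed=1)
        assert out_i.mean_response_correlation == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a, b = _psd(rng, 8), _psd(rng, 8)
        r1 = random_skewers(a, b, n_vectors=2000, seed=9)
        r2 = random_skewers(b, a, n_vectors=2000, seed=9)
        assert r1.mean_response_correlation == pytest.approx(
            r2.mean_response_correlation, abs=1e-12
        )

    def test_matches_independent_monte_carlo_oracle(self):
        a = np.eye(16)
        b = np.diag(np.r_[10.0, np.ones(15)])
        out = random_skewers(a, b, n_vectors=10_000, seed=3)

        # brute-force oracle with a different generator stream
        oracle_rng = np.random.RandomState(12345)
        tot = 0.0
        n = 10_000
        for _ in range(n):
            v = oracle_rng.uniform(-1, 1, 16)
            v /= np.linalg.norm(v)
            ra, rb = a @ v, b @ v
            tot += abs(ra @ rb) / (np.linalg.norm(ra) * np.linalg.norm(rb))
        assert out.mean_response_correlation == pytest.approx(tot / n, abs=0.01)

    def test_interpolation_toward_target_is_monotone(self, rng):
        a = _psd(rng, 10)
        b = _psd(rng, 10)
        b *= np.trace(a) / np.trace(b)
        values = [
            random_skewers((1 - t) * b + t * a, a, n_vectors=4000, seed=5)
            .mean_response_correlation
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(x < y + 1e-9 for x, y in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0, abs=1e-12)

    def test_analytic_and_montecarlo_null_agree(self, rng):
        a, b = _psd(rng, 12), _psd(rng, 12)
        pa = random_skewers(a, b, n_vectors=4000, seed=2, null="analytic").p_value
        pm = random_skewers(a, b, n_vectors=4000, seed=2, null="montecarlo").p_value
        assert pm == pytest.approx(pa, abs=0.02)

    def test_gaussian_sampling_close_to_uniform(self, rng):
        a, b = _psd(rng, 8), _psd(rng, 8)
        ru = random_skewers(a, b, n_vectors=8000, seed=4, method="uniform")
        rg = random_skewers(a, b, n_vectors=8000, seed=4, method="gaussian")
        assert rg.mean_response_correlation == pytest.approx(
            ru.mean_response_correlation, abs=0.03
        )


class TestEndToEndSlopeRecovery:
    def test_slope_two_recovered_with_shared_eigenvectors(self):
        """When G is built on D's exact eigenvectors with log-variances of
        slope 2, the estimated subspace slope is unbiased for 2 and its CI
        covers 2 in most replicates (the CI itself is ~95% nominal, so a
        single replicate would be an unreliable check)."""
        import dataclasses
        import warnings

        import shapevar as sv
        from shapevar._geometry import normalize, tangent_basis
        from shapevar.procrustes import align_to_reference
        from shapevar.compare import subspace_comparison_with_ci
        from shapevar.simulate import default_paper_design

        covered = 0
        b_hats = []
        for seed in (61, 62, 63, 64, 65):
            params = default_paper_design(seed=seed)
            basis = tangent_basis(normalize(params.mean_shape))
            d_red = basis.T @ params.D_true @ basis
            vals, vecs = np.linalg.eigh(d_red)
            order = np.argsort(vals)[::-1][:6]
            lam_d = vals[order]
            g_eigs = lam_d**2 / (lam_d**2).sum() * 3.1e-4  # log-slope 2 exactly
            q6 = vecs[:, order]
            g_shared = basis @ (q6 * g_eigs) @ q6.T @ basis.T
            # E aligned with D keeps P's leading eigenvectors on shared axes
            e_aligned = 0.6 * params.D_true
            params = dataclasses.replace(params, G_true=g_shared, E_true=e_aligned)
            configs, design, truth = sv.simulate_dataset(params)
            aligned = align_to_reference(sv.gpa(configs), params.mean_shape)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mats = sv.estimate_dgp(aligned, design)
                sub = subspace_comparison_with_ci(
                    mats["D"], mats["G"], mats["P"], q=6, n_samples=1000, seed=0
                )
            b_hats.append(sub.b)
            covered += sub.ci_b[0] <= 2.0 <= sub.ci_b[1]
        assert covered >= 3
        assert 1.7 <= np.median(b_hats) <= 2.3


def _cov_with_sampling(rng, p=6, scale=1.0):
    mat = _psd(rng, p) * scale
    from shapevar._geometry import wishart_vech_cov

    return CovarianceMatrix(
        label="other",
        values=mat,
        selected_rank=p,
        fixed_effects_adjusted_for=[],
        n_units=50,
        basis=np.eye(p),
        reduced=mat,
        sampling_cov=wishart_vech_cov(mat, 200),
    )


class TestRemlMvnResample:
    def test_zero_sampling_cov_reproduces_estimate(self, rng):
        cm = _cov_with_sampling(rng)
        cm.sampling_cov = np.zeros_like(cm.sampling_cov)
        out = reml_mvn_resample(cm, 50, seed=0)
        for draw in out.draws:
            np.testing.assert_allclose(draw, cm.values, atol=1e-12)

    def test_mean_of_draws_near_estimate(self, rng):
        cm = _cov_with_sampling(rng)
        out = reml_mvn_resample(cm, 10_000, seed=1)
        mean = out.draws.mean(axis=0)
        # unbiased up to PSD clipping; interior estimate so clipping is rare
        rel = np.linalg.norm(mean - cm.values) / np.linalg.norm(cm.values)
        assert rel < 0.05

    def test_missing_sampling_cov_rejected(self, rng):
        cm = _cov_with_sampling(rng)
        cm.sampling_cov = None
        with pytest.raises(ValueError, match="sampling covariance"):
            reml_mvn_resample(cm, 10)

    def test_heavy_clipping_warns(self, rng):
        # rank-deficient center: every perturbed draw needs clipping
        mat = _psd(rng, 6, rank=2)
        from shapevar._geometry import wishart_vech_cov

        cm = CovarianceMatrix(
            label="other",
            values=mat,
            selected_rank=2,
            fixed_effects_adjusted_for=[],
            n_units=20,
            basis=np.eye(6),
            reduced=mat,
            sampling_cov=wishart_vech_cov(mat + 0.1 * np.trace(mat) * np.eye(6), 30),
        )
        with pytest.warns(UserWarning, match="clipping"):
            out = reml_mvn_resample(cm, 200, seed=2)
        assert out.n_clipped > 100
        for draw in out.draws[:10]:
            assert np.linalg.eigvalsh(draw).min() >= -1e-10 * np.trace(mat)
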