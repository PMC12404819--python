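"""Variance-component estimators: moment/REML agreement, truth recovery,
fixed-effect adjustment, and factor-analytic rank machinery."""

import dataclasses
import warnings

import numpy as np
import pytest

import shapevar as sv
from shapevar._geometry import effective_rank
from shapevar.compare import reference_basis, krzanowski_compare, vector_correlation
from shapevar.procrustes import align_to_reference
from shapevar.simulate import calibration_design, default_paper_design
from shapevar.varcomp import (
    EstimationError,
    estimate_D,
    estimate_G,
    estimate_P,
    fit_factor_model,
    reconstruct_cov,
    select_rank,
)


def _quiet(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


class TestMomentRemlAgreement:
    """On balanced designs the REML optimum coincides with the ANOVA estimator."""

    @pytest.mark.parametrize("which", ["D", "P", "G"])
    def test_agreement_within_tolerance(self, which, calib_aligned, calib_sim):
        _, design, _ = calib_sim
        fn = {"D": estimate_D, "P": estimate_P, "G": estimate_G}[which]
        m = _quiet(fn, calib_aligned, design, method="moment", clip=False,
                   compute_sampling_cov=False)
        r = _quiet(fn, calib_aligned, design, method="reml", clip=False,
                   compute_sampling_cov=False)
        rel = np.linalg.norm(m.values - r.values) / np.linalg.norm(m.values)
        assert rel < 1e-6


class TestNullRecovery:
    def test_zero_developmental_variance(self):
        params = calibration_design(n_families=250, offspring_per_family=4, seed=13)
        params = dataclasses.replace(params, D_true=np.zeros((16, 16)))
        configs, design, truth = sv.simulate_dataset(params)
        aligned = sv.gpa(configs)
        d = _quiet(estimate_D, aligned, design)
        # residual noise scale: measurement variance in the shape space
        noise_scale = float(np.sum(d.meas_variances))
        assert d.trace < 0.2 * noise_scale

    def test_zero_genetic_and_environment_variance(self):
        params = calibration_design(n_families=60, offspring_per_family=4, seed=14)
        zero = np.zeros((16, 16))
        params = dataclasses.replace(params, G_true=zero, E_true=zero)
        configs, design, truth = sv.simulate_dataset(params)
        aligned = sv.gpa(configs)
        p = _quiet(estimate_P, aligned, design)
        g = _quiet(estimate_G, aligned, design)
        ref = np.trace(params.D_true)
        assert p.trace < 0.25 * ref
        assert g.trace < 0.25 * ref


class TestTruthRecovery:
    def test_D_recovery_along_reference_axes(self, paper_aligned, paper_sim):
        _, design, truth = paper_sim
        d = _quiet(estimate_D, paper_aligned, design)
        k = reference_basis(truth.P_true, 6)
        assert krzanowski_compare(d, truth.D_true, k).r >= 0.9

    def test_P_estimates_genetic_plus_environment(self, paper_mats, paper_sim):
        _, _, truth = paper_sim
        p = paper_mats["P"]
        rel = np.linalg.norm(p.values - truth.P_true) / np.linalg.norm(truth.P_true)
        assert rel < 0.35

    def test_gmax_recovered_with_100_families(self):
        params = default_paper_design(seed=17)
        params = dataclasses.replace(
            params, n_families=100, offspring_per_family=6, n_extra_individuals=0
        )
        configs, design, truth = sv.simulate_dataset(params)
        aligned = align_to_reference(sv.gpa(configs), params.mean_shape)
        g = _quiet(estimate_G, aligned, design)
        assert vector_correlation(g.leading_eigenvector, truth.gmax) >= 0.9

    def test_sampling_cov_diagonal_within_factor_two(self):
        # empirical variance of the estimator across replicates should match
        # the reported Wishart sampling covariance on the diagonal
        params = calibration_design(n_families=25, offspring_per_family=4, seed=0)
        from shapevar._geometry import vech

        draws, reported = [], []
        for rep in range(60):
            configs, design, _ = sv.simulate_dataset(params.with_seed(3000 + rep))
            aligned = align_to_reference(sv.gpa(configs), params.mean_shape)
            d = _quiet(estimate_D, aligned, design, clip=False)
            draws.append(vech(d.reduced))
            reported.append(np.diag(d.sampling_cov))
        emp = np.asarray(draws).var(axis=0, ddof=1)
        rep_mean = np.mean(reported, axis=0)
        ratio = np.median(emp / rep_mean)
        assert 0.5 < ratio < 2.0


class TestFixedEffectAdjustment:
    def test_doubling_temperature_effect_leaves_P_unchanged(self):
        base = default_paper_design(seed=23)
        doubled = dataclasses.replace(base, beta_temperature=2 * base.beta_temperature)
        p_hats = []
        for params in (base, doubled):
            configs, design, _ = sv.simulate_dataset(params)
            aligned = align_to_reference(sv.gpa(configs), params.mean_shape)
            p_hats.append(_quiet(estimate_P, aligned, design).values)
        rel = np.linalg.norm(p_hats[0] - p_hats[1]) / np.linalg.norm(p_hats[0])
        assert rel < 0.02

    def test_affine_temperature_recoding_invariance(self, paper_aligned, paper_sim):
        _, design, _ = paper_sim
        recoded = sv.DesignTable(
            design.table.assign(temperature=(design.table["temperature"] == 27.0) * 1.0)
        )
        p1 = _quiet(estimate_P, paper_aligned, design).values
        p2 = _quiet(estimate_P, paper_aligned, recoded).values
        np.testing.assert_allclose(p1, p2, rtol=1e-8, atol=1e-18)

    def test_population_relabeling_invariance(self, paper_aligned, paper_sim):
        _, design, _ = paper_sim
        mapping = {"IT": "pop5", "FL": "pop4", "SC": "pop3", "NC": "pop2", "MI": "pop1"}
        relabeled = sv.DesignTable(
            design.table.assign(
                population_id=design.table["population_id"].map(mapping)
            )
        )
        g1 = _quiet(estimate_G, paper_aligned, design).values
        g2 = _quiet(estimate_G, paper_aligned, relabeled).values
        np.testing.assert_allclose(g1, g2, rtol=1e-8, atol=1e-18)


class TestErrors:
    def test_single_replicate_cannot_separate_error(self, paper_aligned, paper_sim):
        _, design, _ = paper_sim
        mask = (paper_aligned.keys["replicate"] == 1).to_numpy()
        from shapevar.procrustes import AlignedDataset

        sub = AlignedDataset(
            shape_coords=paper_aligned.shape_coords[mask],
            centroid_sizes=paper_aligned.centroid_sizes[mask],
            consensus=paper_aligned.consensus,
            keys=paper_aligned.keys.loc[mask].reset_index(drop=True),
            n_iterations=1,
            final_change=0.0,
            reflect_side="left",
        )
        with pytest.raises(EstimationError, match="single replicate"):
            estimate_D(sub, design)

    def test_all_singleton_families_inestimable(self, calib_aligned, calib_sim):
        _, design, _ = calib_sim
        singleton = sv.DesignTable(
            design.table.assign(family_id=design.table["specimen_id"])
        )
        with pytest.raises(EstimationError, match="singleton"):
            estimate_G(calib_aligned, singleton)


class TestFactorModels:
    def test_loglik_monotone_in_rank_and_aic_identity(self, calib_aligned, calib_sim):
        _, design, _ = calib_sim
        lls = []
        for m in (1, 2, 3):
            fit = fit_factor_model(
                calib_aligned, design, m, random_structure="individual_by_side",
                n_starts=1, seed=0,
            )
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
            lls.append(fit.loglik)
        assert lls[0] <= lls[1] <= lls[2]

    def test_full_rank_fit_reproduces_moment_estimate(self, calib_aligned, calib_sim):
        _, design, _ = calib_sim
        d_mom = _quiet(estimate_D, calib_aligned, design, clip=False,
                       compute_sampling_cov=False)
        pt = d_mom.reduced.shape[0]
        fit = fit_factor_model(
            calib_aligned, design, pt, random_structure="individual_by_side",
            include_specific=False, n_starts=1, seed=0,
        )
        rel = np.linalg.norm(fit.implied_reduced(False) - d_mom.reduced) / np.linalg.norm(
            d_mom.reduced
        )
        assert rel < 1e-5

    def test_reconstruct_cov_consistency(self, calib_aligned, calib_sim):
        _, design, _ = calib_sim
        fit = fit_factor_model(
            calib_aligned, design, 3, random_structure="individual_by_side",
            n_starts=1, seed=0,
        )
        cm = reconstruct_cov(fit)
        assert cm.selected_rank == 3
        vals = np.linalg.eigvalsh(cm.values)
        assert vals.min() >= -1e-12 * max(cm.trace, 1e-300)
        common = reconstruct_cov(fit, include_specific=False)
        assert common.trace <= cm.trace
        assert effective_rank(common.reduced) <= 3

    def test_rank_two_truth_selected(self):
        params = calibration_design(n_families=40, offspring_per_family=5, seed=31)
        basis_params = default_paper_design()
        from shapevar._geometry import tangent_basis, normalize

        basis = tangent_basis(normalize(params.mean_shape))
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.standard_normal((12, 2)))
        d2 = basis @ (q * np.array([3e-4, 1.5e-4])) @ q.T @ basis.T
        params = dataclasses.replace(params, D_true=d2)
        configs, design, _ = sv.simulate_dataset(params)
        aligned = sv.gpa(configs)
        m_star, table, _ = select_rank(
            aligned, design, m_max=5, random_structure="individual_by_side",
            n_starts=2, seed=0,
        )
        assert m_star == 2

    def test_m_max_one_returns_one(self, calib_aligned, calib_sim):
        _, design, _ = calib_sim
        m_star, table, _ = select_rank(
            calib_aligned, design, m_max=1, random_structure="individual_by_side",
            n_starts=1, seed=0,
        )
        assert m_star == 1
        assert len(table) == 1
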