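"""GPA correctness (invariance, idempotence, oracle distance) and symmetry ANOVA."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import shapevar as sv
from shapevar._geometry import centroid_size, normalize, signed_polygon_area
from shapevar.io import LandmarkConfiguration
from shapevar.procrustes import (
    AlignmentError,
    ProcrustesAligner,
    align_to_reference,
    gpa,
    reflect,
    symmetry_anova,
)
from shapevar.simulate import calibration_design


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _cfg(coords, spec="A", side="right", rep=1):
    return LandmarkConfiguration(spec, side, rep, coords)


BASE = np.array(
    [[1.0, 0.2], [0.3, 0.9], [-0.6, 0.7], [-1.0, -0.1], [-0.2, -0.8], [0.8, -0.6]]
)


class TestReflect:
    def test_involution(self):
        c = _cfg(BASE)
        back = reflect(reflect(c))
        np.testing.assert_array_equal(back.coords, c.coords)

    def test_flips_signed_area(self):
        c = _cfg(BASE)
        assert signed_polygon_area(reflect(c).coords) == pytest.approx(
            -signed_polygon_area(c.coords)
        )

    def test_centroid_size_unchanged(self):
        c = _cfg(BASE)
        assert centroid_size(reflect(c).coords) == pytest.approx(
            centroid_size(c.coords)
        )


class TestGpa:
    def test_copies_under_similarity_transforms_align_exactly(self, rng):
        configs = []
        for i in range(30):
            coords = BASE * rng.uniform(0.5, 3.0) @ _rot(rng.uniform(0, 2 * np.pi)).T
            coords = coords + rng.uniform(-50, 50, 2)
            configs.append(_cfg(coords, spec=f"S{i}"))
        aligned = gpa(configs, reflect_side=None)
        spread = aligned.shape_coords.std(axis=0).max()
        assert spread < 1e-8
        total_var = ((aligned.shape_coords - aligned.shape_coords.mean(0)) ** 2).sum()
        assert total_var < 1e-14

    def test_aligned_records_centered_unit_size(self, paper_aligned):
        coords = paper_aligned.shape_coords.reshape(paper_aligned.n_records, -1, 2)
        np.testing.assert_allclose(coords.mean(axis=1), 0.0, atol=1e-9)
        sizes = np.sqrt((coords**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-9)

    def test_consensus_is_mean_of_aligned(self, paper_aligned):
        mean = paper_aligned.shape_coords.mean(axis=0).reshape(-1, 2)
        np.testing.assert_allclose(mean, paper_aligned.consensus, atol=1e-12)

    def test_idempotence(self, rng):
        configs = [
            _cfg(BASE + rng.normal(0, 0.05, BASE.shape), spec=f"S{i}") for i in range(15)
        ]
        first = gpa(configs, reflect_side=None)
        again = gpa(
            [
                _cfg(row.reshape(-1, 2), spec=f"S{i}")
                for i, row in enumerate(first.shape_coords)
            ],
            reflect_side=None,
        )
        assert np.abs(again.shape_coords - first.shape_coords).max() < 1e-6

    def test_alignment_invariant_to_input_similarity_transform(self, rng):
        configs = [
            _cfg(BASE + rng.normal(0, 0.05, BASE.shape), spec=f"S{i}") for i in range(10)
        ]
        ref = gpa(configs, reflect_side=None)
        moved = list(configs)
        moved[3] = _cfg(
            configs[3].coords * 2.7 @ _rot(1.1).T + np.array([5.0, -3.0]), spec="S3"
        )
        out = gpa(moved, reflect_side=None)
        assert np.abs(out.shape_coords - ref.shape_coords).max() < 1e-8

    def test_procrustes_distance_matches_rotation_grid_oracle(self):
        tri1 = np.array([[0.0, 0.0], [1.0, 0.0], [0.4, 0.9]])
        tri2 = np.array([[0.0, 0.1], [1.1, 0.0], [0.3, 1.1]])
        aligned = gpa([_cfg(tri1, "a"), _cfg(tri2, "b")], reflect_side=None)
        dist = np.linalg.norm(aligned.shape_coords[0] - aligned.shape_coords[1])

        z1, z2 = normalize(tri1), normalize(tri2)

        def objective(theta):
            return np.linalg.norm(z1 - z2 @ _rot(theta).T)

        grid = np.linspace(-np.pi, np.pi, 3601)
        best = grid[np.argmin([objective(t) for t in grid])]
        refined = minimize_scalar(
            objective, bounds=(best - 0.01, best + 0.01), method="bounded",
            options={"xatol": 1e-12},
        )
        assert dist == pytest.approx(refined.fun, abs=1e-6)

    def test_rank_of_aligned_covariance_bounded(self, paper_aligned):
        # alignment removes 2 translation, 1 rotation and 1 scale dof; the
        # 4 trailing eigenvalues are only second-order (sphere curvature)
        cov = np.cov(paper_aligned.shape_coords, rowvar=False)
        vals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = paper_aligned.k
        assert (vals[2 * k - 4 :] < 1e-3 * vals[0]).all()

    def test_degenerate_configuration_raises(self):
        configs = [_cfg(BASE, "a"), _cfg(np.ones((6, 2)), "b")]
        with pytest.raises(AlignmentError, match="zero centroid size"):
            gpa(configs, reflect_side=None)

    def test_transform_matches_fit_alignment(self, tiny_sim):
        configs, _, _ = tiny_sim
        aligner = ProcrustesAligner().fit(configs)
        out = aligner.transform(configs[:5])
        np.testing.assert_allclose(out, aligner.shape_coords_[:5], atol=1e-8)

    def test_get_set_params(self):
        aligner = ProcrustesAligner().set_params(tol=1e-8)
        assert aligner.get_params()["tol"] == 1e-8
        with pytest.raises(ValueError):
            aligner.set_params(bogus=1)

    def test_align_to_reference_preserves_internal_geometry(self, paper_aligned, paper_params):
        rotated = align_to_reference(paper_aligned, paper_params.mean_shape)
        d_before = np.linalg.norm(
            paper_aligned.shape_coords[0] - paper_aligned.shape_coords[1]
        )
        d_after = np.linalg.norm(rotated.shape_coords[0] - rotated.shape_coords[1])
        assert d_after == pytest.approx(d_before, rel=1e-10)


class TestSymmetryAnova:
    def test_degrees_of_freedom_for_full_design(self, paper_aligned):
        table = symmetry_anova(paper_aligned, n_permutations=0)
        assert table["individual_x_side"]["df"] == 433
        assert table["error"]["df"] == 868
        assert table["individual"]["df"] == 433
        assert table["side"]["df"] == 1
        assert table.table.loc["total", "df"] == 1735

    def test_sums_of_squares_additive(self, paper_aligned):
        table = symmetry_anova(paper_aligned, n_permutations=0).table
        parts = table.loc[["individual", "side", "individual_x_side", "error"], "SS"].sum()
        assert parts == pytest.approx(table.loc["total", "SS"], rel=1e-10)

    def test_fa_proportion_near_generator_target(self, paper_aligned):
        # generator calibrated so FA contributes ~11% of total shape variance
        table = symmetry_anova(paper_aligned, n_permutations=0)
        assert 0.09 < table.fa_proportion < 0.13
        assert 3.5 < table["individual_x_side"]["F"] < 6.0

    def test_fa_significant_on_default_design(self, paper_aligned):
        table = symmetry_anova(paper_aligned, n_permutations=199, seed=0)
        row = table["individual_x_side"]
        assert row["p"] == pytest.approx(1 / 200, abs=1e-9)
        assert row["Z"] > 3

    def test_null_developmental_variance_gives_f_near_one(self):
        params = calibration_design(n_families=50, offspring_per_family=4, seed=21)
        params = dataclasses.replace(params, D_true=np.zeros((16, 16)))
        configs, _, _ = sv.simulate_dataset(params)
        table = symmetry_anova(sv.gpa(configs), n_permutations=0)
        assert 0.75 < table["individual_x_side"]["F"] < 1.35

    def test_single_replicate_raises(self, paper_aligned):
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
        with pytest.raises(ValueError, match="single replicate"):
            symmetry_anova(sub)
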