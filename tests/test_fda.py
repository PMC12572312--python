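import itertools

import numpy as np
import pandas as pd
import pytest

from growthchart import fda
from growthchart.atlas import LabelVolume


# ---------------------------------------------------------------------------
# independent oracles


def cox_de_boor(x, knots, i, d):
    """Naive B-spline recursion, independent of scipy."""
    if d == 0:
        # half-open spans; make the last span closed at the right edge
        if knots[i] <= x < knots[i + 1]:
            return 1.0
        if x == knots[-1] and knots[i] < knots[i + 1] == knots[-1]:
            return 1.0
        return 0.0
    out = 0.0
    if knots[i + d] > knots[i]:
        out += (x - knots[i]) / (knots[i + d] - knots[i]) * cox_de_boor(x, knots, i, d - 1)
    if knots[i + d + 1] > knots[i + 1]:
        out += (knots[i + d + 1] - x) / (knots[i + d + 1] - knots[i + 1]) * cox_de_boor(
            x, knots, i + 1, d - 1
        )
    return out


def _random_instance(rng, n_pts=40, n_basis=(3, 3, 3), degree=2):
    pts = rng.random((n_pts, 3)) * 1000.0
    basis = fda.make_tensor_basis(pts, n_basis, degree)
    design = fda.build_design_matrix(pts, basis)
    return pts, basis, design


class TestCentroids:
    def test_single_voxel_region_center(self):
        grid = np.zeros((2, 2, 2), dtype=np.int32)
        grid[0, 0, 0] = 1
        vol = LabelVolume(grid, (20.0, 20.0, 20.0))
        c = fda.compute_region_centroids(vol, [1]).iloc[0]
        assert (c["x_um"], c["y_um"], c["z_um"]) == (10.0, 10.0, 10.0)

    def test_symmetric_region_midpoint(self):
        grid = np.zeros((4, 2, 2), dtype=np.int32)
        grid[0, 0, 0] = grid[3, 0, 0] = 1
        vol = LabelVolume(grid, (20.0, 20.0, 20.0))
        c = fda.compute_region_centroids(vol, [1]).iloc[0]
        assert c["x_um"] == pytest.approx(40.0)  # midpoint of voxel centers 10, 70

    def test_origin_translation_equivariance(self):
        grid = np.zeros((3, 3, 3), dtype=np.int32)
        grid[1, 1, 1] = 5
        a = fda.compute_region_centroids(LabelVolume(grid, (20.0,) * 3), [5])
        b = fda.compute_region_centroids(
            LabelVolume(grid, (20.0,) * 3, origin_um=(100.0, -50.0, 7.0)), [5]
        )
        np.testing.assert_allclose(
            b[["x_um", "y_um", "z_um"]].to_numpy() - a[["x_um", "y_um", "z_um"]].to_numpy(),
            [[100.0, -50.0, 7.0]],
        )

    def test_empty_region_rejected(self, volume):
        with pytest.raises(ValueError, match="999"):
            fda.compute_region_centroids(volume, [999])


class TestDesignMatrix:
    def test_rows_sum_to_one(self, cortical_centroids):
        basis = fda.make_tensor_basis(cortical_centroids)
        D = fda.build_design_matrix(cortical_centroids, basis)
        np.testing.assert_allclose(D.sum(axis=1), 1.0, atol=1e-10)

    def test_single_degree_zero_basis_is_all_ones(self, rng):
        pts = rng.random((10, 3)) * 100
        basis = fda.make_tensor_basis(pts, n_basis=(1, 1, 1), degree=0)
        D = fda.build_design_matrix(pts, basis)
        np.testing.assert_allclose(D, 1.0)

    def test_matches_cox_de_boor_tensor_oracle(self, rng):
        pts, basis, D = _random_instance(rng, n_pts=6)
        for p_i, point in enumerate(pts):
            col = 0
            for ix, iy, iz in itertools.product(*(range(n) for n in basis.n_basis)):
                expected = (
                    cox_de_boor(point[0], basis.knots[0], ix, basis.degree)
                    * cox_de_boor(point[1], basis.knots[1], iy, basis.degree)
                    * cox_de_boor(point[2], basis.knots[2], iz, basis.degree)
                )
                assert D[p_i, col] == pytest.approx(expected, abs=1e-12)
                col += 1

    def test_point_outside_domain_rejected(self, rng):
        pts, basis, _ = _random_instance(rng, n_pts=5)
        far = pts.copy()
        far[0, 0] = 1e6
        with pytest.raises(ValueError, match="outside"):
            fda.build_design_matrix(far, basis)


class TestLeastSquaresFit:
    def test_constant_density_reproduced_exactly(self, cortical_centroids):
        basis = fda.make_tensor_basis(cortical_centroids)
        D = fda.build_design_matrix(cortical_centroids, basis)
        y = np.full((1, len(cortical_centroids)), 7000.0)
        coef = fda.fit_function_samples(D, y)
        np.testing.assert_allclose(coef @ D.T, y, rtol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            pts, basis, D = _random_instance(rng)
            y = rng.random((3, len(pts))) * 1e4
            coef = fda.fit_function_samples(D, y)
            oracle = np.linalg.solve(D.T @ D, D.T @ y.T).T
            np.testing.assert_allclose(coef, oracle, rtol=1e-8)

    def test_large_ridge_shrinks_coefficients(self, rng):
        pts, basis, D = _random_instance(rng)
        y = rng.random((1, len(pts))) * 1e4
        small = fda.fit_function_samples(D, y, ridge=1e-6)
        big = fda.fit_function_samples(D, y, ridge=1e12)
        assert np.linalg.norm(big) < 1e-3 * np.linalg.norm(small)

    def test_rank_deficient_without_ridge_rejected(self, rng):
        pts = rng.random((10, 3)) * 100  # 10 points < 27 basis functions
        basis = fda.make_tensor_basis(pts)
        D = fda.build_design_matrix(pts, basis)
        with pytest.raises(ValueError, match="ridge"):
            fda.fit_function_samples(D, np.zeros((1, 10)))


class TestFPCA:
    def test_rank_one_variation_gives_single_component(self, rng):
        pts, basis, D = _random_instance(rng)
        G = fda.basis_gram(basis)
        direction = rng.random(D.shape[1])
        coefs = np.outer(rng.normal(size=12), direction) + 5.0
        model = fda.fit_fpca(coefs, G)
        assert model.n_components == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_identical_samples_give_zero_components(self, rng):
        pts, basis, D = _random_instance(rng)
        G = fda.basis_gram(basis)
        coefs = np.tile(rng.random(D.shape[1]), (6, 1))
        model = fda.fit_fpca(coefs, G)
        assert model.n_components == 0

    def test_ratios_nonincreasing_and_sum_to_one(self, rng):
        pts, basis, D = _random_instance(rng)
        G = fda.basis_gram(basis)
        coefs = rng.normal(size=(15, D.shape[1]))
        model = fda.fit_fpca(coefs, G)
        r = model.explained_variance_ratio
        assert (np.diff(r) <= 1e-12).all()
        assert r.sum() == pytest.approx(1.0)

    def test_components_match_dense_grid_pca_oracle(self, rng):
        """Gram-weighted FPCA equals plain PCA of the functions sampled on a
        dense 20^3 grid (volume-weighted inner product)."""
        pts, basis, D = _random_instance(rng, n_pts=45)
        G = fda.basis_gram(basis)
        # well-separated geometric spectrum along random directions so both
        # discretizations order the components identically
        k = D.shape[1]
        W, _ = np.linalg.qr(rng.normal(size=(k, 6)))
        scales = 100.0 * 0.4 ** np.arange(6)
        coefs = rng.normal(size=(20, 6)) @ (W * scales).T + 50.0
        model = fda.fit_fpca(coefs, G)

        # midpoint rule: 20 cell centers per axis, uniform weights
        axes = [lo + (np.arange(20) + 0.5) * (hi - lo) / 20 for lo, hi in basis.domain]
        grid = np.array(list(itertools.product(*axes)))
        Dg = fda.build_design_matrix(grid, basis)
        F = coefs @ Dg.T  # functions evaluated on the dense grid
        Fc = F - F.mean(axis=0)
        _, _, Vt = np.linalg.svd(Fc, full_matrices=False)
        for j in range(min(3, model.n_components)):
            ours_on_grid = Dg @ model.components[:, j]
            cos = abs(ours_on_grid @ Vt[j]) / (
                np.linalg.norm(ours_on_grid) * np.linalg.norm(Vt[j])
            )
            assert cos >= 0.999

    def test_fewer_than_two_samples_rejected(self, rng):
        pts, basis, D = _random_instance(rng)
        with pytest.raises(ValueError, match="2 samples"):
            fda.fit_fpca(np.zeros((1, D.shape[1])), fda.basis_gram(basis))


class TestReconstructionErrors:
    def test_sample_in_retained_span_has_zero_error(self, rng):
        pts, basis, D = _random_instance(rng, n_pts=45)
        G = fda.basis_gram(basis)
        direction = rng.random(D.shape[1])
        coefs = np.outer(rng.normal(size=8), direction) + 3.0
        y = coefs @ D.T  # exact evaluations of in-span functions
        model = fda.fit_fpca(coefs, G)
        errors, _ = fda.reconstruction_errors(y, D, coefs, model)
        np.testing.assert_allclose(errors, 0.0, atol=1e-6)

    def test_full_component_errors_equal_least_squares_residuals(self, rng):
        pts, basis, D = _random_instance(rng, n_pts=45)
        G = fda.basis_gram(basis)
        y = rng.random((30, len(pts))) * 1e3
        coefs = fda.fit_function_samples(D, y)
        model = fda.fit_fpca(coefs, G, target=1.0)
        assert model.n_components == min(29, D.shape[1])
        errors, _ = fda.reconstruction_errors(y, D, coefs, model)
        residuals = np.linalg.norm(y - coefs @ D.T, axis=1)
        np.testing.assert_allclose(errors, residuals, rtol=1e-6)

    def test_outlier_count_bounded_by_percentile(self, rng):
        pts, basis, D = _random_instance(rng, n_pts=45)
        G = fda.basis_gram(basis)
        y = rng.random((50, len(pts))) * 1e3
        coefs = fda.fit_function_samples(D, y)
        model = fda.fit_fpca(coefs, G)
        _, flags = fda.reconstruction_errors(y, D, coefs, model)
        assert flags.sum() <= int(np.ceil(0.01 * 50)) + 1


class TestPermutationAnova:
    def test_identical_errors_degenerate(self):
        f, p = fda.permutation_anova(np.ones(8), ["a"] * 4 + ["b"] * 4)
        assert (f, p) == (0.0, 1.0)

    def test_exhaustive_worked_example(self):
        """Groups {1,2} vs {9,10}: only the observed split and its mirror
        reach the observed F among the C(4,2)=6 assignments."""
        cfg = fda.FdaConfig(permutation_mode="exhaustive")
        f, p = fda.permutation_anova(
            np.array([1.0, 2.0, 9.0, 10.0]), ["a", "a", "b", "b"], cfg
        )
        assert p == pytest.approx(2 / 6)

    def test_monotone_rescaling_invariance(self, rng):
        vals = rng.random(12)
        labels = ["a", "b", "c"] * 4
        cfg = fda.FdaConfig(n_perm=500, seed=9)
        _, p1 = fda.permutation_anova(vals, labels, cfg)
        _, p2 = fda.permutation_anova(vals * 3.7, labels, cfg)
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            fda.permutation_anova(np.ones(3), ["a", "a", "a"])


class TestPairwiseAndBH:
    def test_identical_groups_give_p_one(self):
        cfg = fda.FdaConfig(permutation_mode="exhaustive")
        table = fda.pairwise_permutation_tests(
            np.array([5.0, 5.0, 5.0, 5.0]), ["a", "a", "b", "b"], cfg
        )
        assert table["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_bh_step_up_worked_example(self):
        """Raw (0.01, 0.02, 0.03, 0.04) all adjust to 0.04."""
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)

    def test_adjusted_at_least_raw(self, rng):
        vals = rng.random(18) * 10
        labels = np.repeat(["a", "b", "c"], 6)
        cfg = fda.FdaConfig(n_perm=200, seed=4)
        table = fda.pairwise_permutation_tests(vals, labels, cfg)
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()
        assert (table["p_adj"] <= 1.0 + 1e-12).all()

    def test_singleton_group_warns(self):
        with pytest.warns(UserWarning, match="singleton"):
            fda.pairwise_permutation_tests(
                np.array([1.0, 2.0, 3.0]), ["a", "b", "b"],
                fda.FdaConfig(n_perm=50, seed=0),
            )


class TestFullProcedure:
    def test_runs_end_to_end_on_study_densities(self, cortical_centroids, rng):
        base = 8000 + 30 * (cortical_centroids[:, 0] - cortical_centroids[:, 0].mean())
        Y = base + rng.normal(0, 300, size=(24, len(base)))
        labels = np.repeat([f"P{4 + 2 * i}" for i in range(6)], 4)
        res = fda.topography_test(
            Y, labels, cortical_centroids, fda.FdaConfig(n_perm=300, seed=1)
        )
        assert res.f_statistic >= 0
        assert 0 < res.p_value <= 1
        assert len(res.pairwise) == 15
        assert res.fpca.n_components >= 1
        d = res.to_dict()
        assert set(d) >= {"F", "permuted_p", "errors", "pairwise"}
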