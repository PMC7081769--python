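"""Factorial ANCOVA core, smoothness estimation, and cluster-level inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from gfcdmap import synth
from gfcdmap.fcd import QualifiedMask
from gfcdmap.voxelstats import (
    EFFECTS,
    build_design,
    estimate_smoothness,
    extract_cluster_means,
    fit_voxelwise_ancova,
    form_clusters,
    monte_carlo_extent_threshold,
    ols_f_tests,
)


def random_table(n_per_cell, rng, outcome_sd=1.0):
    rows = []
    for dx in ("CN", "MCI"):
        for gt in ("e2+", "e3e3", "e4+"):
            rows.extend({"diagnosis": dx, "genotype": gt} for _ in range(n_per_cell))
    table = pd.DataFrame(rows)
    n = len(table)
    table["age"] = rng.normal(73, 6, n)
    table["sex"] = rng.integers(0, 2, n).astype(float)
    table["education"] = rng.normal(16, 2.5, n)
    table["mean_fd"] = np.abs(rng.normal(0.15, 0.05, n))
    return table


def brute_force_f(y, x_full, cols_drop, df_num):
    """Oracle: explicit full-vs-reduced residual sums of squares."""
    def rss(x):
        beta = np.linalg.pinv(x) @ y
        r = y - x @ beta
        return float(r @ r)

    keep = [j for j in range(x_full.shape[1]) if j not in cols_drop]
    rss_f = rss(x_full)
    rss_r = rss(x_full[:, keep])
    df_err = x_full.shape[0] - x_full.shape[1]
    return ((rss_r - rss_f) / df_num) / (rss_f / df_err)


class TestDesign:
    def test_factor_columns_sum_to_zero_when_balanced(self, rng):
        table = random_table(4, rng)
        design = build_design(table)
        for cols in design.effect_columns.values():
            for j in cols:
                assert abs(design.matrix[:, j].sum()) < 1e-12

    def test_empty_cell_errors_naming_cell(self, rng):
        table = random_table(3, rng)
        table = table[~((table.diagnosis == "MCI") & (table.genotype == "e4+"))]
        with pytest.raises(ValueError, match="MCI.*e4"):
            build_design(table)


class TestOlsFTests:
    def test_matches_brute_force_oracle(self, rng):
        table = random_table(5, rng)
        design = build_design(table)
        y = rng.normal(size=(design.n_subjects, 7))
        f_stats, _, dfs, _ = ols_f_tests(y, design)
        for effect, cols in design.effect_columns.items():
            for v in range(7):
                expected = brute_force_f(y[:, v], design.matrix, cols, len(cols))
                assert f_stats[effect][v] == pytest.approx(expected, rel=1e-8)

    def test_matches_statsmodels_type_iii(self, rng):
        """Independent cross-check against statsmodels' Type-III ANOVA."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        table = random_table(4, rng)
        # imbalance so Type I and Type III genuinely differ
        table = pd.concat([table, table.iloc[:5]], ignore_index=True)
        table["y"] = rng.normal(size=len(table))
        design = build_design(table, covariates=("age",))
        f_stats, p_vals, _, _ = ols_f_tests(table["y"].to_numpy()[:, None], design)
        model = ols(
            "y ~ C(diagnosis, Sum) * C(genotype, Sum) + age", data=table
        ).fit()
        aov = sm.stats.anova_lm(model, typ=3)
        assert f_stats["diagnosis"][0] == pytest.approx(
            aov.loc["C(diagnosis, Sum)", "F"], rel=1e-6
        )
        assert f_stats["genotype"][0] == pytest.approx(
            aov.loc["C(genotype, Sum)", "F"], rel=1e-6
        )
        assert f_stats["interaction"][0] == pytest.approx(
            aov.loc["C(diagnosis, Sum):C(genotype, Sum)", "F"], rel=1e-6
        )

    def test_degenerate_voxel_excluded_and_counted(self, rng):
        table = random_table(3, rng)
        design = build_design(table)
        mask = QualifiedMask(np.ones((2, 2, 2), bool))
        y = rng.normal(size=(design.n_subjects, 8))
        y[:, 3] = 0.0
        fm = fit_voxelwise_ancova(y, design, mask)
        assert fm.excluded_voxels == 1
        assert fm.analysis_mask.sum() == 7


class TestSmoothness:
    def _fit_null(self, maps, rng):
        n = maps.shape[0]
        table = random_table(n // 6, rng)
        design = build_design(table)
        mask = QualifiedMask(np.ones(maps.shape[1:], bool))
        return fit_voxelwise_ancova(maps.reshape(n, -1), design, mask)

    def test_unsmoothed_noise_below_1p2_voxels(self, rng):
        maps = rng.standard_normal((18, 12, 12, 12))
        fm = self._fit_null(maps, rng)
        fwhm = estimate_smoothness(fm, (1.0, 1.0, 1.0))
        assert np.all(fwhm <= 1.2)

    def test_recovers_6mm_within_15_percent(self, rng):
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        maps = np.stack([
            ndimage.gaussian_filter(rng.standard_normal((30, 30, 30)), sigma)
            for _ in range(18)
        ])
        fm = self._fit_null(maps, rng)
        fwhm = estimate_smoothness(fm, (3.0, 3.0, 3.0))
        np.testing.assert_allclose(fwhm, 6.0, rtol=0.15)

    def test_constant_residuals_error(self, rng):
        table = random_table(3, rng)
        design = build_design(table)
        mask = QualifiedMask(np.ones((3, 3, 3), bool))
        y = rng.normal(size=(design.n_subjects, 1)) * np.ones((1, 27))
        fm = fit_voxelwise_ancova(y, design, mask)
        fm.residuals = np.zeros_like(fm.residuals)
        with pytest.raises(ValueError):
            estimate_smoothness(fm, (3.0, 3.0, 3.0))


def reference_extent_threshold(shape, sigma_vox, voxel_p, alpha, n_iter, seed):
    """Second, independently coded Monte-Carlo null (plain loops, its own
    quantile bookkeeping) used to cross-check the production implementation."""
    rng = np.random.default_rng(seed)
    z = stats.norm.isf(voxel_p / 2)
    maxima = []
    structure = np.ones((3, 3, 3), dtype=bool)
    for _ in range(n_iter):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="reflect")
        f = (f - f.mean()) / f.std()
        lab, nl = ndimage.label(np.abs(f) > z, structure=structure)
        maxima.append(max((np.sum(lab == i) for i in range(1, nl + 1)), default=0))
    maxima = np.asarray(maxima)
    for k in range(1, int(maxima.max()) + 2):
        if (maxima >= k).mean() <= alpha:
            return k
    return int(maxima.max()) + 1


class TestMonteCarloThreshold:
    def test_unsmoothed_tiny_voxel_p_gives_kmin_one(self):
        mask = np.ones((12, 12, 12), bool)
        k = monte_carlo_extent_threshold(mask, (0.0,) * 3, 1e-6, 0.05, 200, seed=1)
        assert k == 1

    def test_kmin_nondecreasing_in_fwhm(self):
        mask = np.ones((16, 16, 16), bool)
        ks = [
            monte_carlo_extent_threshold(mask, (f,) * 3, 0.005, 0.05, 300, seed=2,
                                         voxel_mm=(3.0,) * 3)
            for f in (0.0, 6.0, 12.0)
        ]
        assert ks[0] <= ks[1] <= ks[2]

    def test_matches_independent_reference_simulation(self):
        mask = np.ones((20, 20, 20), bool)
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        k_ref = reference_extent_threshold((20, 20, 20), sigma, 0.005, 0.05, 1000, seed=5)
        k_impl = monte_carlo_extent_threshold(
            mask, (6.0,) * 3, 0.005, 0.05, 1000, seed=17, voxel_mm=(3.0,) * 3
        )
        assert abs(k_impl - k_ref) <= 2

    def test_unresolvable_alpha_errors(self):
        with pytest.raises(ValueError, match="unresolvable"):
            monte_carlo_extent_threshold(np.ones((8, 8, 8), bool), (0.0,) * 3,
                                         0.005, 0.001, 100, seed=0)


class TestFormClusters:
    def test_no_suprathreshold_voxels_empty_report(self):
        report = form_clusters(np.ones((5, 5, 5)), 0.005, 1)
        assert report.n_clusters == 0

    def test_isolated_voxel_single_cluster(self):
        p = np.ones((5, 5, 5))
        p[2, 2, 2] = 1e-5
        report = form_clusters(p, 0.005, 1)
        assert report.n_clusters == 1
        assert report.clusters[0]["size_voxels"] == 1

    def test_planted_block_exact_size(self):
        p = np.ones((9, 9, 9))
        p[3:6, 3:6, 3:6] = 1e-4
        report = form_clusters(p, 0.005, 27, connectivity=26)
        assert report.n_clusters == 1
        assert report.clusters[0]["size_voxels"] == 27

    def test_below_kmin_discarded(self):
        p = np.ones((9, 9, 9))
        p[3:6, 3:6, 3:6] = 1e-4
        assert form_clusters(p, 0.005, 28, connectivity=26).n_clusters == 0

    def test_peak_world_coordinates(self):
        p = np.ones((5, 5, 5))
        p[1, 2, 3] = 1e-6
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-6.0, -6.0, -6.0]
        report = form_clusters(p, 0.005, 1, affine=affine)
        c = report.clusters[0]
        assert (c["peak_x"], c["peak_y"], c["peak_z"]) == (-3.0, 0.0, 3.0)


class TestExtractClusterMeans:
    def _report(self):
        p = np.ones((4, 4, 4))
        p[0, 0, 0] = 1e-6  # cluster 1: single voxel
        p[2, 2, 2:4] = 1e-6  # cluster 2: two voxels
        return form_clusters(p, 0.005, 1)

    def test_constant_map(self):
        report = self._report()
        mask = QualifiedMask(np.ones((4, 4, 4), bool))
        maps = np.full((3, 64), 2.5)
        out = extract_cluster_means(maps, report, mask)
        assert out.shape == (3, 2)
        np.testing.assert_allclose(out.to_numpy(), 2.5)

    def test_single_voxel_and_pair_mean(self):
        report = self._report()
        mask = QualifiedMask(np.ones((4, 4, 4), bool))
        grid = np.zeros((4, 4, 4))
        grid[0, 0, 0] = 7.0
        grid[2, 2, 2] = 1.0
        grid[2, 2, 3] = 3.0
        out = extract_cluster_means(grid.reshape(1, -1), report, mask)
        np.testing.assert_allclose(out.to_numpy()[0], [7.0, 2.0])


def test_parametric_p_agrees_with_permutation():
    """Diagnosis-effect parametric p vs label-permutation p at probe voxels."""
    rng = np.random.default_rng(21)
    table = random_table(6, rng)
    n_vox = 20
    n = len(table)
    y = rng.normal(size=(n, n_vox))
    design = build_design(table)
    f_obs, p_par, _, _ = ols_f_tests(y, design)

    def diagnosis_f(y_perm):
        beta_f = np.linalg.lstsq(design.matrix, y_perm, rcond=None)[0]
        resid_f = y_perm - design.matrix @ beta_f
        rss_f = (resid_f**2).sum(axis=0)
        x_red = design.reduced("diagnosis")
        beta_r = np.linalg.lstsq(x_red, y_perm, rcond=None)[0]
        resid_r = y_perm - x_red @ beta_r
        rss_r = (resid_r**2).sum(axis=0)
        df_err = design.df_error
        return (rss_r - rss_f) / (rss_f / df_err)

    n_perm = 5000
    exceed = np.zeros(n_vox)
    for _ in range(n_perm):
        exceed += diagnosis_f(y[rng.permutation(n)]) >= f_obs["diagnosis"]
    p_perm = (exceed + 1) / (n_perm + 1)
    np.testing.assert_allclose(p_par["diagnosis"], p_perm, atol=0.02 + 1e-9)
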