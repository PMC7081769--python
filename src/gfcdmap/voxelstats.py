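"""Voxel-wise 2×3 factorial ANCOVA with cluster-extent correction.

The model at every voxel is an ordinary-least-squares fit of the gFCD value
on a diagnosis factor (2 levels), a genotype factor (3 levels), their
interaction, and nuisance covariates (age, sex, education, mean framewise
displacement), with factors in sum-to-zero coding. Each effect's F statistic
is the Type-III (partial) test: the full model against the model with that
effect's columns removed.

Multiple comparisons are controlled at the cluster level in the classic
Monte-Carlo fashion: smooth Gaussian null fields matching the residual
smoothness are simulated on the analysis mask, thresholded at the
cluster-forming p, and the distribution of the maximum cluster size yields
the minimum surviving extent k_min for a chosen cluster-level α. Suprathreshold
connected components smaller than k_min are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fcd import GfcdMap, QualifiedMask, _FWHM_TO_SIGMA

__all__ = [
    "DesignMatrix",
    "FMapSet",
    "ClusterReport",
    "EFFECTS",
    "build_design",
    "ols_f_tests",
    "fit_voxelwise_ancova",
    "estimate_smoothness",
    "monte_carlo_extent_threshold",
    "form_clusters",
    "extract_cluster_means",
]

DIAGNOSIS_LEVELS = ("CN", "MCI")
GENOTYPE_LEVELS = ("e2+", "e3e3", "e4+")
EFFECTS = ("diagnosis", "genotype", "interaction")


@dataclass
class DesignMatrix:
    """Sum-to-zero-coded factorial design with covariates and an intercept.

    ``effect_columns`` maps each testable effect to the indices of its
    columns in ``matrix``, enabling Type-III full-vs-reduced comparisons.
    """

    matrix: np.ndarray
    columns: list[str]
    effect_columns: dict[str, list[int]]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def df_error(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]

    def reduced(self, effect: str) -> np.ndarray:
        drop = set(self.effect_columns[effect])
        keep = [j for j in range(self.matrix.shape[1]) if j not in drop]
        return self.matrix[:, keep]


def _sum_code(labels: pd.Series, levels: tuple[str, ...]) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels → k−1 columns; the last level
    is coded −1 in every column."""
    arr = np.zeros((len(labels), len(levels) - 1))
    for i, lab in enumerate(labels):
        if lab not in levels:
            raise ValueError(f"unknown factor level {lab!r}; expected one of {levels}")
        j = levels.index(lab)
        if j < len(levels) - 1:
            arr[i, j] = 1.0
        else:
            arr[i, :] = -1.0
    return arr


def build_design(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education", "mean_fd"),
    diagnosis_col: str = "diagnosis",
    genotype_col: str = "genotype",
) -> DesignMatrix:
    """Build the 2×3 factorial ANCOVA design from a phenotype table."""
    counts = table.groupby([diagnosis_col, genotype_col], observed=True).size()
    for dx in DIAGNOSIS_LEVELS:
        for gt in GENOTYPE_LEVELS:
            if counts.get((dx, gt), 0) == 0:
                raise ValueError(f"empty design cell: diagnosis={dx}, genotype={gt}")
    d = _sum_code(table[diagnosis_col], DIAGNOSIS_LEVELS)  # (n, 1)
    g = _sum_code(table[genotype_col], GENOTYPE_LEVELS)  # (n, 2)
    inter = d * g  # broadcasts to (n, 2)
    cov = table[list(covariates)].to_numpy(dtype=np.float64) if covariates else np.empty((len(table), 0))
    mat = np.column_stack([np.ones(len(table)), d, g, inter, cov])
    cols = (
        ["intercept", "dx"]
        + ["geno1", "geno2"]
        + ["dx:geno1", "dx:geno2"]
        + list(covariates)
    )
    effect_columns = {"diagnosis": [1], "genotype": [2, 3], "interaction": [4, 5]}
    return DesignMatrix(mat, cols, effect_columns)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and residual sum of squares of Y (n, V) on X (n, p)."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return resid, (resid**2).sum(axis=0)


def ols_f_tests(
    y: np.ndarray, design: DesignMatrix
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, tuple[int, int]], np.ndarray]:
    """Type-III F tests for every effect of a factorial ANCOVA.

    ``y`` is (n_subjects, n_responses). Returns per-effect F arrays, p arrays,
    (df_num, df_den) pairs, and the full-model residual matrix.
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if y.shape[0] != design.n_subjects:
        raise ValueError("response rows do not match the design")
    df_err = design.df_error
    if df_err < 1:
        raise ValueError("no residual degrees of freedom")
    resid_full, rss_full = _rss(design.matrix, y)
    f_stats: dict[str, np.ndarray] = {}
    p_vals: dict[str, np.ndarray] = {}
    dfs: dict[str, tuple[int, int]] = {}
    for effect, cols in design.effect_columns.items():
        df_num = len(cols)
        _, rss_red = _rss(design.reduced(effect), y)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_red - rss_full) / df_num) / (rss_full / df_err)
        f = np.clip(f, 0.0, None)
        f_stats[effect] = f
        p_vals[effect] = stats.f.sf(f, df_num, df_err)
        dfs[effect] = (df_num, df_err)
    return f_stats, p_vals, dfs, resid_full


@dataclass
class FMapSet:
    """3D F and p maps per effect, plus full-model residuals for smoothness."""

    f_maps: dict[str, np.ndarray]
    p_maps: dict[str, np.ndarray]
    dfs: dict[str, tuple[int, int]]
    residuals: np.ndarray  # (n_subjects, V) full-model residuals, mask order
    analysis_mask: np.ndarray  # 3D bool: qualified voxels with usable variance
    affine: np.ndarray
    excluded_voxels: int = 0


def fit_voxelwise_ancova(
    maps: list[GfcdMap] | np.ndarray,
    design: DesignMatrix,
    mask: QualifiedMask,
    affine: np.ndarray | None = None,
) -> FMapSet:
    """Fit the factorial ANCOVA at every qualified voxel.

    Voxels with zero variance across subjects (F undefined) are excluded from
    the analysis mask and counted in ``excluded_voxels``.
    """
    if isinstance(maps, np.ndarray):
        y = np.asarray(maps, dtype=np.float64)
        if affine is None:
            affine = np.eye(4)
    else:
        if affine is None:
            affine = maps[0].affine
        y = np.stack([m.data[mask.mask] for m in maps])  # (n, V)
    if y.shape[0] != design.n_subjects:
        raise ValueError(f"{y.shape[0]} maps for {design.n_subjects} design rows")
    variable = y.std(axis=0) > 0
    excluded = int((~variable).sum())
    y_use = y[:, variable]
    f_stats, p_vals, dfs, resid = ols_f_tests(y_use, design)
    analysis_mask = np.zeros(mask.mask.shape, dtype=bool)
    idx = np.flatnonzero(mask.mask.ravel())[variable]
    analysis_mask.ravel()[idx] = True
    f_maps, p_maps = {}, {}
    for effect in f_stats:
        f3 = np.zeros(mask.mask.shape)
        p3 = np.ones(mask.mask.shape)
        f3[analysis_mask] = f_stats[effect]
        p3[analysis_mask] = p_vals[effect]
        f_maps[effect] = f3
        p_maps[effect] = p3
    return FMapSet(f_maps, p_maps, dfs, resid, analysis_mask, np.asarray(affine), excluded)


def estimate_smoothness(fmaps: FMapSet, voxel_mm: tuple[float, float, float] | None = None) -> np.ndarray:
    """Per-axis Gaussian-field FWHM (mm) from the spatial autocorrelation of
    the model residuals.

    For each residual map the lag-1 spatial correlation ρ along each axis is
    estimated from the variance of first differences between in-mask
    neighbors; under a Gaussian autocorrelation FWHM = d·√(2 ln 2 / −ln ρ)
    for voxel size d. Estimates are averaged over residual maps.
    """
    mask = fmaps.analysis_mask
    if voxel_mm is None:
        voxel_mm = tuple(np.abs(np.diag(fmaps.affine[:3, :3])))
    n_sub = fmaps.residuals.shape[0]
    if n_sub < 2:
        raise ValueError("smoothness estimation needs at least 2 residual maps")
    rho_sum = np.zeros(3)
    rho_cnt = np.zeros(3)
    for s in range(n_sub):
        grid = np.full(mask.shape, np.nan)
        grid[mask] = fmaps.residuals[s]
        vals = fmaps.residuals[s]
        var = vals.var()
        if var <= 0:
            raise ValueError("constant residual map; smoothness undefined")
        for ax in range(3):
            if mask.shape[ax] < 2:
                raise ValueError(f"mask too thin along axis {ax} for smoothness estimation")
            d = np.diff(grid, axis=ax)
            d = d[np.isfinite(d)]
            if d.size < 2:
                raise ValueError(f"too few in-mask neighbor pairs along axis {ax}")
            rho = 1.0 - d.var() / (2.0 * var)
            rho_sum[ax] += rho
            rho_cnt[ax] += 1
    rho = np.clip(rho_sum / rho_cnt, 1e-8, 1 - 1e-8)
    return np.asarray(voxel_mm) * np.sqrt(2.0 * np.log(2.0) / -np.log(rho))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    rules = {6: 1, 18: 2, 26: 3}
    if connectivity not in rules:
        raise ValueError("connectivity must be 6, 18, or 26")
    return ndimage.generate_binary_structure(3, rules[connectivity])


def monte_carlo_extent_threshold(
    mask: QualifiedMask | np.ndarray,
    fwhm_mm: tuple[float, float, float],
    voxel_p: float,
    alpha: float,
    n_iter: int = 1000,
    connectivity: int = 26,
    seed: int = 0,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    two_tailed: bool = True,
) -> int:
    """Minimum cluster extent (voxels) controlling family-wise error at α.

    Simulates ``n_iter`` Gaussian random fields on the mask grid, smooths them
    to ``fwhm_mm``, thresholds at the z quantile matching ``voxel_p``
    (two-tailed by default), and takes the α quantile of the maximum-cluster-
    size distribution: k_min is the smallest k such that the fraction of null
    iterations whose largest cluster reaches k is at most α.
    """
    mask_arr = mask.mask if isinstance(mask, QualifiedMask) else np.asarray(mask, dtype=bool)
    if not (0 < voxel_p < 1 and 0 < alpha < 1):
        raise ValueError("voxel_p and alpha must lie in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    if alpha < 1.0 / n_iter:
        raise ValueError(f"alpha={alpha} is unresolvable with n_iter={n_iter}")
    structure = _connectivity_structure(connectivity)
    sigma_vox = np.asarray(fwhm_mm, dtype=np.float64) * _FWHM_TO_SIGMA / np.asarray(voxel_mm)
    zthr = stats.norm.isf(voxel_p / 2) if two_tailed else stats.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_iter, dtype=np.int64)
    for it in range(n_iter):
        field = rng.standard_normal(mask_arr.shape)
        if np.any(sigma_vox > 0):
            field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="reflect")
        vals = field[mask_arr]
        field = (field - vals.mean()) / vals.std()
        supra = np.zeros(mask_arr.shape, dtype=bool)
        supra[mask_arr] = np.abs(field[mask_arr]) > zthr if two_tailed else field[mask_arr] > zthr
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            max_sizes[it] = np.bincount(labels.ravel())[1:].max()
    # k_min: smallest k with P(max cluster >= k) <= alpha
    order = np.sort(max_sizes)[::-1]
    a = int(np.floor(alpha * n_iter))
    k_min = int(order[a]) + 1 if a < n_iter else 1
    return max(k_min, 1)


@dataclass
class ClusterReport:
    """Suprathreshold clusters surviving the extent threshold."""

    clusters: list[dict]
    labels: np.ndarray  # 3D int labels, 0 = background (relabeled 1..n_clusters)
    voxel_p: float
    k_min: int
    connectivity: int
    alpha: float | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["label", "size_voxels", "size_mm3", "peak_x", "peak_y", "peak_z", "peak_stat"]
        return pd.DataFrame(self.clusters, columns=cols if self.clusters else cols)


def form_clusters(
    pmap: np.ndarray,
    voxel_p: float,
    k_min: int,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
    stat_map: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    alpha: float | None = None,
) -> ClusterReport:
    """Label connected suprathreshold components and drop those below k_min."""
    if k_min < 1:
        raise ValueError("k_min must be at least 1")
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=np.float64)
    supra = np.asarray(pmap) < voxel_p
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    structure = _connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(supra, structure=structure)
    voxel_vol = float(abs(np.linalg.det(affine[:3, :3])))
    clusters = []
    out_labels = np.zeros_like(labels)
    next_label = 0
    if n_lab:
        sizes = np.bincount(labels.ravel())
        score = stat_map if stat_map is not None else -np.asarray(pmap)
        for lab in range(1, n_lab + 1):
            if sizes[lab] < k_min:
                continue
            next_label += 1
            members = labels == lab
            out_labels[members] = next_label
            coords = np.argwhere(members)
            peak_idx = coords[np.argmax(score[members])]
            world = affine @ np.append(peak_idx, 1.0)
            clusters.append(
                {
                    "label": next_label,
                    "size_voxels": int(sizes[lab]),
                    "size_mm3": float(sizes[lab] * voxel_vol),
                    "peak_x": float(world[0]),
                    "peak_y": float(world[1]),
                    "peak_z": float(world[2]),
                    "peak_stat": float(score[members].max()),
                }
            )
    return ClusterReport(clusters, out_labels, voxel_p, k_min, connectivity, alpha, affine)


def extract_cluster_means(
    maps: list[GfcdMap] | np.ndarray, report: ClusterReport, mask: QualifiedMask | None = None
) -> pd.DataFrame:
    """Per-subject mean map value over each surviving cluster.

    ``maps`` may be GfcdMap objects (full grids) or an (n_subjects, V) array
    in mask order, in which case ``mask`` locates the columns on the grid.
    """
    if report.n_clusters == 0:
        raise ValueError("cluster report is empty; nothing to extract")
    if isinstance(maps, np.ndarray):
        if mask is None:
            raise ValueError("mask is required when maps are given in flattened form")
        grids = []
        for row in maps:
            g = np.zeros(mask.mask.shape)
            g[mask.mask] = row
            grids.append(g)
    else:
        grids = [m.data for m in maps]
        if grids and grids[0].shape != report.labels.shape:
            raise ValueError("map grid does not match the cluster report")
    out = {}
    for cl in report.clusters:
        sel = report.labels == cl["label"]
        out[f"cluster_{cl['label']}"] = [float(g[sel].mean()) for g in grids]
    return pd.DataFrame(out)
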