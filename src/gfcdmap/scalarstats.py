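"""Scalar phenotype statistics for the 2 (diagnosis) × 3 (genotype) layout.

Cognitive outcomes are tested with the same Type-III factorial ANCOVA core as
the voxel-wise analysis (age, sex and education as covariates for cognition;
intracranial volume added for regional brain volumes), demographics with
Kruskal–Wallis tests across the six cells (chi-square for sex), and genotype
post-hoc contrasts with Fisher-LSD t tests on covariate-adjusted marginal
means (Tukey HSD selectable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .voxelstats import (
    DIAGNOSIS_LEVELS,
    GENOTYPE_LEVELS,
    DesignMatrix,
    build_design,
    ols_f_tests,
)

__all__ = [
    "AncovaResult",
    "scalar_ancova",
    "demographics_tests",
    "post_hoc_genotype",
    "table1_report",
]

COGNITIVE_OUTCOMES = (
    "mmse",
    "adas13",
    "ravlt_immediate",
    "ravlt_learning",
    "ravlt_forgetting",
    "logical_memory",
    "trails_b",
)
STRUCTURAL_OUTCOMES = ("hippocampus", "entorhinal", "fusiform")
DEMOGRAPHICS = ("age", "education", "icv", "mean_fd")


@dataclass
class AncovaResult:
    outcome: str
    f: dict[str, float]
    p: dict[str, float]
    dfs: dict[str, tuple[int, int]]
    adjusted_cell_means: pd.Series
    covariates: tuple[str, ...]

    @property
    def df_error(self) -> int:
        return next(iter(self.dfs.values()))[1]


def _validate_outcome(y: np.ndarray, outcome: str) -> None:
    if not np.all(np.isfinite(y)):
        raise ValueError(f"outcome {outcome!r} contains missing or non-finite values")
    if y.std() == 0:
        raise ValueError(f"outcome {outcome!r} is constant; F undefined")


def _adjusted_cell_means(
    table: pd.DataFrame, design: DesignMatrix, y: np.ndarray, covariates: tuple[str, ...]
) -> pd.Series:
    """Model-predicted cell means with covariates held at their grand means."""
    coef, *_ = np.linalg.lstsq(design.matrix, y, rcond=None)
    cov_means = (
        table[list(covariates)].to_numpy(dtype=np.float64).mean(axis=0)
        if covariates
        else np.empty(0)
    )
    means = {}
    for dx in DIAGNOSIS_LEVELS:
        for gt in GENOTYPE_LEVELS:
            d = 1.0 if dx == DIAGNOSIS_LEVELS[0] else -1.0
            g = np.zeros(2)
            j = GENOTYPE_LEVELS.index(gt)
            if j < 2:
                g[j] = 1.0
            else:
                g[:] = -1.0
            row = np.concatenate([[1.0, d], g, d * g, cov_means])
            means[(dx, gt)] = float(row @ coef)
    return pd.Series(means)


def scalar_ancova(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
) -> AncovaResult:
    """Type-III 2×3 ANCOVA on one scalar outcome."""
    y = table[outcome].to_numpy(dtype=np.float64)
    _validate_outcome(y, outcome)
    design = build_design(table, covariates=covariates)
    f_stats, p_vals, dfs, _ = ols_f_tests(y[:, None], design)
    f = {e: float(v[0]) for e, v in f_stats.items()}
    p = {e: float(v[0]) for e, v in p_vals.items()}
    cell_means = _adjusted_cell_means(table, design, y, covariates)
    return AncovaResult(outcome, f, p, dfs, cell_means, tuple(covariates))


def demographics_tests(table: pd.DataFrame, variables: tuple[str, ...] = ("age", "education")) -> pd.DataFrame:
    """Kruskal–Wallis across the six diagnosis×genotype cells for continuous
    demographics; contingency chi-square for sex."""
    cells = [
        table[(table["diagnosis"] == dx) & (table["genotype"] == gt)]
        for dx in DIAGNOSIS_LEVELS
        for gt in GENOTYPE_LEVELS
    ]
    if sum(len(c) > 0 for c in cells) < 2:
        raise ValueError("need at least 2 non-empty groups")
    rows = []
    for var in variables:
        samples = [c[var].to_numpy(dtype=np.float64) for c in cells if len(c)]
        flat = np.concatenate(samples)
        if np.all(flat == flat[0]):
            raise ValueError(f"all values of {var!r} are tied; ranks undefined")
        h, p = stats.kruskal(*samples)
        rows.append({"variable": var, "test": "kruskal", "statistic": float(h), "p": float(p)})
    if "sex" in table.columns:
        contingency = pd.crosstab(
            table["diagnosis"].astype(str) + "/" + table["genotype"].astype(str), table["sex"]
        )
        chi2, p, _, _ = stats.chi2_contingency(contingency)
        rows.append({"variable": "sex", "test": "chi2", "statistic": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)


def post_hoc_genotype(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    method: str = "lsd",
) -> pd.DataFrame:
    """Pairwise genotype contrasts on covariate-adjusted marginal means.

    Fits Y ~ genotype (dummy coded) + covariates and tests each pairwise
    difference with a t contrast; ``method='lsd'`` reports unadjusted
    (Fisher LSD) p values, ``'tukey'`` applies the studentized-range
    correction. Also reports the protective-carrier (e2+) vs pooled-others
    contrast.
    """
    y = table[outcome].to_numpy(dtype=np.float64)
    _validate_outcome(y, outcome)
    g_dummies = np.column_stack(
        [(table["genotype"] == gt).to_numpy(dtype=np.float64) for gt in GENOTYPE_LEVELS[1:]]
    )
    cov = table[list(covariates)].to_numpy(dtype=np.float64) if covariates else np.empty((len(table), 0))
    x = np.column_stack([np.ones(len(table)), g_dummies, cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("post-hoc design is rank deficient")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df_err = len(y) - x.shape[1]
    mse = float(resid @ resid) / df_err
    xtx_inv = np.linalg.inv(x.T @ x)
    cov_means = cov.mean(axis=0) if covariates else np.empty(0)

    def marginal_row(gt: str) -> np.ndarray:
        row = np.zeros(x.shape[1])
        row[0] = 1.0
        j = GENOTYPE_LEVELS.index(gt)
        if j > 0:
            row[j] = 1.0
        row[1 + len(GENOTYPE_LEVELS) - 1 :] = cov_means
        return row

    margins = {gt: marginal_row(gt) for gt in GENOTYPE_LEVELS}
    k = len(GENOTYPE_LEVELS)
    rows = []
    contrasts = list(combinations(GENOTYPE_LEVELS, 2)) + [("e2+", "pooled(e3e3,e4+)")]
    for g1, g2 in contrasts:
        c1 = margins[g1]
        if g2.startswith("pooled"):
            n3 = float((table["genotype"] == "e3e3").sum())
            n4 = float((table["genotype"] == "e4+").sum())
            c2 = (n3 * margins["e3e3"] + n4 * margins["e4+"]) / (n3 + n4)
        else:
            c2 = margins[g2]
        c = c1 - c2
        diff = float(c @ coef)
        se = float(np.sqrt(mse * c @ xtx_inv @ c))
        t = diff / se
        if method == "lsd" or g2.startswith("pooled"):
            p = 2 * stats.t.sf(abs(t), df_err)
        elif method == "tukey":
            p = stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df_err)
        else:
            raise ValueError(f"unknown post-hoc method {method!r}")
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "adj_mean1": float(c1 @ coef),
                "adj_mean2": float(c2 @ coef),
                "difference": diff,
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def table1_report(
    table: pd.DataFrame,
    outcomes: tuple[str, ...] = COGNITIVE_OUTCOMES + STRUCTURAL_OUTCOMES,
    cognitive_covariates: tuple[str, ...] = ("age", "sex", "education"),
    structural_covariates: tuple[str, ...] = ("icv",),
) -> pd.DataFrame:
    """Cohort summary: per-cell mean ± SD and the three ANCOVA p values per
    outcome, in the shape of a demographics-and-outcomes cohort table."""
    rows = []
    for outcome in outcomes:
        if outcome not in table.columns:
            continue
        covs = structural_covariates if outcome in STRUCTURAL_OUTCOMES else cognitive_covariates
        res = scalar_ancova(table, outcome, covariates=covs)
        row: dict = {"outcome": outcome}
        for dx in DIAGNOSIS_LEVELS:
            for gt in GENOTYPE_LEVELS:
                cell = table[(table["diagnosis"] == dx) & (table["genotype"] == gt)][outcome]
                row[f"{dx}_{gt}"] = f"{cell.mean():.2f} ± {cell.std():.2f}"
        row["p_diagnosis"] = res.p["diagnosis"]
        row["p_genotype"] = res.p["genotype"]
        row["p_interaction"] = res.p["interaction"]
        rows.append(row)
    return pd.DataFrame(rows)
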