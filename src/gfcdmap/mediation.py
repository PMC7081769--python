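"""Simple (single-mediator) mediation with bias-corrected bootstrap CIs.

The model decomposes the effect of a predictor X on an outcome Y into a
direct path c′ and an indirect path a·b through a mediator M, all adjusted
for covariates, via three OLS regressions:

    M = i1 + a·X + covariates
    Y = i2 + c′·X + b·M + covariates
    Y = i3 + c·X + covariates        (total effect; c = c′ + a·b exactly)

Inference on the indirect effect a·b uses case-resampling bootstrap with
bias-corrected (z0-adjusted percentile) confidence intervals: z0 is the
normal quantile of the fraction of bootstrap estimates below the point
estimate, and the percentile endpoints are shifted to Φ(2·z0 ± z_{α/2}).
The bootstrap is vectorized with batched normal equations, so the default
10,000 resamples run in well under a second at cohort-scale n.

For the imaging-genetics use case X is the genotype coded ordinally by risk
(protective carriers 1, reference homozygotes 2, risk carriers 3), M a brain
feature (regional volume or cluster-mean connectivity density), and Y a
cognitive score; the battery runs every (mediator, outcome) pair within one
diagnosis group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MediationFit",
    "GENOTYPE_RISK_CODE",
    "fit_mediation",
    "screen_gene_cognition",
    "run_mediation_battery",
]

GENOTYPE_RISK_CODE = {"e2+": 1.0, "e3e3": 2.0, "e4+": 3.0}


@dataclass
class MediationFit:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    n_obs: int
    seed: int
    significant: bool
    mediator: str = ""
    outcome: str = ""
    covariates: tuple[str, ...] = ()


def _ols_coef(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("collinear design in mediation regression")
    return coef


def _batched_slope(x: np.ndarray, y: np.ndarray, col: int) -> np.ndarray:
    """Coefficient ``col`` of OLS fits for a batch of designs.

    x: (B, n, p), y: (B, n) → (B,) via batched normal equations."""
    xtx = np.einsum("bni,bnj->bij", x, x)
    xty = np.einsum("bni,bn->bi", x, y)
    return np.linalg.solve(xtx, xty[..., None])[:, col, 0]


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 10000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> MediationFit:
    """Fit the three-regression mediation model and bootstrap the indirect
    effect with a bias-corrected percentile interval."""
    x = np.asarray(x, dtype=np.float64).ravel()
    m = np.asarray(m, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=np.float64)).reshape(n, -1)
    )
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must have equal lengths")
    if n < cov.shape[1] + 4:
        raise ValueError(f"n={n} too small for {cov.shape[1]} covariates")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")

    ones = np.ones((n, 1))
    xa = np.column_stack([ones, x, cov])  # M ~ X
    xb = np.column_stack([ones, x, m, cov])  # Y ~ X + M
    xc = np.column_stack([ones, x, cov])  # Y ~ X
    a = float(_ols_coef(xa, m)[1])
    beta_b = _ols_coef(xb, y)
    c_prime, b = float(beta_b[1]), float(beta_b[2])
    c = float(_ols_coef(xc, y)[1])
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb_boot = x[idx]
    mb_boot = m[idx]
    yb_boot = y[idx]
    cov_boot = cov[idx]  # (B, n, q)
    design_a = np.concatenate(
        [np.ones((n_boot, n, 1)), xb_boot[..., None], cov_boot], axis=2
    )
    design_b = np.concatenate(
        [np.ones((n_boot, n, 1)), xb_boot[..., None], mb_boot[..., None], cov_boot], axis=2
    )
    try:
        a_boot = _batched_slope(design_a, mb_boot, 1)
        b_boot = _batched_slope(design_b, yb_boot, 2)
    except np.linalg.LinAlgError:
        # fall back to per-resample lstsq on singular batches
        a_boot = np.empty(n_boot)
        b_boot = np.empty(n_boot)
        for i in range(n_boot):
            a_boot[i] = np.linalg.lstsq(design_a[i], mb_boot[i], rcond=None)[0][1]
            b_boot[i] = np.linalg.lstsq(design_b[i], yb_boot[i], rcond=None)[0][2]
    boot = a_boot * b_boot

    alpha = 1.0 - ci_level
    prop_below = np.clip((boot < indirect).mean(), 1.0 / n_boot, 1 - 1.0 / n_boot)
    z0 = stats.norm.ppf(prop_below)
    z_crit = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(2 * z0 + z_crit)
    ci_low, ci_high = np.quantile(boot, adj)
    significant = bool(ci_low > 0 or ci_high < 0)
    return MediationFit(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        ci_level=ci_level,
        n_boot=n_boot,
        n_obs=n,
        seed=seed,
        significant=significant,
    )


def screen_gene_cognition(
    table: pd.DataFrame,
    outcomes: tuple[str, ...],
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    genotype_code: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-outcome covariate-adjusted test of the genotype predictor, run
    within each diagnosis group. Used to shortlist outcome candidates; a
    non-significant screen does not preclude testing mediation."""
    code = genotype_code or GENOTYPE_RISK_CODE
    rows = []
    for dx, grp in table.groupby("diagnosis", observed=True):
        x = grp["genotype"].map(code).to_numpy(dtype=np.float64)
        cov = grp[list(covariates)].to_numpy(dtype=np.float64)
        design_full = np.column_stack([np.ones(len(grp)), x, cov])
        design_red = np.column_stack([np.ones(len(grp)), cov])
        for outcome in outcomes:
            y = grp[outcome].to_numpy(dtype=np.float64)
            rf = y - design_full @ np.linalg.lstsq(design_full, y, rcond=None)[0]
            rr = y - design_red @ np.linalg.lstsq(design_red, y, rcond=None)[0]
            df_err = len(grp) - design_full.shape[1]
            rss_f = float(rf @ rf)
            f = ((float(rr @ rr) - rss_f) / 1.0) / (rss_f / df_err)
            rows.append(
                {
                    "diagnosis": dx,
                    "outcome": outcome,
                    "f": f,
                    "p": float(stats.f.sf(f, 1, df_err)),
                }
            )
    return pd.DataFrame(rows)


def run_mediation_battery(
    table: pd.DataFrame,
    mediators: tuple[str, ...],
    outcomes: tuple[str, ...],
    group: str = "MCI",
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    n_boot: int = 10000,
    ci_level: float = 0.95,
    seed: int = 0,
    genotype_code: dict[str, float] | None = None,
) -> list[MediationFit]:
    """One mediation fit per (mediator, outcome) pair within one diagnosis
    group, with genotype as the ordinally coded predictor."""
    code = genotype_code or GENOTYPE_RISK_CODE
    grp = table[table["diagnosis"] == group]
    if grp.empty:
        raise ValueError(f"no subjects with diagnosis {group!r}")
    x = grp["genotype"].map(code).to_numpy(dtype=np.float64)
    cov = grp[list(covariates)].to_numpy(dtype=np.float64)
    fits = []
    for k, mediator in enumerate(mediators):
        for j, outcome in enumerate(outcomes):
            fit = fit_mediation(
                x,
                grp[mediator].to_numpy(dtype=np.float64),
                grp[outcome].to_numpy(dtype=np.float64),
                covariates=cov,
                n_boot=n_boot,
                ci_level=ci_level,
                seed=seed + 1000 * k + j,
            )
            fit.mediator = mediator
            fit.outcome = outcome
            fit.covariates = tuple(covariates)
            fits.append(fit)
    return fits
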