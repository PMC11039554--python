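"""ComBat multi-site harmonization (parametric empirical Bayes).

Implements the standard location/scale batch model
    y_gij = alpha_g + X_ij beta_g + gamma_gi + delta_gi eps_gij
for feature g, site i, subject j: additive site effects gamma and
multiplicative site effects delta are shrunk toward their across-feature
priors (normal for gamma, inverse-gamma for delta, moments-matched) by
iterative conditional estimation, then removed while the intercept,
protected biological covariates and residual scale are restored.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CONV_TOL = 1e-4


def _design_from_phenotype(phenotype: pd.DataFrame, preserve) -> np.ndarray:
    """Covariate design (no intercept): numeric columns as-is, categoricals
    dummy-coded with the first level dropped."""
    cols = []
    for c in preserve:
        v = phenotype[c]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(float)[:, None])
        else:
            d = pd.get_dummies(v, drop_first=True).to_numpy(float)
            cols.append(d)
    if not cols:
        return np.empty((len(phenotype), 0))
    return np.hstack(cols)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=CONV_TOL):
    """Iterative conditional EB estimates of one batch's gamma*, delta*."""
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() > 0 else 0,
            np.abs(d_new - d_old).max() / d_old.max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat(
    features: pd.DataFrame,
    phenotype: pd.DataFrame,
    batch: str = "site",
    preserve=("group", "age", "gender"),
) -> pd.DataFrame:
    """Harmonize a subjects-by-features table across sites.

    Parameters
    ----------
    features
        Subjects in rows (index aligned with ``phenotype`` order),
        features in columns; no missing values.
    phenotype
        Table with the ``batch`` column and every ``preserve`` column.
    preserve
        Biological covariates whose effects are protected (fit in the
        standardization model and re-added after adjustment).

    Returns the harmonized table with identical shape and ordering.
    Constant features are passed through unchanged with a warning.
    """
    if len(features) != len(phenotype):
        raise ValueError("features and phenotype row counts differ")
    y_full = features.to_numpy(float).T  # G x N
    if np.isnan(y_full).any():
        raise ValueError("missing values are not allowed in harmonization input")
    sites = phenotype[batch].to_numpy()
    levels = pd.unique(sites)
    if len(levels) < 2:
        raise ValueError("harmonization requires >= 2 sites")
    batch_idx = [np.flatnonzero(sites == s) for s in levels]
    for s, idx in zip(levels, batch_idx):
        if idx.size < 2:
            raise ValueError(f"site {s!r} has {idx.size} subject(s); >= 2 required")
    n = len(phenotype)
    n_batch = len(levels)
    batch_design = np.zeros((n, n_batch))
    for k, idx in enumerate(batch_idx):
        batch_design[idx, k] = 1.0
    cov = _design_from_phenotype(phenotype, preserve)
    design = np.hstack([batch_design, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (confounded batch/covariates)"
        )

    const = y_full.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} constant feature(s) passed through unharmonized",
            stacklevel=2,
        )
    y = y_full[~const]

    # standardize: grand mean + covariate effects, pooled variance
    b_hat = np.linalg.solve(design.T @ design, design.T @ y.T)  # (B+p) x G
    sizes = np.array([idx.size for idx in batch_idx], dtype=float)
    grand_mean = (sizes / n) @ b_hat[:n_batch]
    var_pooled = ((y - (design @ b_hat).T) ** 2).mean(axis=1)
    zero_var = var_pooled == 0
    var_pooled[zero_var] = 1.0  # features with exact fit: avoid 0/0
    stand_mean = grand_mean[:, None] + (cov @ b_hat[n_batch:]).T
    s_data = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    # EB shrinkage per batch
    gamma_star = np.empty((n_batch, y.shape[0]))
    delta_star = np.empty((n_batch, y.shape[0]))
    for k, idx in enumerate(batch_idx):
        sdat = s_data[:, idx]
        g_hat = sdat.mean(axis=1)
        d_hat = sdat.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        gamma_star[k], delta_star[k] = _it_sol(
            sdat, g_hat, d_hat, g_bar, t2, _aprior(d_hat), _bprior(d_hat)
        )

    adjusted = s_data.copy()
    for k, idx in enumerate(batch_idx):
        adjusted[:, idx] = (adjusted[:, idx] - gamma_star[k][:, None]) / np.sqrt(
            delta_star[k]
        )[:, None]
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

    out = y_full.copy()
    out[~const] = adjusted
    return pd.DataFrame(out.T, index=features.index, columns=features.columns)


def estimate_site_effects(
    features: pd.DataFrame,
    phenotype: pd.DataFrame,
    batch: str = "site",
    preserve=("group", "age", "gender"),
) -> dict[str, pd.DataFrame]:
    """Naive (non-EB) per-site location/scale estimates on standardized data.

    Returned for diagnostics and recovery tests: ``gamma`` are per-site
    feature means and ``delta`` per-site feature variances of the
    standardized data, the quantities the EB step shrinks.
    """
    y = features.to_numpy(float).T
    sites = phenotype[batch].to_numpy()
    levels = pd.unique(sites)
    cov = _design_from_phenotype(phenotype, preserve)
    n = len(phenotype)
    batch_design = np.zeros((n, len(levels)))
    for k, s in enumerate(levels):
        batch_design[sites == s, k] = 1.0
    design = np.hstack([batch_design, cov])
    b_hat = np.linalg.lstsq(design, y.T, rcond=None)[0]
    sizes = np.array([(sites == s).sum() for s in levels], dtype=float)
    grand_mean = (sizes / n) @ b_hat[: len(levels)]
    var_pooled = ((y - (design @ b_hat).T) ** 2).mean(axis=1)
    stand_mean = grand_mean[:, None] + (cov @ b_hat[len(levels):]).T
    s_data = (y - stand_mean) / np.sqrt(np.where(var_pooled == 0, 1, var_pooled))[:, None]
    gamma = pd.DataFrame(
        {s: s_data[:, sites == s].mean(axis=1) for s in levels}, index=features.columns
    )
    delta = pd.DataFrame(
        {s: s_data[:, sites == s].var(axis=1, ddof=1) for s in levels},
        index=features.columns,
    )
    return {"gamma": gamma, "delta": delta}
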