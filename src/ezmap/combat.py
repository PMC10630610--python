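"""Parametric empirical-Bayes batch harmonization (ComBat).

Location/scale harmonization of feature-by-subject data across scanner
batches, shrinking per-batch, per-feature effects toward their batch-wide
means via parametric priors (normal for location, inverse-gamma for
scale), while protecting biological covariates supplied in a design
matrix.  The model, per feature g and subject j in batch i:

    y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

Harmonized data replace (gamma_ig, delta_ig) with the shrunken
(gamma*_ig, delta*_ig) and remove them:

    y*_ijg = sigma_g / delta*_ig * (z_ijg - gamma*_ig) + alpha_g + X_j beta_g

The fit can be estimated on a reference cohort (e.g. healthy controls)
and applied to further subjects from the same batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CombatModel", "fit_combat", "apply_combat", "combat"]


@dataclass
class CombatModel:
    """Fitted harmonization parameters (features along the last axis)."""

    batches: list[str]
    grand_mean: np.ndarray  # (n_features,)
    beta: np.ndarray  # (n_covariates, n_features)
    pooled_sd: np.ndarray  # (n_features,)
    gamma_star: np.ndarray  # (n_batches, n_features)
    delta_star: np.ndarray  # (n_batches, n_features)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative solution for the EB-shrunken location/scale of one batch."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(1e-30)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(1e-30)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def fit_combat(
    data: np.ndarray,
    batch: np.ndarray,
    covariates: np.ndarray | None = None,
) -> CombatModel:
    """Estimate harmonization parameters.

    Parameters
    ----------
    data : (n_subjects, n_features)
    batch : (n_subjects,) batch labels
    covariates : (n_subjects, n_covariates) biological covariates to
        protect (e.g. age, sex); may be None.
    """
    y = np.asarray(data, dtype=float)
    batch = np.asarray(batch)
    if y.ndim != 2:
        raise ValueError("data must be 2-D (subjects x features)")
    labels = sorted({str(b) for b in batch})
    idx = {lab: np.flatnonzero(batch.astype(str) == lab) for lab in labels}
    for lab, ii in idx.items():
        if ii.size < 2:
            raise ValueError(f"batch {lab!r} has fewer than 2 subjects")
    n, n_feat = y.shape
    n_batches = len(labels)
    B = np.zeros((n, n_batches))
    for k, lab in enumerate(labels):
        B[idx[lab], k] = 1.0
    X = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = np.hstack([B, X])
    # per-feature OLS of y on batch indicators + covariates (no intercept;
    # batch columns span it)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    gamma_hat_ols = coef[:n_batches]  # batch means after covariate removal
    beta = coef[n_batches:]
    frac = np.array([idx[lab].size / n for lab in labels])
    grand_mean = frac @ gamma_hat_ols
    resid = y - design @ coef
    pooled_var = (resid**2).mean(axis=0)
    pooled_sd = np.sqrt(pooled_var)
    if np.any(pooled_sd <= 0):
        raise ValueError("feature with zero residual variance; cannot standardize")
    stand = (y - grand_mean[None, :] - X @ beta) / pooled_sd[None, :]
    gamma_star = np.empty((n_batches, n_feat))
    delta_star = np.empty((n_batches, n_feat))
    for k, lab in enumerate(labels):
        z = stand[idx[lab]]
        g_hat = z.mean(axis=0)
        d_hat = z.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        if n_feat < 2 or t2 == 0 or d_hat.var(ddof=1) == 0:
            # too few features for EB pooling: fall back to direct estimates
            gamma_star[k], delta_star[k] = g_hat, d_hat
            continue
        a, b = _aprior(d_hat), _bprior(d_hat)
        gamma_star[k], delta_star[k] = _it_sol(z, g_hat, d_hat, g_bar, t2, a, b)
    return CombatModel(
        batches=labels,
        grand_mean=grand_mean,
        beta=beta,
        pooled_sd=pooled_sd,
        gamma_star=gamma_star,
        delta_star=delta_star,
    )


def apply_combat(
    model: CombatModel,
    data: np.ndarray,
    batch: np.ndarray,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Harmonize (possibly new) subjects with an already-fitted model."""
    y = np.asarray(data, dtype=float)
    batch = np.asarray(batch).astype(str)
    X = np.empty((y.shape[0], 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    out = np.empty_like(y)
    lookup = {lab: k for k, lab in enumerate(model.batches)}
    fitted_cov = model.grand_mean[None, :] + X @ model.beta
    for j in range(y.shape[0]):
        lab = batch[j]
        if lab not in lookup:
            raise ValueError(f"batch {lab!r} was not present at fit time")
        k = lookup[lab]
        z = (y[j] - fitted_cov[j]) / model.pooled_sd
        out[j] = (
            model.pooled_sd / np.sqrt(model.delta_star[k]) * (z - model.gamma_star[k])
            + fitted_cov[j]
        )
    return out


def combat(
    data: np.ndarray, batch: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    """Fit-and-apply harmonization in one step (single batch = identity)."""
    batch = np.asarray(batch)
    if len({str(b) for b in batch}) < 2:
        return np.asarray(data, dtype=float).copy()
    model = fit_combat(data, batch, covariates)
    return apply_combat(model, data, batch, covariates)
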