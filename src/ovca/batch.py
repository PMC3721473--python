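"""Empirical-Bayes batch adjustment, variance filtering and gene centering.

The adjustment is the parametric location/scale model: genes are
standardized against a pooled design fit, per-batch per-gene location and
scale effects are estimated and shrunk toward moment-matched normal /
inverse-gamma priors, then removed and the data back-transformed. Optional
covariates (e.g. subtype labels) are protected in the design so biological
group structure survives adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ovca.io_formats import ExpressionMatrix

__all__ = ["BatchModel", "combat_adjust", "variance_filter", "center_genes"]


@dataclass
class BatchModel:
    """Fitted location/scale batch model.

    ``gamma_star`` and ``delta_star`` are the EB-shrunk per-(batch, gene)
    location and scale effects; ``priors`` holds the per-batch hyperparameters
    (gamma_bar, tau2, a_prior, b_prior).
    """

    batch_levels: list[str]
    gene_ids: list[str]
    grand_mean: np.ndarray
    pooled_var: np.ndarray
    gamma_star: pd.DataFrame  # batches x genes
    delta_star: pd.DataFrame  # batches x genes
    priors: pd.DataFrame  # batches x (gamma_bar, tau2, a_prior, b_prior)


def _design_matrix(batches: np.ndarray, covariates: np.ndarray | None):
    batch_levels = sorted(set(batches))
    B = np.column_stack([(batches == b).astype(float) for b in batch_levels])
    if covariates is None:
        return B, batch_levels, 0
    cov_levels = sorted(set(covariates))
    # drop first level: batch indicators already span the intercept
    C = np.column_stack([(covariates == c).astype(float) for c in cov_levels[1:]])
    if C.size == 0:
        return B, batch_levels, 0
    return np.hstack([B, C]), batch_levels, C.shape[1]


def combat_adjust(
    expr: ExpressionMatrix,
    batches,
    covariates=None,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove batch location/scale effects by parametric empirical Bayes.

    Parameters
    ----------
    expr : ExpressionMatrix
        Log-scale expression, genes x samples.
    batches : sequence of str
        Batch label per sample; every batch needs >= 2 samples.
    covariates : sequence of str, optional
        Biological group label per sample, protected in the design.
    """
    batches = np.asarray([str(b) for b in batches], dtype=object)
    if len(batches) != expr.n_samples:
        raise ValueError("one batch label per sample required")
    if covariates is not None:
        covariates = np.asarray([str(c) for c in covariates], dtype=object)
        if len(covariates) != expr.n_samples:
            raise ValueError("one covariate label per sample required")

    X = expr.values
    design, batch_levels, n_cov = _design_matrix(batches, covariates)
    n_batches = len(batch_levels)
    counts = np.array([(batches == b).sum() for b in batch_levels])
    if np.any(counts < 2):
        bad = batch_levels[int(np.argmin(counts))]
        raise ValueError(f"batch {bad!r} has fewer than 2 samples")

    n_genes, n_samples = X.shape

    zero_var = X.var(axis=1) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} gene(s) with zero variance passed through unadjusted",
            stacklevel=2,
        )

    if n_batches == 1:
        model = BatchModel(
            batch_levels,
            list(expr.gene_ids),
            X.mean(axis=1),
            X.var(axis=1, ddof=0),
            pd.DataFrame(np.zeros((1, n_genes)), index=batch_levels, columns=expr.gene_ids),
            pd.DataFrame(np.ones((1, n_genes)), index=batch_levels, columns=expr.gene_ids),
            pd.DataFrame(
                {"gamma_bar": [0.0], "tau2": [0.0], "a_prior": [np.nan], "b_prior": [np.nan]},
                index=batch_levels,
            ),
        )
        return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), X.copy()), model

    # GLS fit of batch + covariate design, gene-wise (OLS row by row)
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (p, genes)
    frac = counts / n_samples
    grand_mean = frac @ beta[:n_batches]  # genes
    fitted_no_batch = np.outer(np.ones(n_samples), grand_mean).T
    if n_cov:
        fitted_no_batch = fitted_no_batch + (design[:, n_batches:] @ beta[n_batches:]).T

    resid = X - (design @ beta).T
    pooled_var = (resid**2).mean(axis=1)  # genes
    pooled_sd = np.sqrt(pooled_var)
    safe_sd = np.where(pooled_sd == 0, 1.0, pooled_sd)

    Z = (X - fitted_no_batch) / safe_sd[:, None]

    gamma_hat = np.empty((n_batches, n_genes))
    delta_hat = np.empty((n_batches, n_genes))
    for i, b in enumerate(batch_levels):
        cols = batches == b
        gamma_hat[i] = Z[:, cols].mean(axis=1)
        delta_hat[i] = Z[:, cols].var(axis=1, ddof=1)

    # moment-matched hyperpriors per batch
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    v = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * s2 + v**2) / s2
        b_prior = (v * s2 + v**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i in range(n_batches):
        n_b = counts[i]
        g, d = gamma_hat[i].copy(), delta_hat[i].copy()
        cols = batches == batch_levels[i]
        Zb = Z[:, cols]
        # iterate the EB point estimates to convergence
        for _ in range(200):
            g_new = (n_b * tau2[i] * gamma_hat[i] + d * gamma_bar[i]) / (n_b * tau2[i] + d)
            ssq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ssq + b_prior[i]) / (n_b / 2 + a_prior[i] - 1)
            if np.max(np.abs(g_new - g)) < 1e-8 and np.max(np.abs(d_new - d)) < 1e-8:
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        gamma_star[i], delta_star[i] = g, np.maximum(d, 1e-12)

    adjusted = Z.copy()
    for i, b in enumerate(batch_levels):
        cols = batches == b
        adjusted[:, cols] = (Z[:, cols] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i][:, None]
        )
    adjusted = adjusted * safe_sd[:, None] + fitted_no_batch
    adjusted[zero_var] = X[zero_var]

    model = BatchModel(
        batch_levels,
        list(expr.gene_ids),
        grand_mean,
        pooled_var,
        pd.DataFrame(gamma_star, index=batch_levels, columns=expr.gene_ids),
        pd.DataFrame(delta_star, index=batch_levels, columns=expr.gene_ids),
        pd.DataFrame(
            {"gamma_bar": gamma_bar, "tau2": tau2, "a_prior": a_prior, "b_prior": b_prior},
            index=batch_levels,
        ),
    )
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), adjusted), model


def variance_filter(expr: ExpressionMatrix, sd_threshold: float) -> ExpressionMatrix:
    """Keep genes whose sample SD (n-1 denominator) is strictly > threshold."""
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be >= 0")
    if expr.n_samples < 2:
        raise ValueError("variance filter needs >= 2 samples")
    sd = expr.values.std(axis=1, ddof=1)
    keep = sd > sd_threshold
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), expr.values[keep])


def center_genes(
    expr: ExpressionMatrix, method: str = "median", scale: str = "none"
) -> ExpressionMatrix:
    """Subtract a per-gene location; optionally rescale each gene to unit SD."""
    if method == "mean":
        loc = expr.values.mean(axis=1, keepdims=True)
    elif method == "median":
        loc = np.median(expr.values, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown centering method {method!r}")
    values = expr.values - loc
    if scale == "unit":
        sd = values.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = values / sd
    elif scale != "none":
        raise ValueError(f"unknown scale option {scale!r}")
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), values)
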