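"""Cohort merging and empirical-Bayes batch adjustment.

Same-platform cohorts are merged on their common genes and per-batch
location/scale effects are removed with the parametric empirical-Bayes
adjustment of the ComBat family: per-gene standardisation by pooled
mean/variance, shrinkage of per-batch gene means toward a normal prior
and of per-batch gene variances toward an inverse-gamma prior (both
priors estimated by method of moments across genes), iterative
conditional refinement of the batch-effect estimates, then
back-transformation.  Downstream scoring is rank-based within a cohort,
so the adjustment mainly matters for merging batches *before* a screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["merge_common_genes", "combat_adjust"]

log = logging.getLogger(__name__)

_ICM_TOL = 1e-6
_ICM_MAXITER = 200


def merge_common_genes(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate cohorts restricted to their common genes.

    Gene order in the result is lexicographic; each sample keeps (or is
    assigned) its source batch label.  Duplicate sample ids across
    sources are an error.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to merge")
    common = matrices[0].gene_ids
    for m in matrices[1:]:
        common = common.intersection(m.gene_ids)
    if len(common) == 0:
        raise ValueError("no genes shared across all matrices")
    common = common.sort_values()

    all_samples = pd.Index([])
    for m in matrices:
        dup = all_samples.intersection(m.sample_ids)
        if len(dup) > 0:
            raise ValueError(f"duplicate sample ids across sources: {dup.tolist()}")
        all_samples = all_samples.append(m.sample_ids)

    blocks, labels = [], []
    for i, m in enumerate(matrices):
        blocks.append(m.values.loc[common])
        bs = m.batch_series()
        if bs is None:
            bs = pd.Series(f"batch{i + 1}", index=m.sample_ids)
        labels.append(bs)
    values = pd.concat(blocks, axis=1)
    batch = pd.concat(labels)
    return ExpressionMatrix(values=values, batch=batch)


def _moments_priors(gamma_hat: np.ndarray, delta_hat_sq: np.ndarray):
    """Method-of-moments hyperparameters for one batch.

    Normal prior N(gbar, t2) on the standardised batch means; inverse
    gamma prior IG(a, b) on the batch variances with a, b matched to the
    mean and variance of the observed per-gene batch variances.
    """
    gbar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    m = delta_hat_sq.mean()
    s2 = delta_hat_sq.var(ddof=1) if delta_hat_sq.size > 1 else 0.0
    if s2 <= 0:
        # all batch variances identical: a flat prior carries no
        # information, so the variance shrinkage step becomes a no-op
        return gbar, t2, None, None
    a = (2.0 * s2 + m * m) / s2
    b = (m * s2 + m ** 3) / s2
    return gbar, t2, a, b


def _icm_solve(sdat: np.ndarray, gamma_hat, delta_hat_sq, gbar, t2, a, b, n_b):
    """Iterated conditional modes for the EB batch-effect posteriors."""
    gamma = gamma_hat.copy()
    delta_sq = delta_hat_sq.copy()
    for _ in range(_ICM_MAXITER):
        if t2 > 0:
            gamma_new = (n_b * t2 * gamma_hat + delta_sq * gbar) / (
                n_b * t2 + delta_sq
            )
        else:
            gamma_new = np.full_like(gamma_hat, gbar)
        if a is None:
            delta_new = delta_hat_sq
        else:
            resid = sdat - gamma_new[:, None]
            ssq = (resid ** 2).sum(axis=1)
            delta_new = (b + 0.5 * ssq) / (n_b / 2.0 + a - 1.0)
        change = max(
            np.abs(gamma_new - gamma).max() if gamma.size else 0.0,
            np.abs(delta_new - delta_sq).max() if delta_sq.size else 0.0,
        )
        gamma, delta_sq = gamma_new, delta_new
        if change < _ICM_TOL:
            break
    return gamma, delta_sq


def combat_adjust(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    A single batch is returned unchanged.  Genes with zero variance
    within some batch get location-only adjustment for that batch
    (logged).  Output keeps gene/sample identity and ordering.
    """
    batch = matrix.batch_series()
    if batch is None:
        raise ValueError("batch labels are required for adjustment")
    levels = batch.unique()
    if len(levels) < 2:
        return ExpressionMatrix(values=matrix.values.copy(), batch=matrix.batch)
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"every batch needs >= 2 samples; too small: {small}")

    X = matrix.values.to_numpy(dtype=float)
    G, n = X.shape
    masks = [(batch == lev).to_numpy() for lev in levels]
    n_bs = np.array([m.sum() for m in masks])

    # per-gene batch means, grand mean, pooled residual variance
    batch_means = np.stack([X[:, m].mean(axis=1) for m in masks], axis=1)
    grand = batch_means @ (n_bs / n)
    fitted = np.zeros_like(X)
    for j, m in enumerate(masks):
        fitted[:, m] = batch_means[:, j][:, None]
    var_pooled = ((X - fitted) ** 2).sum(axis=1) / n
    zero_var = var_pooled <= 0
    if zero_var.any():
        log.warning("batch adjust: %d gene(s) with zero pooled variance "
                    "(location-only)", int(zero_var.sum()))
    sd = np.sqrt(np.where(zero_var, 1.0, var_pooled))

    sdat = (X - grand[:, None]) / sd[:, None]
    out = sdat.copy()
    for j, m in enumerate(masks):
        n_b = int(n_bs[j])
        sub = sdat[:, m]
        gamma_hat = sub.mean(axis=1)
        delta_hat_sq = sub.var(axis=1)  # ddof=0, consistent with var_pooled
        flat = delta_hat_sq <= 0
        if flat.any():
            log.warning(
                "batch adjust: %d gene(s) with zero variance in batch %s "
                "(scale step skipped)", int(flat.sum()), levels[j]
            )
        delta_for_prior = delta_hat_sq[~flat] if (~flat).any() else np.ones(1)
        gbar, t2, a, b = _moments_priors(gamma_hat, delta_for_prior)
        gamma_star, delta_star_sq = _icm_solve(
            sub, gamma_hat, np.where(flat, 1.0, delta_hat_sq), gbar, t2, a, b, n_b
        )
        delta_star_sq = np.where(flat, 1.0, delta_star_sq)
        out[:, m] = (sub - gamma_star[:, None]) / np.sqrt(delta_star_sq)[:, None]

    adjusted = out * sd[:, None] + grand[:, None]
    return ExpressionMatrix(
        values=pd.DataFrame(adjusted, index=matrix.gene_ids,
                            columns=matrix.sample_ids),
        batch=matrix.batch,
    )
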