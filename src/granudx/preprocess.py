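"""Log transformation, median normalization, and parametric ComBat batch adjustment.

The ComBat model treats each (batch, protein) pair as shifting the
standardized expression by a location gamma and inflating its variance by
a scale delta^2.  Per-batch estimates are shrunk across proteins by
parametric empirical Bayes — a normal prior on gamma and an inverse-gamma
prior on delta^2, hyperparameters estimated by method of moments, with the
posterior solved by fixed-point iteration — then the standardized data are
back-transformed.

The adjusted matrix feeds PCA and heatmaps only.  Differential expression
runs on the unadjusted log2 matrix and handles batch by blocking; the
provenance tag on the returned matrix lets that stage refuse adjusted
input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    PROVENANCE_COMBAT,
    SCALE_LINEAR,
    SCALE_LOG2,
    ExpressionMatrix,
    SampleTable,
)

logger = logging.getLogger(__name__)

__all__ = ["log2_transform", "median_normalize", "combat_adjust", "BatchModel"]


def log2_transform(
    matrix: ExpressionMatrix, pseudocount: float = 0.0
) -> ExpressionMatrix:
    """value -> log2(value + pseudocount); missing stays missing."""
    if matrix.scale != SCALE_LINEAR:
        raise ValueError("log2_transform expects a linear-scale matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = matrix.values + pseudocount
    if (shifted <= 0).any().any():
        raise ValueError(
            "value + pseudocount <= 0 encountered; increase the pseudocount"
        )
    return ExpressionMatrix(np.log2(shifted), scale=SCALE_LOG2)


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each sample column so its median equals the global median of medians."""
    if matrix.scale != SCALE_LOG2:
        raise ValueError("median_normalize expects a log2-scale matrix")
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"all-missing sample column(s): {bad}")
    target = float(np.median(medians))
    return ExpressionMatrix(
        matrix.values - (medians - target), scale=SCALE_LOG2,
        provenance=matrix.provenance,
    )


@dataclass
class BatchModel:
    """Fitted ComBat parameters, for inspection and recovery tests."""

    batches: list[str]
    gamma_hat: pd.DataFrame  # batch × protein, raw location estimates
    gamma_star: pd.DataFrame  # batch × protein, EB-shrunk locations
    delta_sq_hat: pd.DataFrame  # batch × protein, raw scale estimates
    delta_sq_star: pd.DataFrame  # batch × protein, EB-shrunk scales
    grand_mean: pd.Series  # per protein
    pooled_var: pd.Series  # per protein
    hyper: pd.DataFrame  # per batch: gamma_bar, tau_sq, a_prior, b_prior
    n_iterations: dict[str, int]
    skipped_proteins: list[str]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-6, max_iter=100):
    """EB fixed-point iteration for one batch (proteins vectorized)."""
    n = np.sum(~np.isnan(sdat), axis=1).astype(float)
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    trace = []
    for it in range(1, max_iter + 1):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        trace.append(change)
        if change < conv:
            return g_new, d_new, it
    raise RuntimeError(
        f"ComBat EB iteration did not converge in {max_iter} steps; "
        f"relative-change trace tail: {trace[-5:]}"
    )


def combat_adjust(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    mode: str = "parametric",
    conv: float = 1e-6,
    max_iter: int = 100,
) -> tuple[ExpressionMatrix, Optional[BatchModel]]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Requires >= 2 batches with >= 2 samples each; a single-batch matrix is
    returned unchanged (no-op).  Proteins with any missing value are passed
    through unadjusted with a warning; no group covariate is used (the
    adjusted matrix serves visualisation, not testing).
    """
    if mode != "parametric":
        raise ValueError("only parametric ComBat is implemented")
    if matrix.scale != SCALE_LOG2:
        raise ValueError("combat_adjust expects a log2-scale matrix")

    batch_of = samples.batch_of().reindex(matrix.sample_ids)
    if batch_of.isna().any():
        missing = batch_of.index[batch_of.isna()].tolist()
        raise ValueError(f"samples missing from the sample table: {missing}")
    batches = sorted(batch_of.unique())
    if len(batches) == 1:
        logger.info("single batch — ComBat is a no-op")
        return (
            ExpressionMatrix(matrix.values.copy(), SCALE_LOG2, PROVENANCE_COMBAT),
            None,
        )
    sizes = batch_of.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(
            f"batch(es) with a single sample: {small.index.tolist()}; "
            "merge them with another batch or exclude the sample"
        )

    complete = matrix.values.dropna(axis=0, how="any")
    skipped = sorted(set(matrix.protein_ids) - set(complete.index))
    if skipped:
        logger.warning(
            "%d proteins with missing values bypass ComBat", len(skipped)
        )

    dat = complete.to_numpy(dtype=float)  # proteins × samples
    n_array = dat.shape[1]
    batch_idx = {b: np.where((batch_of == b).to_numpy())[0] for b in batches}
    n_batches = np.array([len(batch_idx[b]) for b in batches], dtype=float)

    # batch-design least squares, then size-weighted grand mean
    batch_means = np.column_stack(
        [dat[:, batch_idx[b]].mean(axis=1) for b in batches]
    )  # proteins × batches
    grand_mean = batch_means @ (n_batches / n_array)
    fitted = np.empty_like(dat)
    for j, b in enumerate(batches):
        fitted[:, batch_idx[b]] = batch_means[:, [j]]
    pooled_var = np.sum((dat - fitted) ** 2, axis=1) / n_array  # ML divisor
    if np.any(pooled_var <= 0):
        bad = complete.index[pooled_var <= 0].tolist()
        raise ValueError(f"zero pooled variance for proteins {bad[:5]}")

    s_data = (dat - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    gamma_hat = np.column_stack(
        [s_data[:, batch_idx[b]].mean(axis=1) for b in batches]
    )
    delta_sq_hat = np.column_stack(
        [s_data[:, batch_idx[b]].var(axis=1, ddof=1) for b in batches]
    )

    gamma_star = np.empty_like(gamma_hat)
    delta_sq_star = np.empty_like(delta_sq_hat)
    hyper_rows = []
    n_iters = {}
    for j, b in enumerate(batches):
        g = gamma_hat[:, j]
        d = delta_sq_hat[:, j]
        g_bar = g.mean()
        t2 = g.var(ddof=1)
        m, s2 = d.mean(), d.var(ddof=1)
        a_prior = (2.0 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2
        g_star, d_star, it = _it_sol(
            s_data[:, batch_idx[b]], g, d, g_bar, t2, a_prior, b_prior,
            conv=conv, max_iter=max_iter,
        )
        gamma_star[:, j] = g_star
        delta_sq_star[:, j] = d_star
        hyper_rows.append(
            {"batch": b, "gamma_bar": g_bar, "tau_sq": t2,
             "a_prior": a_prior, "b_prior": b_prior}
        )
        n_iters[b] = it

    adjusted = s_data.copy()
    for j, b in enumerate(batches):
        cols = batch_idx[b]
        adjusted[:, cols] = (
            (s_data[:, cols] - gamma_star[:, j][:, None])
            / np.sqrt(delta_sq_star[:, j])[:, None]
        )
    adjusted = adjusted * np.sqrt(pooled_var)[:, None] + grand_mean[:, None]

    out = matrix.values.copy()
    out.loc[complete.index] = adjusted
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat.T, index=batches, columns=complete.index),
        gamma_star=pd.DataFrame(gamma_star.T, index=batches, columns=complete.index),
        delta_sq_hat=pd.DataFrame(
            delta_sq_hat.T, index=batches, columns=complete.index
        ),
        delta_sq_star=pd.DataFrame(
            delta_sq_star.T, index=batches, columns=complete.index
        ),
        grand_mean=pd.Series(grand_mean, index=complete.index),
        pooled_var=pd.Series(pooled_var, index=complete.index),
        hyper=pd.DataFrame(hyper_rows).set_index("batch"),
        n_iterations=n_iters,
        skipped_proteins=skipped,
    )
    return ExpressionMatrix(out, SCALE_LOG2, PROVENANCE_COMBAT), model
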