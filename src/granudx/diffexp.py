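"""Batch-blocked differential protein expression with empirical-Bayes moderation.

Per protein, an ordinary least-squares model ``log2 value ~ group + batch``
is fitted over the case and reference samples (batch as a blocking factor
with treatment coding, largest batch as reference).  Residual variances are
then shrunk across proteins toward a scaled inverse-chi-square prior whose
hyperparameters (d0 prior degrees of freedom, s0^2 prior scale) are
estimated by moment matching on log s^2 — the standard moderated-t
procedure.  The moderated statistic

    t_p = beta_p / (s_tilde_p * sqrt(v_p)),   s_tilde^2 = (d0 s0^2 + d s^2)/(d0 + d)

is referred to a t distribution on d + d0 degrees of freedom; p-values are
Benjamini-Hochberg adjusted, and a protein is called significant when
adjusted p < 0.01 and |log2FC| > 1 (absolute fold change > 2).

Only proteins supported by at least ``min_peptides`` (default 2) peptides
are tested, and the input matrix must be the raw log2 matrix — a
ComBat-adjusted matrix is refused, since blocking already handles batch
and adjusting first would distort the error model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import (
    PROVENANCE_COMBAT,
    SCALE_LOG2,
    ExpressionMatrix,
    PeptideSupport,
    SampleTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "EBayesParams",
    "ProteinFits",
    "fit_protein_models",
    "ebayes_squeeze",
    "moderated_t_test",
    "bh_adjust",
    "run_differential_expression",
    "classify_and_summarize",
    "compare_signatures",
    "fold_change_phrase",
]


@dataclass
class DesignSpec:
    """Contrast and blocking specification for one DE run."""

    case: str
    reference: str = "healthy"
    blocking: tuple[str, ...] = ("batch",)
    min_peptides: int = 2

    def __post_init__(self) -> None:
        if self.case == self.reference:
            raise ValueError("case and reference groups must differ")


@dataclass
class EBayesParams:
    d0: float  # prior degrees of freedom, may be inf
    s0sq: float  # prior variance scale

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0sq > 0):
            raise ValueError("s0sq must be positive")


@dataclass
class ProteinFits:
    """Per-protein OLS summaries for the contrast."""

    coef: pd.Series  # log2FC case - reference
    s2: pd.Series  # residual variance
    df: pd.Series  # residual degrees of freedom
    leverage: float  # contrast variance factor v = [(X'X)^-1]_cc
    n_case: int
    n_ref: int
    excluded: dict[str, str] = field(default_factory=dict)


def _design_matrix(groups: pd.Series, batches: pd.Series, case: str):
    """Intercept + case indicator + batch treatment dummies (largest batch ref)."""
    n = len(groups)
    cols = ["intercept", f"group[{case}]"]
    X = [np.ones(n), (groups == case).to_numpy(dtype=float)]
    ref_batch = batches.value_counts().idxmax()
    for b in sorted(set(batches) - {ref_batch}):
        cols.append(f"batch[{b}]")
        X.append((batches == b).to_numpy(dtype=float))
    X = np.column_stack(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns from the QR diagonal
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        aliased = [cols[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased or 'batch confounded with group'}"
        )
    return X, cols


def fit_protein_models(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    design: DesignSpec,
    peptides: Optional[PeptideSupport] = None,
) -> ProteinFits:
    """OLS per protein on group + batch covariates; complete cases per protein.

    Proteins failing the peptide-support filter or left with non-positive
    residual degrees of freedom are excluded and recorded.
    """
    if matrix.scale != SCALE_LOG2:
        raise ValueError("fit_protein_models expects a log2-scale matrix")
    if matrix.provenance == PROVENANCE_COMBAT:
        raise ValueError(
            "differential expression must run on the unadjusted log2 matrix; "
            "batch is handled by blocking, not ComBat"
        )
    meta = samples.data.set_index("sample_id")
    use = meta.index[meta["group"].isin([design.case, design.reference])]
    use = [s for s in matrix.sample_ids if s in set(use)]
    groups = meta.loc[use, "group"]
    batches = meta.loc[use, "batch"]
    n_case = int((groups == design.case).sum())
    n_ref = int((groups == design.reference).sum())
    if n_case == 0 or n_ref == 0:
        raise ValueError("both contrast groups must be non-empty")

    excluded: dict[str, str] = {}
    protein_ids = list(matrix.protein_ids)
    if peptides is not None:
        kept = []
        for p in protein_ids:
            if peptides.get(p, 0) < design.min_peptides:
                excluded[p] = f"peptide support < {design.min_peptides}"
            else:
                kept.append(p)
        protein_ids = kept

    Y = matrix.values.loc[protein_ids, use].to_numpy(dtype=float)
    X, _cols = _design_matrix(groups, batches, design.case)
    k = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    v = float(xtx_inv[1, 1])

    complete = ~np.isnan(Y).any(axis=1)
    coef = np.full(len(protein_ids), np.nan)
    s2 = np.full(len(protein_ids), np.nan)
    df = np.full(len(protein_ids), np.nan)

    if complete.any():
        Yc = Y[complete]
        B = xtx_inv @ X.T @ Yc.T  # k × proteins
        resid = Yc.T - X @ B
        d = len(use) - k
        coef[complete] = B[1]
        s2[complete] = np.sum(resid ** 2, axis=0) / d
        df[complete] = d

    # proteins with missing values: refit on their observed samples
    for i in np.where(~complete)[0]:
        mask = ~np.isnan(Y[i])
        if mask.sum() < k + 1:
            excluded[protein_ids[i]] = "too few complete observations"
            continue
        gi, bi = groups[mask], batches[mask]
        if (gi == design.case).sum() == 0 or (gi == design.reference).sum() == 0:
            excluded[protein_ids[i]] = "a contrast group is empty after missingness"
            continue
        try:
            Xi, _ = _design_matrix(gi, bi, design.case)
        except ValueError:
            excluded[protein_ids[i]] = "rank-deficient design after missingness"
            continue
        beta, res, rank, _ = np.linalg.lstsq(Xi, Y[i, mask], rcond=None)
        d_i = mask.sum() - Xi.shape[1]
        if d_i <= 0:
            excluded[protein_ids[i]] = "non-positive residual df"
            continue
        coef[i] = beta[1]
        rss = float(np.sum((Y[i, mask] - Xi @ beta) ** 2))
        s2[i] = rss / d_i
        df[i] = d_i

    ok = ~np.isnan(df)
    idx = pd.Index([p for p, o in zip(protein_ids, ok) if o], name="protein_id")
    return ProteinFits(
        coef=pd.Series(coef[ok], index=idx, name="log2FC"),
        s2=pd.Series(s2[ok], index=idx, name="s2"),
        df=pd.Series(df[ok], index=idx, name="df"),
        leverage=v,
        n_case=n_case,
        n_ref=n_ref,
        excluded=excluded,
    )


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = np.where(x > 1e7, 1.0 / np.sqrt(x), 0.5 + 1.0 / x)
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-10:
            break
    return y


def ebayes_squeeze(
    s2: Sequence[float], df: Sequence[float]
) -> tuple[EBayesParams, pd.Series]:
    """Estimate the variance prior and return posterior (moderated) variances.

    Moment matching on log s^2: with s^2 ~ s0^2 F(d, d0), the residuals
    e = log s^2 - digamma(d/2) + log(d/2) have variance trigamma(d0/2) +
    trigamma(d/2), so the excess variance of e identifies d0 via the
    trigamma inverse and the mean identifies s0^2.  A non-positive excess
    yields d0 = inf (all moderated variances equal s0^2).  Zero sample
    variances are excluded from estimation and assigned s0^2 afterward.
    """
    s2 = pd.Series(s2, dtype=float)
    df = pd.Series(np.broadcast_to(np.asarray(df, dtype=float), len(s2)),
                   index=s2.index)
    if (df < 1).any():
        raise ValueError("residual df must be >= 1")
    positive = s2 > 0
    if positive.sum() < 10:
        raise ValueError(
            "fewer than 10 proteins with positive residual variance; "
            "prior hyperparameters are unidentifiable"
        )
    s2p, dp = s2[positive].to_numpy(), df[positive].to_numpy()
    z = np.log(s2p)
    e = z - special.digamma(dp / 2.0) + np.log(dp / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, dp / 2.0))
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    params = EBayesParams(d0=d0, s0sq=s0sq)

    if np.isinf(d0):
        post = pd.Series(s0sq, index=s2.index)
    else:
        post = (d0 * s0sq + df * s2) / (d0 + df)
        post[~positive] = s0sq  # degenerate fits take the prior scale
    post.name = "s2_post"
    return params, post


def moderated_t_test(
    coef: Sequence[float],
    s2_post: Sequence[float],
    leverage: float,
    df: Sequence[float],
    d0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values.

    ``d0 = 0`` reduces to the ordinary t-test on the unmoderated variances;
    ``d0 = inf`` gives a fixed-variance z-test.
    """
    if leverage <= 0:
        raise ValueError("contrast leverage must be positive")
    coef = np.asarray(coef, dtype=float)
    s2_post = np.asarray(s2_post, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), coef.shape)
    se = np.sqrt(s2_post * leverage)
    t = coef / se
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    return t, p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_differential_expression(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    design: DesignSpec,
    peptides: Optional[PeptideSupport] = None,
    padj_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
    gene_symbols: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """End-to-end DE: OLS fits -> variance moderation -> moderated t -> BH.

    Returns a DataFrame indexed by protein with columns gene, log2FC, t, p,
    padj, significant, n_case, n_ref, n_peptides.  ``significant`` is
    adjusted p < ``padj_threshold`` AND |log2FC| > ``lfc_threshold``.
    """
    fits = fit_protein_models(matrix, samples, design, peptides)
    params, s2_post = ebayes_squeeze(fits.s2, fits.df)
    t, p = moderated_t_test(
        fits.coef.to_numpy(),
        s2_post.to_numpy(),
        fits.leverage,
        fits.df.to_numpy(),
        params.d0,
    )
    padj = bh_adjust(p)
    res = pd.DataFrame(
        {
            "log2FC": fits.coef,
            "t": t,
            "p": p,
            "padj": padj,
            "significant": (padj < padj_threshold)
            & (np.abs(fits.coef) > lfc_threshold),
            "n_case": fits.n_case,
            "n_ref": fits.n_ref,
        },
        index=fits.coef.index,
    )
    if peptides is not None:
        res["n_peptides"] = [peptides.get(pid) for pid in res.index]
    if gene_symbols is not None:
        res.insert(0, "gene", [gene_symbols.get(pid, pid) for pid in res.index])
    res.attrs["ebayes"] = params
    res.attrs["excluded"] = fits.excluded
    return res


def classify_and_summarize(
    result: pd.DataFrame,
    mean_log10_copies: Optional[pd.Series] = None,
    top_k: int = 6,
) -> dict:
    """Count significant under/over-expressed proteins and build the top-k panel.

    The panel holds the ``top_k`` most significant proteins (smallest
    adjusted p) ordered by decreasing mean log10 copy number, mirroring the
    per-disease summary panels.
    """
    sig = result[result["significant"]]
    n_under = int((sig["log2FC"] < 0).sum())
    n_over = int((sig["log2FC"] > 0).sum())
    top = sig.nsmallest(top_k, "padj")
    if mean_log10_copies is not None and len(top):
        key = mean_log10_copies.reindex(top.index)
        top = top.assign(mean_log10_copies=key).sort_values(
            "mean_log10_copies", ascending=False
        )
    return {"n_under": n_under, "n_over": n_over, "panel": top}


def compare_signatures(named_sets: Mapping[str, set]) -> dict[tuple[str, ...], set]:
    """Exact membership partition of the union of named DE sets.

    Keys are sorted tuples of the set names containing each element (the
    regions of a Venn diagram); values are the member sets.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 named sets to compare")
    partition: dict[tuple[str, ...], set] = {}
    union = set().union(*named_sets.values())
    for member in union:
        key = tuple(sorted(name for name, s in named_sets.items() if member in s))
        partition.setdefault(key, set()).add(member)
    return partition


def fold_change_phrase(log2fc: float) -> str:
    """Human-readable fold change: 'down-regulated 84-fold' for log2FC = -6.39."""
    fold = 2.0 ** abs(log2fc)
    direction = "down-regulated" if log2fc < 0 else "up-regulated"
    return f"{direction} {fold:.1f}-fold"
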