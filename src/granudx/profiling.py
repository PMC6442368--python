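"""Cohort-level descriptive analytics.

PCA of expression profiles, replicate-correlation QC, TPM computation from
RNA counts with exon-union lengths, protein–mRNA correlation, the
healthy-referenced z-score heatmap matrix with Euclidean hierarchical
clustering, and hypergeometric gene-set over-representation against the
quantified background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import (
    SCALE_LOG2,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "pca_profiles",
    "replicate_correlation",
    "tpm_from_counts",
    "protein_rna_correlation",
    "zscore_vs_healthy",
    "ora_enrichment",
]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples × components
    variance_fractions: np.ndarray  # per component, non-increasing
    n_proteins_used: int
    n_proteins_dropped: int


def pca_profiles(
    matrix: ExpressionMatrix, n_components: Optional[int] = None
) -> PcaResult:
    """Sample scores from the SVD of the protein-centered log2 matrix.

    Rows (proteins) with any missing value are dropped (count reported);
    each protein is centered across samples; sample scores are the right
    singular vectors scaled by singular values, variance fractions the
    normalized squared singular values.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    complete = matrix.values.dropna(axis=0, how="any")
    dropped = matrix.shape[0] - complete.shape[0]
    X = complete.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(10, len(s))
    scores = pd.DataFrame(
        (vt[:k] * s[:k, None]).T,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var_frac = (s ** 2 / np.sum(s ** 2))[:k]
    return PcaResult(scores, var_frac, complete.shape[0], dropped)


def replicate_correlation(
    matrix: ExpressionMatrix,
    samples: Optional[SampleTable] = None,
    subject: Optional[str] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, float]:
    """All pairwise Pearson coefficients among one subject's samples, plus mean.

    Pass either a sample table and subject id, or an explicit list of
    sample ids.  Correlations are computed on shared observed log2 values.
    """
    if sample_ids is None:
        if samples is None or subject is None:
            raise ValueError("need sample_ids, or a sample table and subject")
        sample_ids = samples.samples_for_subject(subject)
    sample_ids = list(sample_ids)
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples for replicate correlation")
    sub = matrix.values[sample_ids]
    table = pd.DataFrame(np.eye(len(sample_ids)), index=sample_ids, columns=sample_ids)
    pcc = []
    for a, b in combinations(sample_ids, 2):
        pair = sub[[a, b]].dropna()
        r = float(np.corrcoef(pair[a], pair[b])[0, 1])
        table.loc[a, b] = table.loc[b, a] = r
        pcc.append(r)
    return table, float(np.mean(pcc))


def tpm_from_counts(
    counts: Sequence[float], exon_union_lengths: Sequence[float]
) -> np.ndarray:
    """Transcripts per million from read counts and exon-union lengths (bp)."""
    c = np.asarray(counts, dtype=float)
    ln = np.asarray(exon_union_lengths, dtype=float)
    if np.any(ln <= 0):
        raise ValueError("exon-union lengths must be positive")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("all-zero counts")
    rate = c / ln
    return 1.0e6 * rate / rate.sum()


def protein_rna_correlation(
    protein_per_gene: pd.Series, tpm_per_gene: pd.Series, log: bool = True
) -> tuple[float, int]:
    """Pearson r between per-gene protein and RNA summaries on shared genes.

    Both summaries (typically medians over samples) are log2-transformed by
    default; genes missing or non-positive on either side are dropped.
    Needs at least 10 shared genes.
    """
    shared = protein_per_gene.index.intersection(tpm_per_gene.index)
    a = protein_per_gene[shared].astype(float)
    b = tpm_per_gene[shared].astype(float)
    ok = (a > 0) & (b > 0) & a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if len(a) < 10:
        raise ValueError(f"only {len(a)} shared genes with positive values (<10)")
    if log:
        a, b = np.log2(a), np.log2(b)
    r = float(np.corrcoef(a, b)[0, 1])
    return r, int(len(a))


def zscore_vs_healthy(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    healthy_group: str = "healthy",
    linkage_method: str = "average",
) -> dict:
    """Healthy-referenced z-score matrix with Euclidean hierarchical clustering.

    Step 1: per protein, subtract the healthy-group mean.  Step 2: per
    sample, z-transform the column (mean 0, sd 1).  Both axes are then
    clustered agglomeratively on Euclidean distance (linkage method
    selectable; average/UPGMA by default).  Returns the transformed
    matrix, leaf orders, and the two linkage trees.
    """
    healthy = [
        s for s in samples.samples_in_group(healthy_group) if s in matrix.sample_ids
    ]
    if not healthy:
        raise ValueError(f"no samples in group {healthy_group!r}")
    complete = matrix.values.dropna(axis=0, how="any")
    centered = complete.sub(complete[healthy].mean(axis=1), axis=0)
    sd = centered.std(axis=0, ddof=0)
    zero_sd = sd.index[sd == 0].tolist()
    if zero_sd:
        raise ValueError(
            f"zero column standard deviation for sample(s) {zero_sd}; "
            "a column identical to the healthy mean cannot be z-transformed"
        )
    z = centered.sub(centered.mean(axis=0), axis=1).div(sd, axis=1)

    row_link = hierarchy.linkage(z.to_numpy(), method=linkage_method, metric="euclidean")
    col_link = hierarchy.linkage(
        z.to_numpy().T, method=linkage_method, metric="euclidean"
    )
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    return {
        "zscores": z,
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_link,
        "col_linkage": col_link,
    }


def ora_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    min_overlap: int = 2,
    ease: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of gene sets.

    The foreground (e.g. significantly changed proteins) must be a subset
    of the background (all quantified proteins); each gene set is first
    intersected with the background.  ``ease=True`` applies the
    conservative EASE-style overlap-1 penalty.  P-values are BH-adjusted
    across the tested sets; sets with overlap below ``min_overlap`` are
    reported untested (NaN p).
    """
    from .diffexp import bh_adjust

    fg = set(foreground)
    bg = set(background)
    stray = fg - bg
    if stray:
        raise ValueError(f"foreground genes missing from background: {sorted(stray)[:10]}")
    rows = []
    for name in sets:
        desc, members = sets.sets[name]
        in_bg = set(members) & bg
        overlap = fg & in_bg
        k = len(overlap)
        if len(in_bg) == 0 or k < min_overlap:
            p = np.nan
        else:
            k_eff = max(k - 1, 0) if ease else k
            p = float(
                stats.hypergeom.sf(k_eff - 1, len(bg), len(in_bg), len(fg))
            )
        rows.append(
            {
                "set": name,
                "description": desc,
                "overlap": k,
                "set_size_in_background": len(in_bg),
                "foreground_size": len(fg),
                "background_size": len(bg),
                "p": p,
                "members": ";".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    tested = out["p"].notna()
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out.sort_values("p", na_position="last")
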