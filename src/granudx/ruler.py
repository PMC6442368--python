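"""Histone-anchored absolute copy-number estimation (the "proteomic ruler").

Every cell of a diploid human carries a near-constant mass of DNA
(~6.5 pg) and histones are stoichiometric with DNA, so the summed MS
signal of histone proteins in a sample is a built-in standard: the total
histone intensity corresponds to ~6.5 pg of protein mass per cell.  Each
protein's intensity is converted to mass per cell by that ratio and to
copies per cell via its molar mass:

    mass_p   = dna_mass_per_cell * I_p / sum(I_histones)
    copies_p = mass_p * N_A / MW_p

The module also provides the descriptive profiling used on copy numbers:
the ranked cumulative-abundance curve (how few proteins hold half the
proteome) and per-protein coefficients of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import SCALE_LINEAR, ExpressionMatrix, ProteinAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "RulerConstants",
    "default_histone_symbols",
    "copies_per_cell",
    "cumulative_abundance",
    "n_to_fraction",
    "abundance_cv",
    "mean_log10_copies",
]

AVOGADRO = 6.02214076e23  # / mol
DNA_MASS_DIPLOID_HUMAN = 6.5e-12  # grams per cell


def default_histone_symbols() -> frozenset[str]:
    """Histone gene symbols shipped with the package (H1/H2A/H2B/H3/H4 families)."""
    text = (
        resources.files("granudx").joinpath("data/histone_genes.txt").read_text()
    )
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass
class RulerConstants:
    avogadro: float = AVOGADRO
    dna_mass_per_cell: float = DNA_MASS_DIPLOID_HUMAN  # grams
    histone_symbols: frozenset[str] = field(default_factory=default_histone_symbols)

    def __post_init__(self) -> None:
        if self.dna_mass_per_cell <= 0:
            raise ValueError("dna_mass_per_cell must be positive")
        if not self.histone_symbols:
            raise ValueError("histone symbol list must be non-empty")


def copies_per_cell(
    matrix: ExpressionMatrix,
    annotations: Mapping[str, ProteinAnnotation],
    constants: Optional[RulerConstants] = None,
) -> ExpressionMatrix:
    """Convert linear intensities to estimated protein copies per cell.

    Per sample, total histone intensity is equated with ``dna_mass_per_cell``
    grams of protein; each protein's intensity share of that anchor gives
    its mass per cell, divided by molar mass for copy number.  Proteins
    without a molecular weight are omitted (logged).  A sample with zero
    total histone signal is an error.
    """
    if matrix.scale != SCALE_LINEAR:
        raise ValueError("copies_per_cell requires a linear-scale matrix")
    constants = constants or RulerConstants()

    histone_ids = [
        p
        for p in matrix.protein_ids
        if p in annotations
        and (
            annotations[p].is_histone
            or annotations[p].gene_symbol in constants.histone_symbols
        )
    ]
    if not histone_ids:
        raise ValueError("no histone proteins found in the matrix")

    with_mw = [
        p
        for p in matrix.protein_ids
        if p in annotations and annotations[p].molecular_weight is not None
    ]
    missing = sorted(set(matrix.protein_ids) - set(with_mw))
    if missing:
        logger.warning(
            "omitting %d proteins without molecular weight (first: %s)",
            len(missing),
            missing[:5],
        )

    histone_sum = matrix.values.loc[histone_ids].sum(axis=0, skipna=True)
    zero = histone_sum[histone_sum <= 0]
    if len(zero):
        raise ValueError(
            f"zero total histone signal in sample(s): {zero.index.tolist()}"
        )

    mw = pd.Series(
        {p: annotations[p].molecular_weight for p in with_mw}, dtype=float
    )
    intensities = matrix.values.loc[with_mw]
    mass = intensities.div(histone_sum, axis=1) * constants.dna_mass_per_cell
    copies = mass.mul(constants.avogadro / mw, axis=0)
    return ExpressionMatrix(copies, scale=SCALE_LINEAR, provenance="copies-per-cell")


def cumulative_abundance(values: Sequence[float]) -> pd.DataFrame:
    """Ranked cumulative-fraction curve of a non-negative abundance vector.

    Returns a DataFrame with columns ``rank`` (1-based, by descending
    abundance), ``value`` and ``cumulative_fraction`` (non-decreasing,
    ending at 1).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("need a non-empty 1-d abundance vector")
    if np.any(v < 0):
        raise ValueError("abundances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    order = np.argsort(-v, kind="stable")
    sorted_v = v[order]
    frac = np.cumsum(sorted_v) / total
    return pd.DataFrame(
        {
            "rank": np.arange(1, v.size + 1),
            "value": sorted_v,
            "cumulative_fraction": frac,
        }
    )


def n_to_fraction(values: Sequence[float], fraction: float) -> int:
    """Smallest number of top-abundance proteins whose share reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    curve = cumulative_abundance(values)
    idx = np.searchsorted(curve["cumulative_fraction"].to_numpy(), fraction)
    return int(idx) + 1


def abundance_cv(
    matrix: ExpressionMatrix, sample_ids: Optional[Iterable[str]] = None
) -> pd.Series:
    """Per-protein coefficient of variation (%) on linear values.

    Uses the unbiased (n-1) standard deviation; proteins with zero mean get
    NaN (CV undefined).
    """
    if matrix.scale != SCALE_LINEAR:
        raise ValueError("abundance_cv expects linear-scale values")
    sub = matrix.values if sample_ids is None else matrix.values[list(sample_ids)]
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples for a CV")
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    cv[mean == 0] = np.nan
    cv.name = "cv_percent"
    return cv


def mean_log10_copies(
    copies: ExpressionMatrix, sample_ids: Iterable[str]
) -> pd.Series:
    """Mean over the given samples of log10 copy number, per protein.

    This is the ordering key for "top differentially expressed protein"
    panels; zero copies are treated as missing for the log.
    """
    sub = copies.values[list(sample_ids)]
    logged = np.log10(sub.where(sub > 0))
    out = logged.mean(axis=1)
    out.name = "mean_log10_copies"
    return out
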