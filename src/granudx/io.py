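"""Readers and writers for the tabular and sequence formats the pipeline touches.

Matrices and metadata travel as UTF-8 TSV ("." decimal), protein sequences
as FASTA, gene sets as GMT, reports as JSON.  Contaminant entries produced
by upstream search engines (MaxQuant-style ``CON__`` accessions by default)
are dropped at read time.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight as _bio_mw

from .containers import (
    SCALE_LINEAR,
    SCALE_LOG2,
    ExpressionMatrix,
    GeneSetCollection,
    PeptideSupport,
    ProteinAnnotation,
    SampleTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_peptide_support",
    "write_peptide_support",
    "read_fasta_annotations",
    "read_annotation_table",
    "write_annotation_table",
    "read_gene_sets",
    "DEFAULT_CONTAMINANT_PATTERN",
    "protein_mw_from_sequence",
]

DEFAULT_CONTAMINANT_PATTERN = r"^CON__"

PathLike = Union[str, Path]


def read_expression_matrix(
    path: PathLike,
    scale: str = SCALE_LINEAR,
    contaminant_pattern: Optional[str] = DEFAULT_CONTAMINANT_PATTERN,
) -> ExpressionMatrix:
    """Read a protein × sample TSV (first column protein ids, header sample ids).

    Rows whose protein id matches ``contaminant_pattern`` are dropped (pass
    ``None`` to keep everything).  Empty cells become NaN.  Duplicated ids,
    non-numeric cells, and negative values under ``scale="linear"`` are hard
    errors.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dup_cols = sorted({c for c in header if c in seen or seen.add(c)})
    if dup_cols:
        raise ValueError(f"duplicate sample ids in {path}: {dup_cols}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids in {path}: {dups}")

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (df[col].str.strip() != "") & converted.isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric cell at protein {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        numeric[col] = converted

    if contaminant_pattern:
        pat = re.compile(contaminant_pattern)
        keep = ~numeric.index.to_series().str.contains(pat)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d contaminant rows from %s", n_dropped, path)
        numeric = numeric.loc[keep]

    return ExpressionMatrix(numeric, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_sample_table(
    path: PathLike, group_vocabulary: Optional[frozenset[str]] = None
) -> SampleTable:
    """Read per-sample metadata; requires sample_id, group, batch columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in SampleTable.REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{col} required in sample table {path}")
    if "timepoint" in df.columns:
        df["timepoint"] = pd.to_numeric(df["timepoint"], errors="coerce")
    return SampleTable(df, group_vocabulary=group_vocabulary)


def write_sample_table(samples: SampleTable, path: PathLike) -> None:
    samples.data.to_csv(path, sep="\t", index=False, na_rep="")


def read_peptide_support(path: PathLike) -> PeptideSupport:
    """TSV with columns protein_id, n_peptides."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns or "n_peptides" not in df.columns:
        raise ValueError(f"{path}: need columns protein_id, n_peptides")
    return PeptideSupport(dict(zip(df["protein_id"], df["n_peptides"].astype(int))))


def write_peptide_support(peptides: PeptideSupport, path: PathLike) -> None:
    pd.DataFrame(
        {"protein_id": list(peptides), "n_peptides": list(peptides.values())}
    ).to_csv(path, sep="\t", index=False)


# --- FASTA annotations -------------------------------------------------------

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|")
_GENE_FIELD = re.compile(r"GN=(\S+)")


def protein_mw_from_sequence(sequence: str, on_nonstandard: str = "skip") -> float:
    """Average molecular weight (Da) of a protein from its sequence.

    Nonstandard residues are skipped with a warning by default
    (``on_nonstandard="error"`` raises instead).
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    try:
        return float(_bio_mw(seq, seq_type="protein", monoisotopic=False))
    except ValueError:
        if on_nonstandard == "error":
            raise
        standard = set("ACDEFGHIKLMNPQRSTVWY")
        cleaned = "".join(c for c in seq if c in standard)
        dropped = len(seq) - len(cleaned)
        logger.warning("skipped %d nonstandard residues", dropped)
        if not cleaned:
            raise ValueError("sequence has no standard residues")
        return float(_bio_mw(cleaned, seq_type="protein", monoisotopic=False))


def read_fasta_annotations(
    path: PathLike,
    histone_symbols: Optional[frozenset[str]] = None,
    on_nonstandard: str = "skip",
) -> dict[str, ProteinAnnotation]:
    """Parse a protein FASTA into per-protein annotations.

    Accession and gene symbol are taken from UniProt-style headers
    (``sp|ACC|NAME ... GN=SYMBOL``); plain headers use the first token as
    accession.  Unparseable headers get a synthetic id with a warning.
    Molecular weight is the water-adjusted sum of average residue masses.
    """
    from .ruler import default_histone_symbols

    if histone_symbols is None:
        histone_symbols = default_histone_symbols()
    annotations: dict[str, ProteinAnnotation] = {}
    for i, record in enumerate(SeqIO.parse(str(path), "fasta")):
        header = record.description
        m = _UNIPROT_HEADER.match(record.id)
        if m:
            acc = m.group("acc")
        elif record.id:
            acc = record.id.split("|")[0]
        else:
            acc = f"UNKNOWN_{i}"
            logger.warning("unparseable FASTA header %r; using %s", header, acc)
        gm = _GENE_FIELD.search(header)
        gene = gm.group(1) if gm else acc
        seq = str(record.seq)
        mw = protein_mw_from_sequence(seq, on_nonstandard=on_nonstandard)
        annotations[acc] = ProteinAnnotation(
            protein_id=acc,
            gene_symbol=gene,
            molecular_weight=mw,
            is_histone=gene in histone_symbols,
            sequence=seq,
        )
    return annotations


def read_annotation_table(path: PathLike) -> dict[str, ProteinAnnotation]:
    """TSV with columns protein_id, gene_symbol, molecular_weight, is_histone."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_symbol": str})
    out = {}
    for row in df.itertuples(index=False):
        mw = getattr(row, "molecular_weight", None)
        out[row.protein_id] = ProteinAnnotation(
            protein_id=row.protein_id,
            gene_symbol=row.gene_symbol,
            molecular_weight=None if mw is None or np.isnan(mw) else float(mw),
            is_histone=bool(getattr(row, "is_histone", False)),
        )
    return out


def write_annotation_table(
    annotations: dict[str, ProteinAnnotation], path: PathLike
) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "gene_symbol": a.gene_symbol,
                "molecular_weight": a.molecular_weight,
                "is_histone": a.is_histone,
            }
            for a in annotations.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member TAB member ...

    Lines with fewer than three fields are skipped with a warning; members
    are de-duplicated within each set, preserving order.
    """
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: fewer than 3 fields, skipped", path, lineno)
                continue
            name, desc, *members = fields
            collection.add(name, desc, members)
    return collection
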