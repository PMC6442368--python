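"""Batch-blocked moderated-t differential expression, disease vs healthy.

Fits per-protein linear models (group + processing-date batch), moderates
the residual variances with an empirical-Bayes prior, and calls proteins
significant at BH-adjusted p < 0.01 with |fold change| > 2 — then compares
the disease signatures as a Venn-style partition.
"""

import numpy as np

from granudx import (
    CohortConfig,
    DesignSpec,
    classify_and_summarize,
    compare_signatures,
    generate_cohort,
    log2_transform,
    run_differential_expression,
)
from granudx.diffexp import fold_change_phrase

cohort = generate_cohort(CohortConfig(seed=2))
log2 = log2_transform(cohort.matrix)
genes = {p: a.gene_symbol for p, a in cohort.annotations.items()}

de_sets = {}
for disease in ("SCN-ELANE", "CGD", "LAD"):
    res = run_differential_expression(
        log2, cohort.samples, DesignSpec(case=disease), cohort.peptides,
        gene_symbols=genes,
    )
    summary = classify_and_summarize(res)
    eb = res.attrs["ebayes"]
    print(f"{disease}: {summary['n_under']} under- / {summary['n_over']} "
          f"overexpressed (prior df d0={eb.d0:.1f}, scale s0^2={eb.s0sq:.3f})")
    sig = res[res["significant"]].nsmallest(2, "padj")
    for pid, row in sig.iterrows():
        print(f"  {row['gene']:<8} {fold_change_phrase(row['log2FC'])}"
              f"  padj={row['padj']:.1e}")
    de_sets[disease] = set(res.index[res["significant"]])

partition = compare_signatures(de_sets)
print("\nDE-set overlap (Venn regions):")
for names, members in sorted(partition.items()):
    print(f"  {' & '.join(names)}: {len(members)} proteins")
print("\nLow overlap between diseases means each signature is specific — "
      "the basis for proteome-guided diagnosis.")
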