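"""Proteomic-ruler copy numbers and the extreme concentration of the proteome.

The summed histone MS signal in each sample is anchored to the ~6.5 pg of
DNA in a diploid cell, converting relative intensities to absolute copies
per cell.  Granulocyte proteomes are extremely top-heavy: a handful of
proteins holds half of all protein copies.
"""

import numpy as np

from granudx import (
    CohortConfig,
    abundance_cv,
    copies_per_cell,
    cumulative_abundance,
    generate_cohort,
    n_to_fraction,
)

cohort = generate_cohort(CohortConfig(seed=3))
copies = copies_per_cell(cohort.matrix, cohort.annotations)
healthy = cohort.samples.samples_in_group("healthy")
mean_copies = copies.values[healthy].mean(axis=1)

print(f"copy numbers estimated for {copies.shape[0]} proteins "
      f"across {copies.shape[1]} samples")
print(f"dynamic range: {np.log10(mean_copies.max() / mean_copies.min()):.1f} "
      "orders of magnitude")

k = n_to_fraction(mean_copies.to_numpy(), 0.5)
print(f"proteins holding 50% of all copies: {k}")

curve = cumulative_abundance(mean_copies.to_numpy())
print("cumulative share after top 1/10/100 proteins: "
      + ", ".join(f"{curve['cumulative_fraction'].iloc[i - 1]:.2f}"
                  for i in (1, 10, 100)))

cv = abundance_cv(cohort.matrix, healthy)
print(f"median CV across healthy donors: {cv.median():.0f}%")
print("\nCopies per cell put fold changes on an absolute scale: a protein "
      "at 1e7 copies halving is a different clinical signal than one at "
      "1e3 copies halving.")
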