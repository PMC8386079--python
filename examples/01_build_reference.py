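"""Build a deconvolution signature from a labelled single-cell dataset.

Generates a small synthetic multi-subject dataset, builds the reference
(per-type relative abundances averaged across subjects with outlier
exclusion, cross-subject variances, cell sizes) and prints a summary.
"""

import numpy as np

from dcap import OutlierConfig, SynthConfig, build_reference, generate_synthetic_sc

sc = generate_synthetic_sc(
    SynthConfig(n_genes=200, n_cell_types=4, n_subjects=3, random_seed=0)
)
print(f"single-cell dataset: {sc.n_genes} genes x {sc.n_cells} cells, "
      f"{len(sc.subjects)} subjects, {len(sc.cell_types)} cell types")

ref = build_reference(sc, theta_config=OutlierConfig(rho="auto"),
                      size_config=OutlierConfig(rho="auto"))

print(f"cell sizes S^k (avg molecules/cell): {np.round(ref.cell_size, 1)}")
print(f"theta columns sum to {ref.theta_avg.sum(axis=0).round(6)}")
print(f"design matrix X = S * theta, shape {ref.design_matrix.shape}, "
      f"column means {ref.design_matrix.mean(axis=0).round(3)}")
print(f"median cross-subject variance per type: "
      f"{np.median(ref.var_matrix, axis=0)}")
# Each design column is the expected expression contributed by one average
# cell of that type; the variance matrix says how trustworthy each gene is.
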