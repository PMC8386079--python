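# Methods

## Problem and model

Bulk RNA-seq measures the summed expression of all cells in a tissue.
Given a labelled single-cell reference from the same tissue type, the
package estimates the per-sample cell-type proportions `p` (non-negative,
summing to 1) under the mixture model

    y_g = Σ_k p_k X_gk + ε_g,       ε_g ~ N(0, δ_g²)

where `X_gk = S^k θ_gk` is the expected expression of gene `g` contributed
by one average cell of type `k`: `θ_gk` is the type's relative abundance
profile (molecule fractions, columns summing to 1) and `S^k` the average
molecules per cell. Two error sources are treated on an equal footing:

1. bulk measurement noise, variance `δ_g²`, and
2. reference error — the same cell type expresses genes differently in
   different subjects, captured by the cross-subject variance
   `v_gk² = Var_j[θ_jg^k]`.

Propagating both through the mixture gives the per-gene reciprocal weight

    1/w_g = n + C² δ_g² + C² Σ_k p_k² (S^k)² v_gk²

used in a weighted non-negative least-squares fit of `√w ⊙ y` on
`√w ⊙ X`. Genes with stable reference expression (information genes) get
the largest weights.

## Identifiability and the scale constants

The model's scale adjustment `C` (introduced so proportions can sum to 1)
and the tissue's total cell count are not identifiable from a single bulk
profile. Both are absorbed by (a) dividing the bulk vector by its total
(relative abundance) and (b) renormalising the NNLS coefficients onto the
simplex; equivalently `C = 1` throughout. A consequence is that results are
invariant to any positive rescaling of the bulk sample (tested).

## Iteration

`δ_g²` is unobservable, so the fit alternates:

0. optionally normalise the bulk vector to relative abundance (default on);
   drop genes with all-zero reference rows (no signal, degenerate weights);
1. unweighted NNLS fit, coefficients renormalised → p⁽⁰⁾;
2. per-gene squared residuals of the current fit → δ̂_g²;
3. weights from p of the *previous* iteration and δ̂²;
4. NNLS on the √w-scaled system, renormalise → p⁽ᵗ⁺¹⁾;
5. stop when `max_k |p⁽ᵗ⁺¹⁾ − p⁽ᵗ⁾| < tol` (max-norm chosen over a summed
   norm: it bounds every cell type's movement) or when `t+1 = max_iter`.

Defaults: `n = 1e−4` (keeps weights finite when both variance terms
vanish; any value ≪ typical 1/w changes results negligibly), `tol = 1e−6`,
`max_iter = 100`. In the noise-free limit the residuals are zero, the
weights are flat, and the first weighted solve reproduces the unweighted
one — convergence in one iteration, exact recovery.

The non-negative solves use scipy's Lawson–Hanson active-set
implementation; the test suite cross-checks its objective values against an
exact enumeration over all candidate supports (every subset of ≤ 4
columns), which is a global optimum certificate independent of the solver.

## Outlier exclusion when averaging across subjects

Per (gene, type) — and per type for cell sizes — the across-subject values
are clustered on the number line, the centre is the centroid of the largest
cluster (ties towards the smaller centroid), and values at distance ≥ ρ
from the centre are excluded before taking the mean. Design choices:

- **Exact 1-D k-means.** In one dimension the optimal clusters are
  contiguous in sorted order, so the global optimum is found by dynamic
  programming over split points. This replaces randomized Lloyd iterations:
  it is deterministic (no seed sensitivity), exact, and fast enough to run
  per (gene, type). The `random_seed` config field is retained only for
  provenance records.
- **n_clusters = 2 by default** — one "typical" cluster plus one potential
  outlier cluster; `n_clusters = 1` degenerates to mean-centred
  thresholding. Capped at the number of distinct values.
- **ρ selection.** A fixed numeric ρ is the reproducible path used in
  tests. `rho="auto"` grid-searches multiples {1, 1.5, 2, 3, 5} of the
  values' median absolute deviation (falling back to the mean absolute
  deviation when the MAD is zero) and keeps the smallest threshold
  retaining ≥ 50 % of values — a declared heuristic, not a canonical rule.
  If a threshold would exclude everything, all values are kept (a warning
  is logged); an empty average is never produced.
- **Variance before exclusion.** `v_gk²` is the population variance
  (divide by J) over the unfiltered per-subject values; a single
  contributing subject gives 0. `variance_after_exclusion=True` recomputes
  it post-filtering as a sensitivity analysis.
- Exclusion is applied per (gene, type) value set independently, not per
  subject globally.

Note that averaging kept values per gene means the averaged θ columns are
no longer exactly normalised (sums land within a few percent of 1); the
downstream fit is unaffected because coefficients are renormalised anyway.

## Synthetic data generator

`generate_synthetic_sc` emulates the structure the model assumes: per-type
base profiles drawn from a symmetric Dirichlet (concentration 0.5 by
default — sparse, cell-type-specific profiles typical of marker-driven
expression); per-subject multiplicative log-normal perturbation
(`cross_subject_sd`, default 0.2; 0.5 in the weighting benchmarks to give
substantial inter-individual variability) renormalised to the simplex;
per-type cell sizes uniform in 500–2000 molecules; per-cell totals Poisson
around the type's size (floored at 1); per-cell counts multinomial. The
multinomial is the simplest generative model under which the
molecule-fraction definition of θ is exact in expectation (verified by a
law-of-large-numbers test against the generator's stored base profiles).

What it does **not** emulate: dropout/zero inflation, UMI saturation,
batch effects, ambient RNA, or realistic gene-gene correlation. Passing
tests therefore demonstrate correctness of the estimator under its own
modelling assumptions, not robustness to platform artifacts.

Bulk simulation is `y = Xp + ε` with Gaussian noise clipped at zero —
either homoscedastic or, via `reference_linked_noise_sd`, heteroscedastic
with `sd_g = sqrt(Σ_k p_k² (S^k)² v_gk²)`, the model's own variance
structure. Pseudo-bulk construction simply sums each subject's cell columns
(raw counts, no depth normalisation) and records label counts as truth.

## Problem sizes used in the shipped checks

Exact-recovery: G = 1000, K = 6, J = 5, 20 mixtures. Solver cross-check:
50 instances, K ≤ 4, G ≤ 50. Weighting benefit: 100 replicates (5
independent references × 20 noise/proportion draws) at G = 300, K = 5,
J = 4, `cross_subject_sd = 0.5`, unit-scale reference-linked noise. These
sizes make the whole suite run in seconds while leaving the qualitative
conclusions stable across seeds.

## Known limitations

- Bulk input scale (counts/CPM/TPM) is not prescribed; because the bulk
  vector is normalised and coefficients renormalised, any per-sample
  positive scaling is equivalent. Gene-length-dependent transforms (TPM vs
  counts) are *not* equivalent and should match between bulk and reference.
- Cell types with identical design columns are not identifiable; the split
  between them is arbitrary (a warning is emitted).
- The residual-based δ̂² estimate conflates model misfit with measurement
  noise; genes poorly described by the mixture are downweighted even if
  precisely measured.
- Proportions are of *cells*, derived via the cell-size scaling; if cell
  sizes are badly estimated (few cells, extreme outliers), proportions
  inherit that bias.
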