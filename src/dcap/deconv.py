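"""Iteratively re-weighted non-negative least squares deconvolution.

A bulk sample's expression is modelled as a non-negative mixture of the
reference's per-type expression columns, observed with gene-level noise.
Two error sources enter the per-gene weight: the bulk measurement variance
δ_g² (unknown, estimated from the squared residuals of the current fit) and
the propagated cross-subject reference variance Σ_k p_k² S_k'² v_gk². With
both on the same footing the reciprocal weight is

    1 / w_g = n + δ_g² + Σ_k p_k² S_k'² v_gk²

where the small offset n keeps weights finite when both error terms vanish.
The proportion-dependent weight makes the problem non-linear, so the fit
starts from an unweighted non-negative least squares solution and
alternates weight updates with weighted solves until the proportions stop
moving or an iteration cap is reached.

The overall scale of the bulk sample and the total cell count of the tissue
are not identifiable from proportions alone; both are absorbed by
normalising the bulk vector to relative abundance and renormalising the
solved coefficients onto the simplex (equivalently, the model's scale
adjustment C is fixed at 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from dcap.data_model import BulkDataset
from dcap.errors import DegenerateGroupError, ValidationError
from dcap.reference import ReferenceModel

logger = logging.getLogger("dcap")


@dataclass
class DeconvConfig:
    """Iteration settings.

    n_offset : small positive stabiliser in the reciprocal weight (keeps
        weights finite when residual and reference variance are both zero).
    tol : convergence threshold on the max absolute change in proportions
        between successive iterations.
    max_iter : iteration cap; the second stopping condition.
    normalize_bulk : divide each bulk vector by its total before fitting,
        making the result invariant to sequencing depth.
    """

    n_offset: float = 1e-4
    tol: float = 1e-6
    max_iter: int = 100
    nonneg_solver: str = "active_set"
    normalize_bulk: bool = True

    def __post_init__(self) -> None:
        if self.n_offset <= 0:
            raise ValidationError("n_offset must be > 0")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.nonneg_solver != "active_set":
            raise ValidationError(f"unknown solver {self.nonneg_solver!r}")


@dataclass
class WeightState:
    """Per-gene weights and the variance components behind them."""

    weights: np.ndarray
    residual_var: np.ndarray
    scale: float = 1.0


@dataclass
class DeconvolutionResult:
    """Per-sample cell-type proportions with convergence diagnostics."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    n_iter: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)  # per-sample final gene weights
    raw_coefficients: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)  # sample -> reason

    def write(self, path, float_format: str = "%.6f") -> None:
        self.proportions.to_csv(path, sep="\t", float_format=float_format)


def nnls(design: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Non-negative least squares via the Lawson–Hanson active-set method:
    returns the KKT-optimal coefficient vector with all entries >= 0."""
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    if design.ndim != 2 or design.shape[1] < 1:
        raise ValidationError("design must be a 2-D matrix with >= 1 column")
    if design.shape[0] != target.size:
        raise ValidationError(
            f"design rows {design.shape[0]} != target length {target.size}"
        )
    if not design.any():
        raise DegenerateGroupError("design matrix is entirely zero")
    coef, _ = scipy.optimize.nnls(design, target)
    return coef


def compute_weights(
    proportions: np.ndarray,
    cell_size: np.ndarray,
    var_matrix: np.ndarray,
    residual_var: np.ndarray,
    scale: float = 1.0,
    n_offset: float = 1e-4,
) -> np.ndarray:
    """Per-gene weights from the two-part variance model.

    1/w_g = n + C²·δ_g² + C²·Σ_k p_k² S_k'² v_gk², with C fixed at 1 by
    default. Larger residuals or less stable reference genes get smaller
    weight.
    """
    if n_offset < 0:
        raise ValidationError("n_offset must be >= 0")
    p = np.asarray(proportions, dtype=float)
    s = np.asarray(cell_size, dtype=float)
    v = np.asarray(var_matrix, dtype=float)
    d = np.asarray(residual_var, dtype=float)
    ref_term = v @ (p**2 * s**2)
    inv_w = n_offset + scale**2 * d + scale**2 * ref_term
    return 1.0 / inv_w


def _check_duplicate_columns(design: np.ndarray) -> None:
    _, counts = np.unique(design.round(12), axis=1, return_counts=True)
    if (counts > 1).any():
        logger.warning(
            "design matrix has identical columns; the split between those "
            "cell types is not identifiable"
        )


def deconvolve_sample(
    bulk_vector: np.ndarray,
    ref: ReferenceModel,
    config: DeconvConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Estimate one sample's cell-type proportions.

    Returns ``(proportions, diagnostics)`` where diagnostics carries the
    iteration count, convergence flag, final per-gene weights and the raw
    (pre-normalisation) coefficients. Genes with zero expression across all
    reference cell types are dropped from the fit — they carry no signal
    and would make the weights degenerate.
    """
    config = config or DeconvConfig()
    y = np.asarray(bulk_vector, dtype=float).ravel()
    if y.size != ref.n_genes:
        raise ValidationError(
            f"bulk vector length {y.size} != reference genes {ref.n_genes}"
        )
    if not y.any():
        raise DegenerateGroupError("bulk vector is entirely zero")

    keep = ref.design_matrix.any(axis=1)
    X = ref.design_matrix[keep, :]
    V = ref.var_matrix[keep, :]
    y = y[keep]
    _check_duplicate_columns(X)
    if config.normalize_bulk:
        total = y.sum()
        if total <= 0:
            raise DegenerateGroupError("bulk vector sums to zero on reference genes")
        y = y / total

    coef = nnls(X, y)
    if coef.sum() <= 0:
        raise DegenerateGroupError(
            "initial non-negative fit is all-zero; bulk carries no reference signal"
        )
    p = coef / coef.sum()

    n_iter, converged = 0, False
    weights = np.full(y.size, 1.0 / config.n_offset)
    for n_iter in range(1, config.max_iter + 1):
        residual = y - X @ coef
        residual_var = residual**2
        weights = compute_weights(
            p, ref.cell_size, V, residual_var, scale=1.0, n_offset=config.n_offset
        )
        sw = np.sqrt(weights)
        coef = nnls(sw[:, None] * X, sw * y)
        if coef.sum() <= 0:
            logger.warning("weighted fit collapsed to zero; keeping previous estimate")
            converged = True
            break
        p_new = coef / coef.sum()
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < config.tol:
            converged = True
            break

    diagnostics = {
        "n_iter": n_iter,
        "converged": converged,
        "weights": weights,
        "raw_coefficients": coef,
        "scale": 1.0,
    }
    return p, diagnostics


def deconvolve(
    bulk: BulkDataset,
    ref: ReferenceModel,
    config: DeconvConfig | None = None,
) -> DeconvolutionResult:
    """Deconvolve every bulk sample independently and assemble the results.

    A sample that fails (e.g. all-zero expression) yields an all-NaN row
    with the reason logged; the remaining samples are unaffected.
    """
    config = config or DeconvConfig()
    return _deconvolve_many(bulk, ref, lambda y: deconvolve_sample(y, ref, config))


def deconvolve_baseline_nnls(
    bulk: BulkDataset, ref: ReferenceModel
) -> DeconvolutionResult:
    """Unweighted NNLS baseline: a single non-negative fit per sample,
    normalised to the simplex. The comparison point for the weighted model."""

    def one(y: np.ndarray) -> tuple[np.ndarray, dict]:
        y = np.asarray(y, dtype=float).ravel()
        if not y.any():
            raise DegenerateGroupError("bulk vector is entirely zero")
        keep = ref.design_matrix.any(axis=1)
        total = y[keep].sum()
        if total <= 0:
            raise DegenerateGroupError("bulk vector sums to zero on reference genes")
        coef = nnls(ref.design_matrix[keep, :], y[keep] / total)
        if coef.sum() <= 0:
            raise DegenerateGroupError("non-negative fit is all-zero")
        return coef / coef.sum(), {
            "n_iter": 1,
            "converged": True,
            "weights": np.ones(int(keep.sum())),
            "raw_coefficients": coef,
            "scale": 1.0,
        }

    return _deconvolve_many(bulk, ref, one)


def _deconvolve_many(bulk: BulkDataset, ref: ReferenceModel, solve) -> DeconvolutionResult:
    if bulk.n_samples == 0:
        raise ValidationError("bulk dataset has no samples")
    if bulk.gene_ids != ref.gene_ids:
        raise ValidationError(
            "bulk and reference gene spaces differ; run harmonize_genes first"
        )
    K = ref.n_cell_types
    rows = np.full((bulk.n_samples, K), np.nan)
    result = DeconvolutionResult(
        proportions=pd.DataFrame(
            rows,
            index=pd.Index(bulk.sample_ids, name="sample_id"),
            columns=[str(c) for c in ref.cell_types],
        )
    )
    for i, sample in enumerate(bulk.sample_ids):
        try:
            p, diag = solve(bulk.expression[:, i])
        except Exception as exc:  # isolate per-sample failures
            logger.warning("sample %s failed: %s", sample, exc)
            result.failures[sample] = str(exc)
            result.converged[sample] = False
            continue
        result.proportions.iloc[i, :] = p
        result.n_iter[sample] = diag["n_iter"]
        result.converged[sample] = diag["converged"]
        result.weights[sample] = diag["weights"]
        result.raw_coefficients[sample] = diag["raw_coefficients"]
    return result
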