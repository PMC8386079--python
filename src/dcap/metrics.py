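"""Evaluation metrics for predicted versus true proportion matrices.

All three summaries pool over every (sample, cell type) entry, giving one
number per method; a per-cell-type breakdown of absolute differences is
reported alongside for diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from dcap.errors import ValidationError


def _aligned(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pred, pd.DataFrame) and isinstance(truth, pd.DataFrame):
        if set(pred.columns) == set(truth.columns) and set(pred.index) == set(truth.index):
            truth = truth.loc[pred.index, pred.columns]
    a = np.asarray(pred, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite entries in proportion matrices")
    return a.ravel(), b.ravel()


def rmsd(pred, truth) -> float:
    """Root-mean-square deviation between predicted and true proportions,
    pooled over all entries."""
    a, b = _aligned(pred, truth)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mad(pred, truth) -> float:
    """Mean absolute difference between predicted and true proportions."""
    a, b = _aligned(pred, truth)
    return float(np.mean(np.abs(a - b)))


def pearson_r(pred, truth) -> float:
    """Pearson correlation between predicted and true proportions, pooled
    over all entries: cov(pred, truth) / (sd(pred) · sd(truth))."""
    a, b = _aligned(pred, truth)
    if a.size < 2 or np.var(a) == 0 or np.var(b) == 0:
        raise ValidationError("correlation undefined: an input has zero variance")
    return float(scipy.stats.pearsonr(a, b).statistic)


@dataclass
class EvaluationReport:
    """Pooled summary metrics plus a per-cell-type error breakdown."""

    rmsd: float
    mad: float
    pearson_r: float
    per_cell_type: pd.Series = field(default_factory=pd.Series)

    def to_dict(self) -> dict:
        return {
            "rmsd": self.rmsd,
            "mad": self.mad,
            "pearson_r": self.pearson_r,
            "per_cell_type_mad": {str(k): float(v) for k, v in self.per_cell_type.items()},
        }


def evaluate(pred: pd.DataFrame, truth: pd.DataFrame) -> EvaluationReport:
    """Full evaluation of a predicted proportion matrix against ground
    truth (both samples × cell types, matching labels)."""
    if isinstance(pred, pd.DataFrame) and isinstance(truth, pd.DataFrame):
        common = [c for c in pred.columns if c in set(truth.columns)]
        if len(common) != pred.shape[1] or len(common) != truth.shape[1]:
            raise ValidationError("predicted and true cell-type sets differ")
        truth = truth.loc[pred.index, common]
        pred = pred[common]
        breakdown = (pred - truth).abs().mean(axis=0)
    else:
        breakdown = pd.Series(dtype=float)
    return EvaluationReport(
        rmsd=rmsd(pred, truth),
        mad=mad(pred, truth),
        pearson_r=pearson_r(pred, truth),
        per_cell_type=breakdown,
    )
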