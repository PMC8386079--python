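"""Simulation: pseudo-bulk from labelled single cells, and fully synthetic
single-cell datasets with controlled cross-subject variation.

Pseudo-bulk merges all cells of one subject into one bulk sample by summing
counts, recording the per-type cell counts as ground-truth proportions —
the standard way to benchmark deconvolution without paired bulk data.

The synthetic generator emulates the statistical structure the weighted
model assumes: each cell type has a base relative-abundance profile over
genes (Dirichlet-distributed, so sparsity is tunable via the
concentration); each subject perturbs it multiplicatively (log-normal
noise, renormalised), creating genuine cross-subject variance in theta;
per-cell molecule totals are Poisson around a per-type cell size; and
individual cell counts are multinomial draws from the subject- and
type-specific profile — the simplest generative model under which the
molecule-fraction definition of relative abundance is exact in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcap.data_model import BulkDataset, SingleCellDataset
from dcap.errors import ValidationError
from dcap.reference import ReferenceModel

logger = logging.getLogger("dcap")


@dataclass
class SimulationTruth:
    """Simulated bulk samples with their ground-truth composition."""

    bulk: BulkDataset
    proportions_true: pd.DataFrame  # samples x cell types, rows sum to 1
    cell_counts: pd.DataFrame | None = None  # m_j^k where applicable

    def __post_init__(self) -> None:
        sums = self.proportions_true.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("ground-truth proportion rows must sum to 1")


@dataclass
class SynthConfig:
    """Knobs of the synthetic single-cell generator.

    cells_per_group : inclusive (low, high) range of cells drawn per
        (subject, type) group.
    concentration : Dirichlet concentration of the base profiles; smaller
        values give sparser, more cell-type-specific profiles.
    cross_subject_sd : sd of the log-normal perturbation applied per
        subject, the source of cross-subject reference variance v_gk².
    cell_size_range : inclusive range of the per-type mean molecules per
        cell S^k.
    bulk_noise_sd : default measurement-noise sd for downstream bulk
        generation (recorded here so one config describes a whole study).
    """

    n_genes: int = 200
    n_cell_types: int = 4
    n_subjects: int = 3
    cells_per_group: tuple[int, int] = (20, 40)
    concentration: float = 0.5
    cross_subject_sd: float = 0.2
    cell_size_range: tuple[float, float] = (500.0, 2000.0)
    bulk_noise_sd: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cell_types, self.n_subjects) < 1:
            raise ValidationError("counts must be >= 1")
        if self.cells_per_group[0] < 1 or self.cells_per_group[0] > self.cells_per_group[1]:
            raise ValidationError("cells_per_group must be a valid range with low >= 1")
        if self.cross_subject_sd < 0 or self.bulk_noise_sd < 0:
            raise ValidationError("noise sds must be >= 0")
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")


def make_pseudobulk(sc: SingleCellDataset) -> SimulationTruth:
    """One bulk sample per subject: the row-wise sum of that subject's cell
    columns, with ground truth = per-type cell counts / total cells."""
    subjects = sc.subjects
    cell_types = sc.cell_types
    cols, counts = [], []
    kept_subjects = []
    for j in subjects:
        mask = (sc.cell_meta["subject_id"] == j).to_numpy()
        if not mask.any():
            logger.warning("subject %r has no cells; skipped", j)
            continue
        cols.append(sc.counts[:, mask].sum(axis=1))
        types = sc.cell_meta.loc[mask, "cell_type"]
        counts.append([int((types == k).sum()) for k in cell_types])
        kept_subjects.append(str(j))
    bulk = BulkDataset(
        expression=np.column_stack(cols),
        gene_ids=list(sc.gene_ids),
        sample_ids=kept_subjects,
    )
    cc = pd.DataFrame(
        counts, index=pd.Index(kept_subjects, name="sample_id"),
        columns=[str(k) for k in cell_types],
    )
    props = cc.div(cc.sum(axis=1), axis=0)
    return SimulationTruth(bulk=bulk, proportions_true=props, cell_counts=cc)


@dataclass
class _SynthGroundTruth:
    """Generator-side truth stored for law-of-large-numbers checks."""

    base_profiles: np.ndarray  # G x K
    subject_profiles: np.ndarray  # J x G x K
    cell_sizes: np.ndarray  # K


_last_truth: _SynthGroundTruth | None = None


def last_generator_truth() -> _SynthGroundTruth | None:
    """Ground truth (base and per-subject profiles) of the most recent
    :func:`generate_synthetic_sc` call, for validation against empirical
    estimates."""
    return _last_truth


def generate_synthetic_sc(config: SynthConfig) -> SingleCellDataset:
    """Draw a labelled multi-subject single-cell count matrix.

    Fully reproducible from ``config.random_seed``; the generator's own
    base profiles are retrievable via :func:`last_generator_truth`.
    """
    global _last_truth
    rng = np.random.default_rng(config.random_seed)
    G, K, J = config.n_genes, config.n_cell_types, config.n_subjects
    base = rng.dirichlet(np.full(G, config.concentration), size=K).T  # G x K
    sizes = rng.uniform(*config.cell_size_range, size=K)

    subject_profiles = np.empty((J, G, K))
    for j in range(J):
        noise = rng.lognormal(mean=0.0, sigma=config.cross_subject_sd, size=(G, K)) \
            if config.cross_subject_sd > 0 else np.ones((G, K))
        perturbed = base * noise
        subject_profiles[j] = perturbed / perturbed.sum(axis=0, keepdims=True)

    lo, hi = config.cells_per_group
    columns, meta_rows = [], []
    cell_idx = 0
    for j in range(J):
        for k in range(K):
            n_cells = int(rng.integers(lo, hi + 1))
            theta = subject_profiles[j, :, k]
            totals = rng.poisson(sizes[k], size=n_cells)
            totals = np.maximum(totals, 1)  # a cell always has >= 1 molecule
            for t in totals:
                columns.append(rng.multinomial(int(t), theta))
                meta_rows.append(
                    {
                        "cell_id": f"cell{cell_idx:05d}",
                        "subject_id": f"subject{j}",
                        "cell_type": f"type{k}",
                    }
                )
                cell_idx += 1
    counts = np.column_stack(columns).astype(float)
    sc = SingleCellDataset(
        counts=counts,
        gene_ids=[f"gene{g:05d}" for g in range(G)],
        cell_meta=pd.DataFrame(meta_rows),
    )
    _last_truth = _SynthGroundTruth(
        base_profiles=base, subject_profiles=subject_profiles, cell_sizes=sizes
    )
    return sc


def reference_linked_noise_sd(
    ref: ReferenceModel, proportions: np.ndarray, scale: float = 1.0
) -> np.ndarray:
    """Per-gene noise sd following the model's own variance structure:
    sd_g = scale · sqrt(Σ_k p_k² S_k'² v_gk²). Genes whose reference
    expression varies more across subjects are noisier — the regime the
    weighted fit is built for."""
    p = np.asarray(proportions, dtype=float).ravel()
    var = ref.var_matrix @ (p**2 * ref.cell_size**2)
    return scale * np.sqrt(var)


def generate_noisy_bulk(
    ref: ReferenceModel,
    proportions: np.ndarray,
    noise_sd,
    seed: int | None = None,
) -> SimulationTruth:
    """Bulk samples y_j = Σ_k p_jk X_·k + ε_j with Gaussian noise clipped
    at zero.

    ``noise_sd`` is a scalar (homoscedastic), a length-G vector, or a
    samples × G matrix of per-gene standard deviations.
    """
    p = np.atleast_2d(np.asarray(proportions, dtype=float))
    if p.shape[1] != ref.n_cell_types:
        raise ValidationError(
            f"proportions have {p.shape[1]} columns, reference has "
            f"{ref.n_cell_types} cell types"
        )
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("proportion rows must sum to 1")
    sd = np.asarray(noise_sd, dtype=float)
    if (sd < 0).any():
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = p @ ref.design_matrix.T  # samples x G
    if sd.ndim == 0:
        noise = rng.normal(0.0, 1.0, size=clean.shape) * float(sd)
    elif sd.ndim == 1:
        noise = rng.normal(0.0, 1.0, size=clean.shape) * sd[np.newaxis, :]
    else:
        noise = rng.normal(0.0, 1.0, size=clean.shape) * sd
    expr = np.clip(clean + noise, 0.0, None)
    sample_ids = [f"sim{s}" for s in range(p.shape[0])]
    bulk = BulkDataset(
        expression=expr.T, gene_ids=list(ref.gene_ids), sample_ids=sample_ids
    )
    props = pd.DataFrame(
        p, index=pd.Index(sample_ids, name="sample_id"),
        columns=[str(c) for c in ref.cell_types],
    )
    return SimulationTruth(bulk=bulk, proportions_true=props)
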