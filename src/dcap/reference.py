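"""Build the deconvolution signature from labelled single-cell counts.

For each subject j and cell type k the reference records

* the relative abundance ``theta[j, g, k]`` — the fraction of the group's
  total mRNA molecules carried by gene g (columns sum to 1 over genes),
* the cell size ``S[j, k]`` — average total molecules per cell of type k.

Across subjects, per-(gene, type) values are averaged after a k-means-based
outlier exclusion (values far from the dominant cluster's centre are
dropped), the cross-subject variance v_gk² of theta is retained as the
reference-error component of the deconvolution weights, and the design
matrix is the product X_gk = S^k' · theta_gk' — the expected expression of
gene g contributed by one average cell of type k.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dcap.data_model import CellTypeIndexSet, SingleCellDataset
from dcap.errors import DegenerateGroupError, MissingGroupError, ValidationError

logger = logging.getLogger("dcap")

#: multiples of the robust scale tried when the distance threshold is "auto"
DEFAULT_RHO_GRID = (1.0, 1.5, 2.0, 3.0, 5.0)


@dataclass
class OutlierConfig:
    """Settings for the k-means outlier exclusion applied before averaging.

    ``rho`` is the distance threshold (in the units of the clustered values)
    around the dominant cluster's centre; values at or beyond it are treated
    as outliers. ``"auto"`` grid-searches multiples of the values' robust
    scale (median absolute deviation, falling back to the mean absolute
    deviation when the MAD is zero) and keeps the smallest threshold
    retaining at least half of the values. ``random_seed`` is recorded for
    provenance; the 1-D clustering itself is solved exactly and needs no
    randomness.
    """

    n_clusters: int = 2
    rho: float | str = "auto"
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if isinstance(self.rho, str):
            if self.rho != "auto":
                raise ValidationError(f"rho must be positive or 'auto', got {self.rho!r}")
            if not self.rho_grid:
                raise ValidationError("rho_grid must be non-empty when rho='auto'")
        elif self.rho <= 0:
            raise ValidationError("rho must be > 0")


def _kmeans_1d(values: np.ndarray, n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D k-means: optimal clusters are contiguous in sorted order,
    so dynamic programming over split positions minimises the within-cluster
    sum of squares globally. Returns (centroids, cluster sizes)."""
    v = np.sort(values)
    n = len(v)
    k = min(n_clusters, len(np.unique(v)))
    if k == 1:
        return np.array([v.mean()]), np.array([n])
    # prefix sums for O(1) segment SSE
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(i: int, j: int) -> float:  # segment v[i:j]
        s, s2, m = c1[j] - c1[i], c2[j] - c2[i], j - i
        return s2 - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for q in range(1, k + 1):
        for j in range(q, n + 1):
            best, arg = INF, q - 1
            for i in range(q - 1, j):
                c = cost[q - 1, i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cost[q, j], back[q, j] = best, arg
    bounds = [n]
    for q in range(k, 0, -1):
        bounds.append(back[q, bounds[-1]])
    bounds = bounds[::-1]
    centroids = np.array([v[bounds[q] : bounds[q + 1]].mean() for q in range(k)])
    sizes = np.diff(bounds)
    return centroids, np.asarray(sizes)


def _cluster_center(values: np.ndarray, n_clusters: int) -> float:
    """Centre point of the dominant cluster (largest; ties broken towards
    the smallest centroid)."""
    centroids, sizes = _kmeans_1d(values, n_clusters)
    order = np.lexsort((centroids, -sizes))  # biggest cluster, then smallest centre
    return float(centroids[order[0]])


def _auto_rho(values: np.ndarray, center: float, config: OutlierConfig) -> float:
    med = np.median(values)
    scale = float(np.median(np.abs(values - med)))
    if scale == 0.0:
        scale = float(np.mean(np.abs(values - med)))
    if scale == 0.0:  # all values identical
        return np.inf
    for mult in sorted(config.rho_grid):
        rho = mult * scale
        if np.mean(np.abs(values - center) < rho) >= 0.5:
            return rho
    return sorted(config.rho_grid)[-1] * scale


def exclude_outliers(
    values, config: OutlierConfig | None = None
) -> tuple[np.ndarray, float]:
    """Drop values far from the dominant cluster's centre.

    All values are clustered on the number line with 1-D k-means; the centre
    point is the centroid of the largest cluster and values with
    ``|v - centre| >= rho`` are excluded. If exclusion would remove
    everything, the full input is returned with a warning — an empty average
    is never produced.

    Returns ``(kept_values, centre)``.
    """
    config = config or OutlierConfig()
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("cannot exclude outliers from an empty value set")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite values passed to outlier exclusion")
    center = _cluster_center(v, config.n_clusters)
    rho = _auto_rho(v, center, config) if config.rho == "auto" else float(config.rho)
    kept = v[np.abs(v - center) < rho]
    if kept.size == 0:
        logger.warning(
            "outlier threshold %.4g would exclude all %d values; keeping all", rho, v.size
        )
        kept = v
    return kept, center


def relative_abundance(
    sc: SingleCellDataset, idx: CellTypeIndexSet, subject, cell_type
) -> np.ndarray:
    """Per-gene relative abundance theta_jg^k for one (subject, type) group:
    the group's molecules of gene g divided by the group's total molecules.
    Sums to 1 over genes."""
    if (subject, cell_type) not in idx:
        raise MissingGroupError(f"no cells for subject {subject!r}, type {cell_type!r}")
    cols = idx.indices(subject, cell_type)
    gene_totals = sc.counts[:, cols].sum(axis=1)
    total = gene_totals.sum()
    if total <= 0:
        raise DegenerateGroupError(
            f"all-zero counts for subject {subject!r}, type {cell_type!r}"
        )
    return gene_totals / total


def cell_size(
    sc: SingleCellDataset, idx: CellTypeIndexSet, subject, cell_type
) -> float:
    """Average total mRNA molecules per cell, S_j^k, for one group."""
    if (subject, cell_type) not in idx:
        raise MissingGroupError(f"no cells for subject {subject!r}, type {cell_type!r}")
    cols = idx.indices(subject, cell_type)
    return float(sc.counts[:, cols].sum() / len(cols))


def _robust_mean(vals: np.ndarray, config: OutlierConfig) -> float:
    # cheap exits: a single value, or (numeric rho) a spread already inside
    # the threshold — the centre lies within [min, max], so nothing can be
    # excluded and the mean is the answer
    if vals.size == 1:
        return float(vals[0])
    if vals.max() == vals.min():
        return float(vals[0])
    if not isinstance(config.rho, str) and vals.max() - vals.min() < config.rho:
        return float(vals.mean())
    kept, _ = exclude_outliers(vals, config)
    return float(kept.mean())


def average_abundance(
    per_subject_theta: np.ndarray, config: OutlierConfig | None = None
) -> np.ndarray:
    """Outlier-robust across-subject average of relative abundances.

    ``per_subject_theta`` is a J × G × K tensor with NaN marking subjects
    that lack a cell type. For each (gene, type) the across-subject values
    are passed through :func:`exclude_outliers` and the mean of the kept
    values is returned (G × K).
    """
    config = config or OutlierConfig()
    theta = np.asarray(per_subject_theta, dtype=float)
    J, G, K = theta.shape
    out = np.empty((G, K))
    for k in range(K):
        block = theta[:, :, k]  # J x G
        present = ~np.isnan(block[:, 0])
        if not present.any():
            raise MissingGroupError(f"cell type index {k} present in no subject")
        vals = block[present, :]
        for g in range(G):
            out[g, k] = _robust_mean(vals[:, g], config)
    return out


def cross_subject_variance(per_subject_theta: np.ndarray) -> np.ndarray:
    """Population variance over subjects of theta_jg^k, per (gene, type);
    zero when a single subject contributes. This is the v_gk² term of the
    deconvolution weights: genes stable across subjects (information genes)
    get small variance and hence large weight."""
    theta = np.asarray(per_subject_theta, dtype=float)
    if np.isnan(theta).all(axis=0).any():
        raise MissingGroupError("some (gene, type) has no contributing subject")
    with np.errstate(invalid="ignore"):
        var = np.nanvar(theta, axis=0, ddof=0)
    return np.nan_to_num(var, nan=0.0)


def average_cell_size(
    per_subject_sizes: np.ndarray, config: OutlierConfig | None = None
) -> np.ndarray:
    """Outlier-robust across-subject average cell size per type.

    ``per_subject_sizes`` is J × K with NaN for absent (subject, type)
    pairs. Same exclusion rule as :func:`average_abundance`, with the
    threshold interpreted in molecule units (rho_s rather than rho_theta).
    """
    config = config or OutlierConfig()
    sizes = np.asarray(per_subject_sizes, dtype=float)
    J, K = sizes.shape
    out = np.empty(K)
    for k in range(K):
        vals = sizes[~np.isnan(sizes[:, k]), k]
        if vals.size == 0:
            raise MissingGroupError(f"cell type index {k} present in no subject")
        out[k] = _robust_mean(vals, config)
    return out


@dataclass
class ReferenceModel:
    """The deconvolution signature built from a single-cell dataset."""

    theta_avg: np.ndarray  # G x K, outlier-robust average relative abundance
    var_matrix: np.ndarray  # G x K, cross-subject variance v_gk^2
    cell_size: np.ndarray  # K, average molecules per cell S^k'
    design_matrix: np.ndarray  # G x K, X_gk = S^k' * theta_gk'
    cell_types: list
    gene_ids: list[str]
    subjects: list = field(default_factory=list)
    per_subject_theta: np.ndarray | None = None  # J x G x K, NaN = absent
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        G, K = len(self.gene_ids), len(self.cell_types)
        for name in ("theta_avg", "var_matrix", "design_matrix"):
            arr = getattr(self, name)
            if arr.shape != (G, K):
                raise ValidationError(f"{name} shape {arr.shape} != ({G}, {K})")
            if arr.size and np.nanmin(arr) < 0:
                raise ValidationError(f"{name} has negative entries")
        if self.cell_size.shape != (K,) or (self.cell_size < 0).any():
            raise ValidationError("cell_size must be a non-negative length-K vector")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def save(self, directory: str | Path) -> None:
        """Serialise as a directory of TSVs plus a JSON sidecar with the
        build configuration."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        idx = pd.Index(self.gene_ids, name="gene_id")
        cols = [str(c) for c in self.cell_types]
        pd.DataFrame(self.theta_avg, index=idx, columns=cols).to_csv(
            d / "theta_avg.tsv", sep="\t"
        )
        pd.DataFrame(self.var_matrix, index=idx, columns=cols).to_csv(
            d / "var.tsv", sep="\t"
        )
        pd.DataFrame(self.design_matrix, index=idx, columns=cols).to_csv(
            d / "design.tsv", sep="\t"
        )
        pd.Series(self.cell_size, index=cols, name="cell_size").to_csv(
            d / "cell_size.tsv", sep="\t"
        )
        (d / "config.json").write_text(
            json.dumps({"config": self.config, "subjects": [str(s) for s in self.subjects]},
                       indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceModel":
        d = Path(directory)
        theta = pd.read_csv(d / "theta_avg.tsv", sep="\t", index_col=0)
        var = pd.read_csv(d / "var.tsv", sep="\t", index_col=0)
        design = pd.read_csv(d / "design.tsv", sep="\t", index_col=0)
        size = pd.read_csv(d / "cell_size.tsv", sep="\t", index_col=0)["cell_size"]
        sidecar = {}
        if (d / "config.json").exists():
            sidecar = json.loads((d / "config.json").read_text())
        return cls(
            theta_avg=theta.to_numpy(),
            var_matrix=var.to_numpy(),
            cell_size=size.to_numpy(dtype=float),
            design_matrix=design.to_numpy(),
            cell_types=list(theta.columns),
            gene_ids=[str(g) for g in theta.index],
            subjects=sidecar.get("subjects", []),
            config=sidecar.get("config", {}),
        )


def build_reference(
    sc: SingleCellDataset,
    theta_config: OutlierConfig | None = None,
    size_config: OutlierConfig | None = None,
    variance_after_exclusion: bool = False,
) -> ReferenceModel:
    """Compose the full signature from a labelled single-cell dataset.

    Per subject and type, relative abundances and cell sizes are computed;
    across subjects they are averaged with k-means outlier exclusion
    (thresholds rho_theta and rho_s from the two configs); the
    cross-subject variance of theta becomes the reference-error term of the
    deconvolution weights, and the design matrix is X = S ⊙ theta.

    By default the variance is taken over the unfiltered per-subject values;
    ``variance_after_exclusion=True`` recomputes it on the outlier-filtered
    values as a sensitivity analysis.
    """
    theta_config = theta_config or OutlierConfig()
    size_config = size_config or OutlierConfig()
    idx = CellTypeIndexSet.from_dataset(sc)
    subjects, cell_types = sc.subjects, sc.cell_types
    J, G, K = len(subjects), sc.n_genes, len(cell_types)

    per_subject_theta = np.full((J, G, K), np.nan)
    per_subject_size = np.full((J, K), np.nan)
    for jj, j in enumerate(subjects):
        for kk, k in enumerate(cell_types):
            if (j, k) not in idx:
                continue
            per_subject_theta[jj, :, kk] = relative_abundance(sc, idx, j, k)
            per_subject_size[jj, kk] = cell_size(sc, idx, j, k)

    theta_avg = average_abundance(per_subject_theta, theta_config)
    if variance_after_exclusion:
        var_matrix = _variance_post_exclusion(per_subject_theta, theta_config)
    else:
        var_matrix = cross_subject_variance(per_subject_theta)
    sizes = average_cell_size(per_subject_size, size_config)
    design = theta_avg * sizes[np.newaxis, :]
    return ReferenceModel(
        theta_avg=theta_avg,
        var_matrix=var_matrix,
        cell_size=sizes,
        design_matrix=design,
        cell_types=cell_types,
        gene_ids=list(sc.gene_ids),
        subjects=subjects,
        per_subject_theta=per_subject_theta,
        config={
            "theta": {"n_clusters": theta_config.n_clusters, "rho": theta_config.rho,
                      "random_seed": theta_config.random_seed},
            "size": {"n_clusters": size_config.n_clusters, "rho": size_config.rho,
                     "random_seed": size_config.random_seed},
            "variance_after_exclusion": variance_after_exclusion,
        },
    )


def _variance_post_exclusion(theta: np.ndarray, config: OutlierConfig) -> np.ndarray:
    J, G, K = theta.shape
    out = np.zeros((G, K))
    for k in range(K):
        present = ~np.isnan(theta[:, 0, k])
        vals = theta[present, :, k]
        for g in range(G):
            kept, _ = exclude_outliers(vals[:, g], config)
            out[g, k] = float(np.var(kept))
    return out
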