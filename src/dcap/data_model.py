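"""Domain containers and I/O for expression matrices and cell metadata.

Two matrix layouts are supported on disk: dense TSV/CSV with gene
identifiers in the first column and a header row of cell or sample
identifiers, and MatrixMarket coordinate files (genes as rows) with
companion ``features.tsv`` / ``barcodes.tsv`` files. Cell metadata is a
TSV/CSV with mandatory columns ``cell_id``, ``subject_id``, ``cell_type``.

Gene identifiers are matched by exact string equality after whitespace
stripping; no symbol/accession conversion is attempted here — identifier
mapping belongs upstream of deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from dcap.errors import ParseError, ValidationError

logger = logging.getLogger("dcap")

META_COLUMNS = ("cell_id", "subject_id", "cell_type")

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


def _check_nonnegative(matrix: np.ndarray, what: str) -> None:
    if matrix.size and matrix.min() < 0:
        g, c = np.unravel_index(int(np.argmin(matrix)), matrix.shape)
        raise ValidationError(
            f"negative entry {matrix[g, c]} in {what} at row {g}, column {c}"
        )


@dataclass
class SingleCellDataset:
    """Raw molecule counts (genes × cells) with per-cell subject and
    cell-type labels; the source for all reference quantities."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_meta: pd.DataFrame  # columns: cell_id, subject_id, cell_type

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_meta)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_meta)} cells"
            )
        _check_nonnegative(self.counts, "single-cell counts")
        _check_unique(self.gene_ids, "gene ids")
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell metadata lacks columns {missing}")
        if self.cell_meta[list(META_COLUMNS)].isna().any().any():
            raise ValidationError("cell metadata contains missing labels")
        _check_unique(self.cell_meta["cell_id"], "cell ids")
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def subjects(self) -> list:
        return sorted(self.cell_meta["subject_id"].unique().tolist())

    @property
    def cell_types(self) -> list:
        return sorted(self.cell_meta["cell_type"].unique().tolist())

    def write(self, counts_path: str | Path, meta_path: str | Path) -> None:
        """Write counts as dense TSV (genes × cells) and metadata as TSV."""
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.cell_meta["cell_id"].tolist(),
        )
        df.to_csv(counts_path, sep="\t")
        self.cell_meta.to_csv(meta_path, sep="\t", index=False)


@dataclass
class BulkDataset:
    """Gene-by-sample bulk expression to be deconvolved."""

    expression: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        if self.expression.ndim != 2:
            raise ValidationError("expression must be a 2-D matrix")
        if self.expression.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression shape {self.expression.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_nonnegative(self.expression, "bulk expression")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.expression,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class CellTypeIndexSet:
    """Mapping (subject j, cell type k) → column indices C_j^k of the cells
    in that group, with the per-group cell count m_j^k."""

    groups: dict[tuple, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_dataset(cls, sc: SingleCellDataset) -> "CellTypeIndexSet":
        groups = {
            (j, k): idx.to_numpy()
            for (j, k), idx in sc.cell_meta.groupby(
                ["subject_id", "cell_type"], sort=True
            ).groups.items()
        }
        return cls(groups=groups)

    def indices(self, subject, cell_type) -> np.ndarray:
        return self.groups[(subject, cell_type)]

    def size(self, subject, cell_type) -> int:
        """m_j^k, the number of cells of type k from subject j."""
        return len(self.groups[(subject, cell_type)])

    def __contains__(self, key: tuple) -> bool:
        return key in self.groups


def _read_dense(path: Path, sep: str, what: str) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty {what} file") from exc
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed structure
        raise ParseError(f"{path}: cannot parse {what} file: {exc}") from exc
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: {what} file has no data columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        line = raw.index.get_loc(row) + 2  # header line + 1-based
        raise ParseError(f"{path}: non-numeric value at line {line} (gene {row!r})")
    numeric.index = numeric.index.astype(str).str.strip()
    return numeric


def read_single_cell(
    counts_path: str | Path,
    meta_path: str | Path,
    format: str = "tsv",
) -> SingleCellDataset:
    """Read a single-cell count matrix plus per-cell metadata.

    ``format`` is one of ``tsv``, ``csv`` (dense, genes in column 1) or
    ``mtx`` (MatrixMarket coordinate file with sibling ``features.tsv`` and
    ``barcodes.tsv``). Cells whose metadata row is absent or carries a
    missing subject/cell-type label are dropped with a logged count rather
    than imputed: every reference quantity needs a known subject and type.
    """
    counts_path, meta_path = Path(counts_path), Path(meta_path)
    if format in _SEPARATORS:
        df = _read_dense(counts_path, _SEPARATORS[format], "counts")
        counts = df.to_numpy(dtype=float)
        gene_ids = df.index.tolist()
        cell_ids = [str(c).strip() for c in df.columns]
    elif format == "mtx":
        try:
            mat = scipy.io.mmread(counts_path)
        except Exception as exc:
            raise ParseError(f"{counts_path}: cannot parse MatrixMarket file: {exc}") from exc
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        feat = counts_path.with_name("features.tsv")
        barc = counts_path.with_name("barcodes.tsv")
        for p in (feat, barc):
            if not p.exists():
                raise ParseError(f"{p}: companion file not found")
        gene_ids = [ln.split("\t")[0].strip() for ln in feat.read_text().splitlines() if ln.strip()]
        cell_ids = [ln.split("\t")[0].strip() for ln in barc.read_text().splitlines() if ln.strip()]
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise ValidationError(
                f"MTX shape {counts.shape} does not match features/barcodes "
                f"({len(gene_ids)}, {len(cell_ids)})"
            )
    else:
        raise ValueError(f"unknown format {format!r}")

    try:
        meta = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise ParseError(f"{meta_path}: cannot parse metadata: {exc}") from exc
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ParseError(f"{meta_path}: metadata lacks columns {missing_cols}")
    meta = meta.copy()
    meta["cell_id"] = meta["cell_id"].astype(str).str.strip()
    meta = meta.set_index("cell_id", drop=False)

    labelled = meta.reindex(cell_ids)
    keep = labelled[["subject_id", "cell_type"]].notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "dropping %d of %d cells with missing subject or cell-type labels",
            n_dropped,
            len(cell_ids),
        )
    counts = counts[:, keep]
    cell_meta = labelled.loc[keep, list(META_COLUMNS)].reset_index(drop=True)
    return SingleCellDataset(counts=counts, gene_ids=gene_ids, cell_meta=cell_meta)


def read_bulk(path: str | Path, format: str = "tsv") -> BulkDataset:
    """Read a dense bulk expression table: gene ids in column 1, one column
    per sample."""
    if format not in _SEPARATORS:
        raise ValueError(f"unknown format {format!r}")
    df = _read_dense(Path(path), _SEPARATORS[format], "bulk expression")
    return BulkDataset(
        expression=df.to_numpy(dtype=float),
        gene_ids=df.index.tolist(),
        sample_ids=[str(s) for s in df.columns],
    )


def harmonize_genes(
    sc: SingleCellDataset, bulk: BulkDataset
) -> tuple[SingleCellDataset, BulkDataset]:
    """Restrict both datasets to their common genes, in a shared row order.

    The deconvolution equation relates bulk and reference values gene by
    gene, so both matrices must live on an identical gene axis. Row order
    follows the single-cell dataset's order of appearance; idempotent.
    """
    bulk_set = set(bulk.gene_ids)
    common = [g for g in sc.gene_ids if g in bulk_set]
    if not common:
        raise ValidationError("no genes shared between single-cell and bulk datasets")
    logger.info(
        "harmonized gene space: %d common of %d (sc) and %d (bulk)",
        len(common),
        sc.n_genes,
        bulk.n_genes,
    )
    sc_pos = {g: i for i, g in enumerate(sc.gene_ids)}
    bulk_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    sc_rows = [sc_pos[g] for g in common]
    bulk_rows = [bulk_pos[g] for g in common]
    sc_out = SingleCellDataset(
        counts=sc.counts[sc_rows, :],
        gene_ids=common,
        cell_meta=sc.cell_meta.copy(),
    )
    bulk_out = BulkDataset(
        expression=bulk.expression[bulk_rows, :],
        gene_ids=common,
        sample_ids=list(bulk.sample_ids),
    )
    return sc_out, bulk_out
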