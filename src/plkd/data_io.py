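"""Expression-matrix and gene-set I/O.

Supported on-disk formats: AnnData ``.h5ad`` (cells x genes, labels under
``obs['cell_type']`` / ``obs['batch']``), MatrixMarket ``.mtx`` with
``genes.tsv`` / ``barcodes.tsv`` sidecars, dense CSV (first column = cell id,
header row = gene names), and GMT gene-set files.

Normalization follows the common scRNA-seq recipe: per-cell counts are scaled
to a common target sum (default: the median of per-cell totals) and log1p
transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DataIOError(ValueError):
    """Raised for malformed expression or gene-set inputs."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for s in names:
        seen[s] = seen.get(s, 0) + 1
        if seen[s] == 2:
            dups.append(s)
    if dups:
        raise DataIOError(f"duplicate {what}: {', '.join(sorted(dups))}")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers and per-cell labels.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` float array; raw counts or normalized
        log-space values depending on ``normalized``.
    gene_names, cell_ids
        Ordered, unique identifiers for columns and rows.
    cell_type, batch
        Optional per-cell labels of length ``n_cells``.
    normalized
        True once :func:`normalize_log1p` has been applied.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    cell_type: np.ndarray | None = None
    batch: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataIOError("values must be a 2-D cells x genes matrix")
        n_cells, n_genes = self.values.shape
        if len(self.gene_names) != n_genes:
            raise DataIOError("gene_names length does not match column count")
        if len(self.cell_ids) != n_cells:
            raise DataIOError("cell_ids length does not match row count")
        _check_unique(self.gene_names, "gene names")
        _check_unique(self.cell_ids, "cell ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataIOError(f"non-finite value at cell {bad[0]}, gene {bad[1]}")
        if not self.normalized and np.any(self.values < 0):
            raise DataIOError("negative values in a count matrix")
        for name in ("cell_type", "batch"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if lab.shape != (n_cells,):
                    raise DataIOError(f"{name} labels must have length {n_cells}")
                setattr(self, name, lab)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            gene_names=list(self.gene_names),
            cell_ids=list(self.cell_ids),
            cell_type=None if self.cell_type is None else self.cell_type.copy(),
            batch=None if self.batch is None else self.batch.copy(),
        )


@dataclass
class GeneSetCollection:
    """Named pathway -> gene-symbol sets (parsed from GMT)."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataIOError(f"gene set {name!r} is empty")

    @property
    def m(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _from_anndata(adata) -> ExpressionMatrix:
    import scipy.sparse as sp

    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    kwargs = {}
    if "cell_type" in adata.obs:
        kwargs["cell_type"] = adata.obs["cell_type"].to_numpy()
    if "batch" in adata.obs:
        kwargs["batch"] = adata.obs["batch"].to_numpy()
    normalized = bool(adata.uns.get("normalized", False))
    return ExpressionMatrix(
        values=np.asarray(X, dtype=np.float64),
        gene_names=[str(g) for g in adata.var_names],
        cell_ids=[str(c) for c in adata.obs_names],
        normalized=normalized,
        **kwargs,
    )


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a cells x genes expression matrix.

    ``format`` is one of ``{"h5ad", "mtx", "csv"}``; when omitted it is
    inferred from the file suffix. For ``mtx``, ``genes.tsv`` and
    ``barcodes.tsv`` must sit next to the matrix file; MatrixMarket stores
    genes x cells, so the matrix is transposed on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".h5ad": "h5ad", ".mtx": "mtx", ".csv": "csv"}.get(path.suffix)
        if format is None:
            raise DataIOError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "h5ad":
        import anndata as ad

        return _from_anndata(ad.read_h5ad(path))
    if format == "mtx":
        import scipy.io as sio

        genes_f = path.parent / "genes.tsv"
        cells_f = path.parent / "barcodes.tsv"
        for f in (genes_f, cells_f):
            if not f.exists():
                raise FileNotFoundError(f"mtx sidecar missing: {f}")
        M = sio.mmread(path).toarray().T  # stored genes x cells
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_f, sep="\t", header=None)[0].astype(str).tolist()
        return ExpressionMatrix(values=M, gene_names=genes, cell_ids=cells)
    if format == "csv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        _check_unique(header, "gene names")
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            for i in range(df.shape[0]):
                for j in range(df.shape[1]):
                    try:
                        float(df.iat[i, j])
                    except (TypeError, ValueError):
                        raise DataIOError(
                            f"non-numeric entry at row {df.index[i]!r}, "
                            f"column {df.columns[j]!r}"
                        ) from None
            vals = df.astype(float).to_numpy()
        return ExpressionMatrix(
            values=vals.astype(np.float64),
            gene_names=[str(g) for g in df.columns],
            cell_ids=[str(c) for c in df.index],
        )
    raise DataIOError(f"unknown format {format!r}")


def to_anndata(X: ExpressionMatrix):
    """Convert to :class:`anndata.AnnData` (labels into ``obs``)."""
    import anndata as ad

    obs = pd.DataFrame(index=pd.Index(X.cell_ids, name="cell_id"))
    if X.cell_type is not None:
        obs["cell_type"] = pd.Categorical(X.cell_type)
    if X.batch is not None:
        obs["batch"] = pd.Categorical(X.batch)
    adata = ad.AnnData(
        X=X.values.copy(),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(X.gene_names, name="gene")),
    )
    adata.uns["normalized"] = bool(X.normalized)
    return adata


def write_expression(X: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write an expression matrix (formats as :func:`read_expression`)."""
    path = Path(path)
    if format is None:
        format = {".h5ad": "h5ad", ".mtx": "mtx", ".csv": "csv"}.get(path.suffix)
        if format is None:
            raise DataIOError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "h5ad":
        to_anndata(X).write_h5ad(path)
    elif format == "mtx":
        import scipy.io as sio
        import scipy.sparse as sp

        sio.mmwrite(str(path), sp.coo_matrix(X.values.T))
        pd.Series(X.gene_names).to_csv(path.parent / "genes.tsv", sep="\t",
                                       header=False, index=False)
        pd.Series(X.cell_ids).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                     header=False, index=False)
    elif format == "csv":
        pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_names).to_csv(path)
    else:
        raise DataIOError(f"unknown format {format!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name, description, gene, gene, ...``.

    The description column is discarded and gene symbols are deduplicated
    within each set. Duplicate pathway names or short lines are errors.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIOError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description, genes..."
                )
            name = fields[0]
            if name in sets:
                raise DataIOError(f"{path}: duplicate pathway name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise DataIOError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection | Mapping[str, set[str]],
              path: str | Path, description: str = "na") -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# normalization / gene alignment
# ---------------------------------------------------------------------------

def normalize_log1p(X: ExpressionMatrix,
                    target_sum: float | str = "median") -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then ``log1p``.

    ``target_sum="median"`` (default) uses the median of per-cell totals as
    the common library size, the same convention as
    ``scanpy.pp.normalize_total``. A second call on already-normalized data
    is rejected.
    """
    if X.normalized:
        raise DataIOError("matrix is already normalized")
    totals = X.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise DataIOError(
            "cells with zero total counts: "
            + ", ".join(X.cell_ids[i] for i in zero[:10])
        )
    if target_sum == "median":
        target = float(np.median(totals))
    else:
        target = float(target_sum)
        if target <= 0:
            raise DataIOError("target_sum must be positive")
    out = X.copy()
    out.values = np.log1p(X.values * (target / totals)[:, None])
    out.normalized = True
    return out


def align_genes(X: ExpressionMatrix, reference_genes: Sequence[str]) -> ExpressionMatrix:
    """Reorder columns to ``reference_genes``.

    Genes absent from ``X`` are zero-filled; extra genes are dropped. Both
    events are reported with a warning; an empty intersection is an error.
    Matching is case-sensitive exact string match.
    """
    reference_genes = list(reference_genes)
    _check_unique(reference_genes, "reference gene names")
    col = {g: j for j, g in enumerate(X.gene_names)}
    shared = [g for g in reference_genes if g in col]
    if not shared:
        raise DataIOError("no genes shared with the reference gene list")
    missing = [g for g in reference_genes if g not in col]
    extra = sorted(set(X.gene_names) - set(reference_genes))
    if missing:
        warnings.warn(
            f"{len(missing)} reference genes absent from input, zero-filled: "
            + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        )
    if extra:
        warnings.warn(
            f"{len(extra)} genes not in reference dropped: "
            + ", ".join(extra[:10]) + ("..." if len(extra) > 10 else "")
        )
    out = np.zeros((X.n_cells, len(reference_genes)), dtype=np.float64)
    for j, g in enumerate(reference_genes):
        if g in col:
            out[:, j] = X.values[:, col[g]]
    return ExpressionMatrix(
        values=out,
        gene_names=reference_genes,
        cell_ids=list(X.cell_ids),
        cell_type=X.cell_type,
        batch=X.batch,
        normalized=X.normalized,
    )
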