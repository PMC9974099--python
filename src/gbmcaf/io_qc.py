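"""Count-matrix I/O, per-cell quality control, and log-normalization.

The central container is :class:`CountMatrix`: unique cell and gene
identifiers plus a sparse cells x genes matrix of non-negative integer UMI
counts. Matrices round-trip through the 10x-style triplet layout
(``matrix.mtx`` in Matrix Market coordinate format with genes as rows,
``features.tsv``, ``barcodes.tsv``) or a dense TSV with gene rows and cell
columns.

QC follows the strict-inequality reading of the filters applied to the
serially trypsinized glioblastoma cells: a cell is removed when its
mitochondrial fraction exceeds 20% or its UMI total is below 200 or above
20,000; the boundary values 200, 20,000 and exactly 20% are retained.
Normalization is the global-scaling LogNormalize transform,
``ln(1 + count * scale / total)`` with ``scale`` defaulting to 10,000.
Genes are never filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .exceptions import FormatError, ParameterError

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "CellQC",
    "QCFilterResult",
    "read_counts",
    "write_counts",
    "read_gene_annotation",
    "compute_cell_qc",
    "qc_filter",
    "log_normalize",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(pd.unique(ids)) != len(ids):
        raise FormatError(f"duplicate {what} identifiers")


@dataclass
class CountMatrix:
    """Cells x genes sparse matrix of non-negative integer UMI counts."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if m.nnz:
            data = m.data
            if not np.issubdtype(data.dtype, np.integer):
                if np.any(data != np.round(data)):
                    raise FormatError("counts must be integers")
            if data.min(initial=0) < 0:
                raise FormatError("counts must be non-negative")
        self.counts = m.astype(np.int64)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense per-cell count vector for one gene."""
        return np.asarray(
            self.counts[:, self.gene_index(gene)].todense()
        ).ravel()

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(self.cell_ids[idx], self.gene_ids, self.counts[idx])


@dataclass
class NormalizedMatrix:
    """LogNormalize-transformed expression on the same axes as its source counts.

    Values are natural-log scale, zero counts map to exactly zero, and the
    matrix stays sparse.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values.data)):
            raise FormatError("normalized values must be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def expr(self, gene: str) -> np.ndarray:
        """Dense per-cell expression vector for one gene."""
        try:
            j = self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return np.asarray(self.values[:, j].todense()).ravel()

    def dense(self, genes) -> np.ndarray:
        idx = [self._gene_index[g] for g in genes]
        return np.asarray(self.values[:, idx].todense())


@dataclass
class CellQC:
    """Per-cell QC metrics: UMI totals and mitochondrial fraction.

    ``mito_fraction`` is defined as 0 for zero-depth cells, which are flagged
    in ``zero_depth`` and always fail filtering.
    """

    total_umi: np.ndarray
    mito_fraction: np.ndarray
    zero_depth: np.ndarray
    mito_prefix: str = "MT-"


@dataclass
class QCFilterResult:
    matrix: CountMatrix
    report: pd.DataFrame
    removed: dict = field(default_factory=dict)


def write_counts(
    m: CountMatrix,
    outdir,
    gene_annotation: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> Path:
    """Write the 10x-style triplet layout (plus optional truth labels).

    ``features.tsv`` columns are gene id, gene name, chromosome, start; the
    last two are ``.``/``-1`` when no annotation is supplied.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(
        str(outdir / "matrix.mtx"),
        m.counts.T.tocoo(),
        field="integer",
        comment="genes x cells UMI counts",
    )
    if gene_annotation is not None:
        ann = gene_annotation.set_index("gene")
        chrom = [str(ann.loc[g, "chromosome"]) if g in ann.index else "." for g in m.gene_ids]
        start = [int(ann.loc[g, "start"]) if g in ann.index else -1 for g in m.gene_ids]
    else:
        chrom = ["."] * m.n_genes
        start = [-1] * m.n_genes
    feats = pd.DataFrame(
        {"gene_id": m.gene_ids, "gene_name": m.gene_ids, "chromosome": chrom, "start": start}
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    if labels is not None:
        pd.DataFrame({"barcode": m.cell_ids, "label": labels.reindex(m.cell_ids).values}).to_csv(
            outdir / "labels.tsv", sep="\t", header=False, index=False
        )
    return outdir


def read_counts(path) -> CountMatrix:
    """Read a triplet directory (matrix.mtx + features.tsv + barcodes.tsv) or dense TSV.

    The dense dialect has the gene id in the first column and a header row of
    cell ids. Non-integer or negative entries raise :class:`FormatError`.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        bars = path / "barcodes.tsv"
        for p in (mtx, feats, bars):
            if not p.exists():
                raise FormatError(f"missing {p.name} in {path}")
        mat = mmread(str(mtx))  # genes x cells
        genes = pd.read_csv(feats, sep="\t", header=None).iloc[:, 0].astype(str).values
        cells = pd.read_csv(bars, sep="\t", header=None).iloc[:, 0].astype(str).values
        if mat.shape[0] != len(genes) or mat.shape[1] != len(cells):
            raise FormatError(
                f"matrix.mtx declares {mat.shape[0]} genes x {mat.shape[1]} cells but "
                f"features.tsv lists {len(genes)} and barcodes.tsv {len(cells)}"
            )
        return CountMatrix(cells, genes, sp.csr_matrix(mat.T))
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if vals.size and not np.issubdtype(vals.dtype, np.integer):
        if np.any(vals != np.round(vals)):
            raise FormatError(f"non-integer count entry in {path}")
    return CountMatrix(
        df.columns.astype(str).values,
        df.index.astype(str).values,
        sp.csr_matrix(vals.T),
    )


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene, chromosome, start."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "chromosome", "start"}
    if not needed.issubset(df.columns):
        # headerless fallback: assume the three columns in order
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "chromosome", "start"])
    df["chromosome"] = df["chromosome"].astype(str)
    df["start"] = df["start"].astype(int)
    return df[["gene", "chromosome", "start"]]


def compute_cell_qc(m: CountMatrix, mito_prefix: str = "MT-") -> CellQC:
    """Per-cell UMI totals and mitochondrial fraction.

    The mitochondrial fraction is the summed count over genes whose name
    starts with ``mito_prefix`` divided by the cell total; cells with zero
    total are flagged instead.
    """
    total = m.total_counts()
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in m.gene_ids])
    if mito_mask.any():
        mito = np.asarray(m.counts[:, np.flatnonzero(mito_mask)].sum(axis=1)).ravel()
    else:
        mito = np.zeros(m.n_cells)
    zero = total == 0
    frac = np.zeros(m.n_cells, dtype=float)
    nz = ~zero
    frac[nz] = mito[nz] / total[nz]
    return CellQC(total_umi=total, mito_fraction=frac, zero_depth=zero, mito_prefix=mito_prefix)


def qc_filter(
    m: CountMatrix,
    qc: CellQC,
    mito_max: float = 0.20,
    umi_min: int = 200,
    umi_max: int = 20000,
) -> QCFilterResult:
    """Apply the cell filters; boundaries are retained (strict exclusions).

    Removes cells with mito_fraction > ``mito_max``, total UMI < ``umi_min``
    or > ``umi_max``, and zero-depth cells. The gene axis is unchanged.
    """
    fail_mito = qc.mito_fraction > mito_max
    fail_low = qc.total_umi < umi_min
    fail_high = qc.total_umi > umi_max
    fail_zero = qc.zero_depth
    keep = ~(fail_mito | fail_low | fail_high | fail_zero)

    reasons = []
    for i in range(m.n_cells):
        r = []
        if fail_zero[i]:
            r.append("zero_depth")
        if fail_mito[i]:
            r.append("mito_fraction")
        if fail_low[i]:
            r.append("umi_low")
        if fail_high[i]:
            r.append("umi_high")
        reasons.append(";".join(r))
    report = pd.DataFrame(
        {
            "cell": m.cell_ids,
            "total_umi": qc.total_umi,
            "mito_fraction": qc.mito_fraction,
            "passed": keep,
            "reason": reasons,
        }
    )
    removed = {
        "mito_fraction": int(fail_mito.sum()),
        "umi_low": int(fail_low.sum()),
        "umi_high": int(fail_high.sum()),
        "zero_depth": int(fail_zero.sum()),
        "total_removed": int((~keep).sum()),
    }
    if not keep.any():
        warnings.warn("QC filter removed every cell", stacklevel=2)
    return QCFilterResult(matrix=m.subset_cells(keep), report=report, removed=removed)


def log_normalize(m: CountMatrix, scale: float = 10000.0) -> NormalizedMatrix:
    """LogNormalize: value(c, g) = ln(1 + count(c, g) * scale / total(c)).

    Every cell must have positive depth; the error names the first offender.
    """
    if scale <= 0:
        raise ParameterError("scale must be positive")
    total = m.total_counts()
    if np.any(total == 0):
        bad = m.cell_ids[int(np.argmax(total == 0))]
        raise ParameterError(f"cell {bad!r} has zero total UMI; filter before normalizing")
    x = sp.diags(scale / total) @ m.counts.astype(np.float64)
    x = sp.csr_matrix(x)
    x.data = np.log1p(x.data)
    return NormalizedMatrix(m.cell_ids, m.gene_ids, x)
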