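"""Expression containers and the normalisation / centering steps feeding NMF and scoring.

The pipeline works on a genes x cells matrix with one sample (cell line)
label per cell.  NMF consumes a per-sample *centered, non-negative* version
of the normalised matrix: each gene is centered on its mean across the
sample's cells and negative residuals are clipped to zero, so factors pick
up genes expressed *above* their sample average.  Scoring, by contrast,
uses the signed centered values (no clipping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression with ids and a cell -> sample mapping.

    ``values`` may hold raw counts or normalised expression; operations
    document which they expect.
    """

    values: np.ndarray  # (n_genes, n_cells), finite, non-negative for counts
    gene_ids: list[str]
    cell_ids: list[str]
    sample_of_cell: list[str]  # parallel to cell_ids

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        self.sample_of_cell = list(map(str, self.sample_of_cell))
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"dimension mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if len(self.sample_of_cell) != len(self.cell_ids):
            raise ValidationError("sample_of_cell must map every cell to one sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> list[str]:
        """Sample ids in first-appearance order."""
        return list(dict.fromkeys(self.sample_of_cell))

    def cells_of_sample(self, sample_id: str) -> np.ndarray:
        """Column indices of the cells belonging to ``sample_id``."""
        mask = np.asarray([s == sample_id for s in self.sample_of_cell])
        if not mask.any():
            raise KeyError(f"unknown sample id: {sample_id}")
        return np.flatnonzero(mask)

    def subset_sample(self, sample_id: str) -> "ExpressionMatrix":
        idx = self.cells_of_sample(sample_id)
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            sample_of_cell=[sample_id] * len(idx),
        )


@dataclass
class CenteredNonNegMatrix:
    """Per-gene centered expression with negatives clipped to zero."""

    values: np.ndarray  # (n_genes, n_cells), >= 0
    gene_ids: list[str]
    cell_ids: list[str]
    sample_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min(initial=0.0) < 0:
            raise ValidationError("centered-clipped matrix must be non-negative")


def load_expression(
    path: str | Path,
    fmt: str = "mtx",
    genes_in_rows: bool = True,
    samples_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``fmt='mtx'``: ``path`` is a Matrix Market file with ``genes.tsv``,
    ``barcodes.tsv`` and optionally ``samples.tsv`` sidecars in the same
    directory (one id per line; samples.tsv one sample label per cell).
    ``fmt='dense_tsv'``: tab-separated, header row of cell ids, first
    column gene ids.  Orientation of the dense file is declared by
    ``genes_in_rows``, never guessed.
    """
    path = Path(path)
    if fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        gene_ids = _read_id_list(path.parent / "genes.tsv")
        cell_ids = _read_id_list(path.parent / "barcodes.tsv")
        if not genes_in_rows:
            values = values.T
        if values.shape[0] != len(gene_ids):
            raise ValidationError(
                f"genes.tsv lists {len(gene_ids)} genes but matrix has {values.shape[0]} rows"
            )
        if values.shape[1] != len(cell_ids):
            raise ValidationError(
                f"barcodes.tsv lists {len(cell_ids)} cells but matrix has {values.shape[1]} columns"
            )
        spath = Path(samples_path) if samples_path else path.parent / "samples.tsv"
        if spath.exists():
            samples = _read_id_list(spath)
            if len(samples) != len(cell_ids):
                raise ValidationError(
                    f"samples.tsv lists {len(samples)} labels for {len(cell_ids)} cells"
                )
        else:
            samples = ["sample_0"] * len(cell_ids)
    elif fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not genes_in_rows:
            df = df.T
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        if samples_path is not None:
            samples = _read_id_list(samples_path)
            if len(samples) != len(cell_ids):
                raise ValidationError("sample labels do not match cell count")
        else:
            samples = ["sample_0"] * len(cell_ids)
    else:
        raise ValidationError(f"unknown format: {fmt!r} (expected 'mtx' or 'dense_tsv')")

    if np.nanmin(values) < 0:
        raise ValidationError("expression matrix contains negative entries")
    return ExpressionMatrix(values, gene_ids, cell_ids, samples)


def write_expression(matrix: ExpressionMatrix, out_dir: str | Path) -> Path:
    """Write matrix.mtx + genes.tsv / barcodes.tsv / samples.tsv sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx_path = out_dir / "matrix.mtx"
    spio.mmwrite(mtx_path, sparse.coo_matrix(matrix.values))
    (out_dir / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
    (out_dir / "samples.tsv").write_text("\n".join(matrix.sample_of_cell) + "\n")
    return mtx_path


def _read_id_list(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing sidecar file: {path}")
    # first tab-separated field of each line, so 10x-style two-column files work
    return [line.split("\t")[0] for line in path.read_text().splitlines() if line.strip()]


def normalize_log(
    matrix: ExpressionMatrix, scale: float = 10_000.0, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Counts-per-``scale`` normalisation followed by log2(x + pseudocount).

    Each cell's counts are rescaled to sum to ``scale`` and then log2
    transformed; genes that are zero everywhere stay zero.  Cells with a
    zero total cannot be normalised and raise an error naming them.
    """
    totals = matrix.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [matrix.cell_ids[i] for i in np.flatnonzero(zero)]
        raise ValidationError(f"cells with zero total counts: {bad}")
    values = np.log2(matrix.values / totals * scale + pseudocount)
    return ExpressionMatrix(values, matrix.gene_ids, matrix.cell_ids, matrix.sample_of_cell)


def center_genes(values: np.ndarray) -> np.ndarray:
    """Subtract each gene's mean across cells (signed; used for scoring)."""
    return values - values.mean(axis=1, keepdims=True)


def center_and_clip(
    matrix: ExpressionMatrix, per_sample: bool = True
) -> list[CenteredNonNegMatrix]:
    """Center each gene on its mean and clip negatives to zero.

    With ``per_sample=True`` (default) centering is done within each
    sample and one matrix per sample is returned; otherwise a single
    globally centered matrix is returned (in a one-element list).
    """
    out: list[CenteredNonNegMatrix] = []
    if per_sample:
        for sid in matrix.samples:
            sub = matrix.subset_sample(sid)
            if sub.n_cells < 2:
                raise ValidationError(f"sample {sid!r} has fewer than 2 cells")
            out.append(
                CenteredNonNegMatrix(
                    values=np.clip(center_genes(sub.values), 0.0, None),
                    gene_ids=list(matrix.gene_ids),
                    cell_ids=sub.cell_ids,
                    sample_id=sid,
                )
            )
    else:
        if matrix.n_cells < 2:
            raise ValidationError("need at least 2 cells to center")
        out.append(
            CenteredNonNegMatrix(
                values=np.clip(center_genes(matrix.values), 0.0, None),
                gene_ids=list(matrix.gene_ids),
                cell_ids=list(matrix.cell_ids),
                sample_id="__all__",
            )
        )
    return out


def filter_detected_genes(
    matrix: ExpressionMatrix, min_detect_frac: float = 0.02
) -> np.ndarray:
    """Boolean mask of genes detected (value > 0) in >= ``min_detect_frac`` of cells."""
    frac = (matrix.values > 0).mean(axis=1)
    keep = frac >= min_detect_frac
    if not keep.any():
        warnings.warn("gene detection filter removed every gene; keeping all")
        return np.ones(matrix.n_genes, dtype=bool)
    return keep
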