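"""Reading and writing expression matrices, labels, and model bundles.

The shared data model is a cells x genes :class:`ExpressionMatrix` with a
``layer_tag`` recording which transform has been applied (``raw_counts``,
``normalized`` or ``standardized``), and a :class:`ReferenceAtlas` pairing a
raw-count matrix with one categorical state label per cell.

Supported on-disk formats:

* Matrix Market triplets (``matrix.mtx[.gz]``) with ``features.tsv[.gz]`` /
  ``genes.tsv[.gz]`` and ``barcodes.tsv[.gz]`` sidecars, genes x cells on disk
  (CellRanger convention) unless ``cells_rows=True``;
* dense TSV/CSV, cells x genes, header row = gene IDs, first column = cell IDs;
* HDF5 single-cell containers with the standard ``X`` / ``obs`` / ``var``
  layout, via :mod:`anndata`.

Model bundles are single ``.zip`` archives holding a JSON manifest plus an
``arrays.npz`` member; see :func:`save_model` / :func:`load_model`.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    CellStateWarning,
    FormatError,
    ModelIOError,
    ValidationError,
)

MODEL_FORMAT_VERSION = "cellstate-model-v1"

#: store matrices sparse (CSR by cell) whenever density is below this
SPARSE_DENSITY_THRESHOLD = 0.5

LAYER_TAGS = ("raw_counts", "normalized", "standardized")


def _as_storage(values) -> np.ndarray | sp.csr_matrix:
    """Return ``values`` as float64 ndarray or CSR, sparsifying dense input
    below the density threshold (and densifying near-dense sparse input)."""
    if sp.issparse(values):
        values = values.tocsr().astype(np.float64)
        density = values.nnz / max(1, values.shape[0] * values.shape[1])
        return values if density < SPARSE_DENSITY_THRESHOLD else np.asarray(values.todense())
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValidationError(f"expression values must be 2-D, got shape {values.shape}")
    if values.size:
        density = np.count_nonzero(values) / values.size
        if density < SPARSE_DENSITY_THRESHOLD:
            return sp.csr_matrix(values)
    return values


def _check_unique(ids: np.ndarray, what: str) -> None:
    uniq, counts = np.unique(ids, return_counts=True)
    dups = uniq[counts > 1]
    if dups.size:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionMatrix:
    """A cells x genes numeric expression matrix.

    Parameters
    ----------
    values : ndarray or sparse matrix, cells x genes
    cell_ids, gene_ids : ordered unique identifiers
    layer_tag : one of ``raw_counts``, ``normalized``, ``standardized``;
        ``raw_counts`` requires all values to be non-negative integers.
    """

    values: np.ndarray | sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = _as_storage(self.values)
        n, g = self.values.shape
        if n != len(self.cell_ids):
            raise ValidationError(f"{n} rows but {len(self.cell_ids)} cell_ids")
        if g != len(self.gene_ids):
            raise ValidationError(f"{g} columns but {len(self.gene_ids)} gene_ids")
        _check_unique(self.cell_ids, "cell IDs")
        _check_unique(self.gene_ids, "gene IDs")
        if self.layer_tag not in LAYER_TAGS:
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == "raw_counts":
            data = self.values.data if sp.issparse(self.values) else self.values
            if data.size and data.min() < 0:
                raise ValidationError("raw counts contain negative entries")
            if data.size and np.any(data != np.floor(data)):
                raise ValidationError("raw counts contain non-integer entries")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.layer_tag == other.layer_tag
            and np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.to_dense(), other.to_dense())
        )

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.values.copy() if sp.issparse(self.values) else self.values.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id")),
            uns={"layer_tag": self.layer_tag},
        )


@dataclass
class ReferenceAtlas:
    """A raw-count :class:`ExpressionMatrix` with one state label per cell.

    The label vocabulary is the lexicographically sorted set of observed
    labels; its order governs class index assignment everywhere downstream.
    """

    matrix: ExpressionMatrix
    labels: np.ndarray
    label_vocabulary: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.matrix.n_cells:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.matrix.n_cells} cells"
            )
        vocab = np.array(sorted(set(self.labels.tolist())), dtype=object)
        if self.label_vocabulary is None:
            self.label_vocabulary = vocab
        else:
            self.label_vocabulary = np.asarray(self.label_vocabulary, dtype=object)
            if not np.array_equal(self.label_vocabulary, vocab):
                raise ValidationError(
                    "label_vocabulary must be the sorted set of observed labels"
                )

    @property
    def n_states(self) -> int:
        return len(self.label_vocabulary)

    def class_counts(self) -> dict[str, int]:
        uniq, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------

def _find_sidecar(mtx_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in (".tsv", ".tsv.gz", ".txt"):
            cand = mtx_path.parent / f"{stem}{suffix}"
            if cand.exists():
                return cand
    raise FormatError(
        f"no sidecar file {'/'.join(stems)}.tsv[.gz] next to {mtx_path}"
    )


def _read_id_column(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def _validate_mtx_header(path: Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline().strip()
    if not first.startswith("%%MatrixMarket"):
        raise FormatError(f"malformed Matrix Market header in {path}: {first!r}")


def read_matrix(path, format: str, cells_rows: bool = False) -> ExpressionMatrix:
    """Read an expression matrix as raw counts.

    Parameters
    ----------
    format : ``"mtx"``, ``"dense_tsv"`` or ``"h5sc"``.
    cells_rows : for ``mtx`` only — set when the on-disk matrix is already
        cells x genes instead of the genes x cells CellRanger convention.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "mtx":
        _validate_mtx_header(path)
        try:
            mat = scipy.io.mmread(str(path))
        except ValueError as exc:
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = sp.coo_matrix(mat)
        if not cells_rows:
            mat = mat.T
        if mat.shape[0] == 0:
            raise FormatError(f"no cells in {path}")
        if mat.shape[1] == 0:
            raise FormatError(f"no genes in {path}")
        gene_ids = _read_id_column(_find_sidecar(path, ("features", "genes")))
        cell_ids = _read_id_column(_find_sidecar(path, ("barcodes",)))
        return ExpressionMatrix(mat.tocsr(), cell_ids, gene_ids, "raw_counts")
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.shape[0] == 0:
            raise FormatError(f"no cells in {path}")
        return ExpressionMatrix(
            df.to_numpy(dtype=np.float64),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            "raw_counts",
        )
    if format == "h5sc":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if adata.n_obs == 0:
            raise FormatError(f"no cells in {path}")
        tag = adata.uns.get("layer_tag", "raw_counts")
        return ExpressionMatrix(
            adata.X,
            adata.obs_names.to_numpy(dtype=object),
            adata.var_names.to_numpy(dtype=object),
            str(tag),
        )
    raise ValidationError(f"unknown matrix format {format!r}")


def write_matrix(m: ExpressionMatrix, path, format: str) -> None:
    """Write ``m`` in one of the supported formats (inverse of read_matrix)."""
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), sp.coo_matrix(m.values.T))  # genes x cells on disk
        pd.Series(m.gene_ids.astype(str)).to_csv(
            path.parent / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(m.cell_ids.astype(str)).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
        return
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        dense = m.to_dense()
        if m.layer_tag == "raw_counts":
            dense = dense.astype(np.int64)
        df = pd.DataFrame(dense, index=m.cell_ids.astype(str), columns=m.gene_ids.astype(str))
        df.index.name = "cell_id"
        df.to_csv(path, sep=sep)
        return
    if format == "h5sc":
        m.to_anndata().write_h5ad(path)
        return
    raise ValidationError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {"cell_id", "cell", "barcode", "id", "cell_barcode"}


def read_labels(path, cell_ids) -> np.ndarray:
    """Read a two-column (cell_id, label) delimited file.

    Returns labels aligned to ``cell_ids`` order. A header row is detected by
    a conventional first-column name (``cell_id``, ``barcode``, ...). Rows for
    unknown cells are ignored with a warning; cells of the matrix missing from
    the file are an error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell_id, label)")
    if str(df.iloc[0, 0]).strip().lower() in _HEADER_TOKENS:
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for cid, lab in zip(df.iloc[:, 0], df.iloc[:, 1]):
        cid, lab = str(cid), str(lab)
        if cid in mapping and mapping[cid] != lab:
            raise ValidationError(
                f"cell {cid!r} has conflicting labels {mapping[cid]!r} and {lab!r}"
            )
        mapping[cid] = lab
    wanted = [str(c) for c in cell_ids]
    missing = [c for c in wanted if c not in mapping]
    if missing:
        raise ValidationError(
            f"{len(missing)} matrix cells missing from label file: "
            + ", ".join(missing[:10])
        )
    extra = set(mapping) - set(wanted)
    if extra:
        warnings.warn(
            f"{len(extra)} label rows for cells not in the matrix were ignored",
            CellStateWarning,
            stacklevel=2,
        )
    return np.array([mapping[c] for c in wanted], dtype=object)


def read_atlas(matrix_path, labels_path, format: str = "mtx", **kw) -> ReferenceAtlas:
    """Convenience: read matrix + labels into a ReferenceAtlas."""
    m = read_matrix(matrix_path, format, **kw)
    labels = read_labels(labels_path, m.cell_ids)
    return ReferenceAtlas(m, labels)


def write_labels(path, cell_ids, labels) -> None:
    pd.DataFrame({"cell_id": np.asarray(cell_ids, dtype=str),
                  "label": np.asarray(labels, dtype=str)}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def save_model(results, path) -> None:
    """Serialize a fitted :class:`~cellstate.model.CellStateResults` to a
    single zip archive (JSON manifest + npz arrays)."""
    path = Path(path)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "calibrated": results.calibrated,
        "classes": results.classes.astype(str).tolist(),
        "gene_panel": results.gene_panel.astype(str).tolist(),
        "config": results.config.to_dict(),
        "training_report": results.training_report,
    }
    arrays = {
        "coef": results.coef,
        "intercept": results.intercept,
        "gene_mean": results.gene_stats.mean,
        "gene_std": results.gene_stats.std,
        "hvg_flag": results.gene_stats.hvg_flag.astype(np.int8),
    }
    if results.calibrated:
        arrays["calib_a"] = results.calib_a
        arrays["calib_b"] = results.calib_b
    buf = _io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("arrays.npz", buf.getvalue())


def load_model(path):
    """Load a model bundle written by :func:`save_model`.

    Raises :class:`ModelIOError` on truncation or a version mismatch; never
    falls back silently.
    """
    from .model import CellStateResults, ModelConfig
    from .preprocess import GeneStats

    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such model bundle: {path}")
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            arrays = np.load(_io.BytesIO(zf.read("arrays.npz")))
            arrays = {k: arrays[k] for k in arrays.files}
    except (zipfile.BadZipFile, KeyError, ValueError, OSError) as exc:
        raise ModelIOError(f"model bundle {path} is truncated or corrupt: {exc}") from exc
    version = manifest.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"model bundle {path} has format version {version!r}; "
            f"this build reads {MODEL_FORMAT_VERSION!r}"
        )
    gene_panel = np.array(manifest["gene_panel"], dtype=object)
    stats = GeneStats(
        gene_ids=gene_panel,
        mean=arrays["gene_mean"],
        std=arrays["gene_std"],
        hvg_flag=arrays["hvg_flag"].astype(bool),
    )
    return CellStateResults(
        classes=np.array(manifest["classes"], dtype=object),
        gene_panel=gene_panel,
        gene_stats=stats,
        coef=arrays["coef"],
        intercept=arrays["intercept"],
        calib_a=arrays.get("calib_a"),
        calib_b=arrays.get("calib_b"),
        config=ModelConfig.from_dict(manifest["config"]),
        training_report=manifest["training_report"],
    )
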