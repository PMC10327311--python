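"""Readers and writers for CellRanger-style per-sample artifacts.

The transfer formats are deliberately plain: a MatrixMarket triple
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, optionally gzipped)
for the feature-barcode count matrix, and CSV for projections, metrics
summaries and the sample metadata sheet.  Barcodes keep their trailing
gem-group suffixes (``-1``); joins between artifacts use exact string
equality, since aggregated matrices rely on the suffix to disambiguate.
"""

from __future__ import annotations

import csv
import gzip
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .qc_metrics import LIBRARY_TYPES, SampleQCMetrics

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Input artifact violates its format contract."""


# ---------------------------------------------------------------------------
# feature-barcode matrix


@dataclass
class GeneCellMatrix:
    """Sparse non-negative integer counts: rows = features, columns = barcodes."""

    counts: sp.csc_matrix
    feature_names: list[str]
    feature_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        n_feat, n_bc = self.counts.shape
        if len(self.feature_names) != n_feat or len(self.feature_ids) != n_feat:
            raise FormatError(
                f"matrix has {n_feat} rows but {len(self.feature_names)} feature "
                f"names / {len(self.feature_ids)} feature ids"
            )
        if len(self.barcodes) != n_bc:
            raise FormatError(
                f"matrix has {n_bc} columns but {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def per_barcode_totals(self) -> dict[str, int]:
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        return {bc: int(t) for bc, t in zip(self.barcodes, totals)}

    def subset_barcodes(self, barcodes: Sequence[str]) -> "GeneCellMatrix":
        index = {bc: i for i, bc in enumerate(self.barcodes)}
        missing = [bc for bc in barcodes if bc not in index]
        if missing:
            raise KeyError(f"barcodes not in matrix: {missing[:5]}")
        cols = [index[bc] for bc in barcodes]
        return GeneCellMatrix(
            counts=self.counts[:, cols],
            feature_names=list(self.feature_names),
            feature_ids=list(self.feature_ids),
            barcodes=list(barcodes),
        )


def _open_maybe_gz(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def _find(dirpath: Path, stem: str, alt: str | None = None) -> Path:
    for name in ([stem, f"{stem}.gz"] + ([alt, f"{alt}.gz"] if alt else [])):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{dirpath}: no {stem}[.gz]" + (f" or {alt}[.gz]" if alt else ""))


def read_mtx_triple(directory: str | os.PathLike) -> GeneCellMatrix:
    """Read a 10X-style directory: matrix.mtx + features.tsv + barcodes.tsv.

    Plain and gzipped variants are both accepted, as is the legacy
    ``genes.tsv`` name.  MatrixMarket 1-based coordinates become 0-based
    internal indices.  Header/TSV length mismatches and negative entries
    raise :class:`FormatError`.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv", "genes.tsv")
    bc_path = _find(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csc_matrix(mat)

    with _open_maybe_gz(feat_path) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    n_feat, n_bc = mat.shape
    if len(feat_rows) != n_feat:
        raise FormatError(
            f"{feat_path.name} lists {len(feat_rows)} features but the matrix "
            f"header declares {n_feat} rows"
        )
    if len(barcodes) != n_bc:
        raise FormatError(
            f"{bc_path.name} lists {len(barcodes)} barcodes but the matrix "
            f"header declares {n_bc} columns"
        )
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path.name}: negative count entry")

    feature_ids = [r[0] for r in feat_rows]
    feature_names = [r[1] if len(r) > 1 else r[0] for r in feat_rows]
    return GeneCellMatrix(
        counts=mat, feature_names=feature_names,
        feature_ids=feature_ids, barcodes=barcodes,
    )


def write_mtx_triple(
    matrix: GeneCellMatrix, directory: str | os.PathLike,
    feature_type: str = "Gene Expression",
) -> None:
    """Write the 10X triple (uncompressed) so it round-trips exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    with open(directory / "matrix.mtx", "w", encoding="utf-8") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n%\n")
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]} {coo.nnz}\n")
        order = np.lexsort((coo.row, coo.col))
        for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{r + 1} {c + 1} {int(v)}\n")
    with open(directory / "features.tsv", "w", encoding="utf-8") as fh:
        for fid, fname in zip(matrix.feature_ids, matrix.feature_names):
            fh.write(f"{fid}\t{fname}\t{feature_type}\n")
    with open(directory / "barcodes.tsv", "w", encoding="utf-8") as fh:
        fh.writelines(bc + "\n" for bc in matrix.barcodes)


# ---------------------------------------------------------------------------
# projections


@dataclass
class ProjectionTable:
    """2-D embedding coordinates (UMAP or t-SNE) keyed by barcode."""

    barcodes: list[str]
    coordinates: np.ndarray  # (n, 2)
    method: str = "UMAP"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise FormatError("coordinates must be an (n, 2) array")
        if len(self.barcodes) != self.coordinates.shape[0]:
            raise FormatError("one coordinate pair per barcode required")
        if self.method not in ("UMAP", "tSNE"):
            raise FormatError(f"unknown projection method {self.method!r}")

    def __len__(self) -> int:
        return len(self.barcodes)


_BARCODE_COLS = ("barcode", "Barcode", "barcodes", "cell", "Cell")


def read_projection(path: str | os.PathLike, method: str = "UMAP") -> ProjectionTable:
    """Read a projection CSV: one barcode column plus two numeric columns.

    Any column whose name matches a known barcode alias is used as the key;
    the first two remaining columns are the coordinates.  Rows with
    non-numeric coordinates are dropped with a warning; row order is kept.
    """
    df = pd.read_csv(path, dtype=str)
    bc_col = next((c for c in df.columns if c in _BARCODE_COLS), None)
    if bc_col is None:
        raise FormatError(
            f"{path}: no barcode column (expected one of {_BARCODE_COLS})"
        )
    coord_cols = [c for c in df.columns if c != bc_col][:2]
    if len(coord_cols) < 2:
        raise FormatError(f"{path}: need two coordinate columns")
    coords = df[coord_cols].apply(pd.to_numeric, errors="coerce")
    good = coords.notna().all(axis=1)
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) with non-numeric coordinates",
                       path, n_bad)
    return ProjectionTable(
        barcodes=df.loc[good, bc_col].tolist(),
        coordinates=coords.loc[good].to_numpy(dtype=float).reshape(-1, 2),
        method=method,
    )


def write_projection(table: ProjectionTable, path: str | os.PathLike) -> None:
    axis = "UMAP" if table.method == "UMAP" else "tSNE"
    df = pd.DataFrame({
        "Barcode": table.barcodes,
        f"{axis}-1": table.coordinates[:, 0],
        f"{axis}-2": table.coordinates[:, 1],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metrics summary CSV

_CANONICAL_KEYS = {
    "number of reads": "n_reads",
    "mean reads per cell": "mean_reads_per_cell",
    "estimated number of cells": "estimated_cells",
    "sequencing saturation": "sequencing_saturation",
    "fraction reads in cells": "fraction_reads_in_cells",
    "total genes detected": "total_genes_detected",
    "median genes per cell": "median_genes_per_cell",
}

_NUMBER_RE = re.compile(r"^-?[\d,]*\.?\d+%?$")


def parse_metric_value(raw: str) -> float | None:
    """Parse a CellRanger-style metric string to a number.

    Percent strings (``"91.2%"``) keep their percent scale (91.2); thousands
    separators (``"1,204"``) are stripped.  Unparseable input returns
    ``None``.
    """
    s = str(raw).strip().strip('"')
    if not s or not _NUMBER_RE.match(s):
        return None
    s = s.rstrip("%").replace(",", "")
    try:
        return float(s)
    except ValueError:  # pragma: no cover - regex should prevent this
        return None


def read_metrics_csv(
    path: str | os.PathLike, sample_id: str = "", library_type: str = "GEX",
) -> SampleQCMetrics:
    """Read a metrics summary CSV into :class:`SampleQCMetrics`.

    Both layouts produced in the wild are accepted: a single header row plus
    one value row (CellRanger ``metrics_summary.csv``), or two columns of
    key/value pairs.  Known metric names map onto canonical fields; unknown
    keys are preserved verbatim in ``extras``.  An unparseable numeric value
    warns and records the field as missing.
    """
    with open(path, encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if any(x.strip() for x in r)]
    if not rows:
        raise FormatError(f"{path}: empty metrics CSV")

    if all(len(r) == 2 for r in rows):
        pairs = [(r[0], r[1]) for r in rows]
        # a 2-column file may still be header+values; detect a header row
        if pairs and pairs[0][0].strip().lower() not in _CANONICAL_KEYS and \
                len(rows) == 2 and len(rows[0]) == len(rows[1]):
            maybe = list(zip(rows[0], rows[1]))
            if sum(k.strip().lower() in _CANONICAL_KEYS for k, _ in maybe) > \
                    sum(k.strip().lower() in _CANONICAL_KEYS for k, _ in pairs):
                pairs = maybe
    else:
        if len(rows) < 2:
            raise FormatError(f"{path}: expected a header row and a value row")
        pairs = list(zip(rows[0], rows[1]))

    kwargs: dict = {}
    extras: dict = {}
    for key, raw in pairs:
        canon = _CANONICAL_KEYS.get(key.strip().lower())
        value = parse_metric_value(raw)
        if canon is not None:
            if value is None:
                logger.warning("%s: metric %r has unparseable value %r; "
                               "recorded as missing", path, key, raw)
            kwargs[canon] = value
        else:
            extras[key.strip()] = value if value is not None else raw
    return SampleQCMetrics(
        sample_id=sample_id, library_type=library_type, extras=extras, **kwargs
    )


def write_metrics_csv(metrics: SampleQCMetrics, path: str | os.PathLike) -> None:
    """Write metrics in CellRanger key/value style with printed percent signs."""
    inverse = {v: k.title() for k, v in _CANONICAL_KEYS.items()}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        for field_name, label in inverse.items():
            v = getattr(metrics, field_name)
            if v is None:
                continue
            if field_name in ("sequencing_saturation", "fraction_reads_in_cells"):
                w.writerow([label, f"{v:.1f}%"])
            else:
                w.writerow([label, f"{v:,.0f}"])
        for k, v in metrics.extras.items():
            if isinstance(v, (int, float, str)):
                w.writerow([k, v])


# ---------------------------------------------------------------------------
# sample metadata sheet


@dataclass
class SampleMetadata:
    """The per-project sample sheet with a required "Library Type" column."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.table):
            if "sample_id" not in self.table.columns:
                raise FormatError("metadata sheet needs a sample_id column")
            if "library_type" not in self.table.columns:
                raise FormatError("metadata sheet needs a Library Type column")
            bad = set(self.table["library_type"]) - set(LIBRARY_TYPES)
            if bad:
                raise FormatError(f"unsupported library type(s): {sorted(bad)}")
            if self.table["sample_id"].duplicated().any():
                raise FormatError("sample_id values must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def library_types(self) -> list[str]:
        return sorted(set(self.table["library_type"]))


_META_ALIASES = {
    "sample": "sample_id", "sample_id": "sample_id", "sample id": "sample_id",
    "library type": "library_type", "library_type": "library_type",
}


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    df = pd.read_csv(path, dtype=str)
    df.columns = [_META_ALIASES.get(c.strip().lower(), c) for c in df.columns]
    return SampleMetadata(table=df)
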