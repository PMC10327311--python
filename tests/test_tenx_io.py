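import gzip
import logging

import numpy as np
import pytest

from conftest import make_matrix
from dropqc.tenx_io import (
    FormatError,
    SampleMetadata,
    parse_metric_value,
    read_metadata,
    read_metrics_csv,
    read_mtx_triple,
    read_projection,
    write_metrics_csv,
    write_mtx_triple,
)


def write_triple(tmp_path, mtx, features, barcodes, gz=False):
    def put(name, text):
        if gz:
            with gzip.open(tmp_path / (name + ".gz"), "wt") as fh:
                fh.write(text)
        else:
            (tmp_path / name).write_text(text)
    put("matrix.mtx", mtx)
    put("features.tsv", features)
    put("barcodes.tsv", barcodes)
    return tmp_path


MTX_3X2 = ("%%MatrixMarket matrix coordinate integer general\n"
           "3 2 2\n1 1 5\n3 2 2\n")
FEATURES_3 = "ID1\tA\tGene Expression\nID2\tB\tGene Expression\nID3\tC\tGene Expression\n"


class TestReadMtxTriple:
    @pytest.mark.parametrize("gz", [False, True], ids=["plain", "gzip"])
    def test_coordinates_map_to_dense_counts(self, tmp_path, gz):
        d = write_triple(tmp_path, MTX_3X2, FEATURES_3, "AAAC-1\nAAAG-1\n",
                         gz=gz)
        m = read_mtx_triple(d)
        assert m.counts.toarray().tolist() == [[5, 0], [0, 0], [0, 2]]
        assert m.feature_names == ["A", "B", "C"]
        assert m.barcodes == ["AAAC-1", "AAAG-1"]

    def test_empty_matrix_is_all_zero(self, tmp_path):
        mtx = "%%MatrixMarket matrix coordinate integer general\n10 4 0\n"
        feats = "".join(f"I{i}\tG{i}\tx\n" for i in range(10))
        bcs = "".join(f"B{i}\n" for i in range(4))
        m = read_mtx_triple(write_triple(tmp_path, mtx, feats, bcs))
        assert m.shape == (10, 4)
        assert m.counts.nnz == 0

    def test_barcode_count_mismatch_raises(self, tmp_path):
        mtx = "%%MatrixMarket matrix coordinate integer general\n3 4 0\n"
        d = write_triple(tmp_path, mtx, FEATURES_3, "A\nB\nC\n")
        with pytest.raises(FormatError, match="barcodes"):
            read_mtx_triple(d)

    def test_negative_entry_raises(self, tmp_path):
        mtx = ("%%MatrixMarket matrix coordinate integer general\n"
               "3 2 1\n1 1 -5\n")
        d = write_triple(tmp_path, mtx, FEATURES_3, "A\nB\n")
        with pytest.raises(FormatError, match="negative"):
            read_mtx_triple(d)

    def test_legacy_genes_tsv_accepted(self, tmp_path):
        d = write_triple(tmp_path, MTX_3X2, "x", "AAAC-1\nAAAG-1\n")
        (tmp_path / "features.tsv").unlink()
        (tmp_path / "genes.tsv").write_text(FEATURES_3)
        assert read_mtx_triple(d).feature_names == ["A", "B", "C"]


def test_mtx_round_trip_lossless(tmp_path):
    rng = np.random.default_rng(3)
    dense = rng.poisson(0.8, size=(30, 12))
    m = make_matrix(dense)
    write_mtx_triple(m, tmp_path)
    back = read_mtx_triple(tmp_path)
    assert (back.counts.toarray() == dense).all()
    assert back.feature_names == m.feature_names
    assert back.feature_ids == m.feature_ids
    assert back.barcodes == m.barcodes


def test_mtx_reader_agrees_with_scanpy(tmp_path):
    """Cross-check the 10X triple reader against scanpy's on the same dir."""
    sc = pytest.importorskip("scanpy")
    rng = np.random.default_rng(5)
    m = make_matrix(rng.poisson(1.0, size=(20, 8)))
    write_mtx_triple(m, tmp_path)
    # scanpy's uncompressed reader expects the legacy genes.tsv name
    (tmp_path / "features.tsv").rename(tmp_path / "genes.tsv")
    ours = read_mtx_triple(tmp_path)
    theirs = sc.read_10x_mtx(tmp_path, var_names="gene_ids")
    assert (theirs.X.toarray().T == ours.counts.toarray()).all()
    assert list(theirs.obs_names) == ours.barcodes
    assert list(theirs.var_names) == ours.feature_ids


class TestReadProjection:
    def test_one_row(self, tmp_path):
        p = tmp_path / "u.csv"
        p.write_text("Barcode,UMAP-1,UMAP-2\nAAAC,1.0,2.0\n")
        t = read_projection(p, method="UMAP")
        assert t.barcodes == ["AAAC"]
        assert t.coordinates.tolist() == [[1.0, 2.0]]

    def test_non_numeric_row_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "u.csv"
        p.write_text("Barcode,UMAP-1,UMAP-2\nA,1.0,2.0\nB,NA,3.0\nC,4.0,5.0\n")
        with caplog.at_level(logging.WARNING):
            t = read_projection(p)
        assert t.barcodes == ["A", "C"]  # order preserved
        assert any("non-numeric" in r.message for r in caplog.records)

    def test_header_only_is_valid_empty(self, tmp_path):
        p = tmp_path / "u.csv"
        p.write_text("Barcode,UMAP-1,UMAP-2\n")
        assert len(read_projection(p)) == 0

    def test_missing_barcode_column_raises(self, tmp_path):
        p = tmp_path / "u.csv"
        p.write_text("X,Y,Z\n1,2,3\n")
        with pytest.raises(FormatError, match="barcode"):
            read_projection(p)


@pytest.mark.parametrize("raw,expected", [
    ("45.1%", 45.1),
    ('8,120', 8120.0),
    ("91.2%", 91.2),
    ("1,204", 1204.0),
    ("0", 0.0),
    ("abc", None),
    ("", None),
])
def test_parse_metric_value(raw, expected):
    assert parse_metric_value(raw) == expected


class TestReadMetricsCsv:
    def test_key_value_layout(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text('Sequencing Saturation,45.1%\n'
                     'Estimated Number of Cells,"8,120"\n'
                     'Some Custom Metric,7\n')
        m = read_metrics_csv(p)
        assert m.sequencing_saturation == 45.1
        assert m.estimated_cells == 8120
        assert m.extras["Some Custom Metric"] == 7.0

    def test_single_row_layout(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text('Estimated Number of Cells,Mean Reads per Cell,'
                     'Sequencing Saturation\n"1,234","50,000",91.2%\n')
        m = read_metrics_csv(p)
        assert m.estimated_cells == 1234
        assert m.mean_reads_per_cell == 50000
        assert m.sequencing_saturation == 91.2

    def test_unparseable_value_missing_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.csv"
        p.write_text("Mean Reads per Cell,abc\n")
        with caplog.at_level(logging.WARNING):
            m = read_metrics_csv(p)
        assert m.mean_reads_per_cell is None
        assert any("unparseable" in r.message for r in caplog.records)

    def test_round_trip_preserves_percent_scale(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("Sequencing Saturation,45.1%\n"
                     "Fraction Reads in Cells,91.2%\n")
        m = read_metrics_csv(p)
        out = tmp_path / "out.csv"
        write_metrics_csv(m, out)
        back = read_metrics_csv(out)
        assert back.sequencing_saturation == 45.1
        assert back.fraction_reads_in_cells == 91.2


class TestSampleMetadata:
    def test_reader_normalizes_library_type_column(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("Sample,Library Type\ns1,GEX\ns2,VDJ\n")
        meta = read_metadata(p)
        assert meta.sample_ids == ["s1", "s2"]
        assert meta.library_types == ["GEX", "VDJ"]

    def test_unknown_library_type_rejected(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("sample_id,library_type\ns1,RNA\n")
        with pytest.raises(FormatError, match="library type"):
            read_metadata(p)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("sample_id,library_type\ns1,GEX\ns1,GEX\n")
        with pytest.raises(FormatError, match="unique"):
            read_metadata(p)
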