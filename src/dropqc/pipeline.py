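"""Per-sample orchestration: read inputs, score, call cells.

One :func:`run_sample` call takes a CellRanger-style sample directory plus a
reference gene-set collection and produces everything the report needs: the
count matrix, the barcode-rank curve with knee/inflection and SKP/EB call
vectors, and the per-cell enrichment result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .barcode_rank import (
    BarcodeRankCurve,
    build_curve,
    detect_knee_inflection,
    expression_based_calls,
)
from .enrichment import DEFAULT_MAX_RANK_FRACTION, EnrichmentResult, enrich
from .qc_metrics import SampleQCMetrics
from .reference_sets import ReferenceGeneSetCollection
from .tenx_io import (
    GeneCellMatrix,
    ProjectionTable,
    read_metrics_csv,
    read_mtx_triple,
    read_projection,
)

logger = logging.getLogger(__name__)


@dataclass
class SampleRun:
    """All per-sample results needed downstream."""

    sample_id: str
    matrix: GeneCellMatrix
    curve: BarcodeRankCurve
    enrichment: EnrichmentResult
    metrics: SampleQCMetrics | None = None
    projections: dict[str, ProjectionTable] = field(default_factory=dict)


def call_cells(
    matrix: GeneCellMatrix,
    collection: ReferenceGeneSetCollection,
    max_rank_fraction: float = DEFAULT_MAX_RANK_FRACTION,
    seed: int = 0,
    case_insensitive: bool = False,
) -> tuple[BarcodeRankCurve, EnrichmentResult]:
    """Depth-based then expression-based cell calling on a raw matrix.

    Builds the barcode-rank curve, detects its knee and inflection, scores
    the barcodes at or above the inflection (the SKP calls) against the
    reference sets, and sets the SKP/EB call vectors on the curve.
    """
    curve = build_curve(matrix.per_barcode_totals())
    detect_knee_inflection(curve)
    above = list(curve.barcodes[: curve.inflection_index + 1])
    sub = matrix.subset_barcodes(above)
    result = enrich(sub, collection, max_rank_fraction=max_rank_fraction,
                    seed=seed, case_insensitive=case_insensitive)
    expression_based_calls(curve, result)
    return curve, result


def run_sample(
    sample_dir: str | Path,
    collection: ReferenceGeneSetCollection,
    sample_id: str | None = None,
    max_rank_fraction: float = DEFAULT_MAX_RANK_FRACTION,
    seed: int = 0,
    case_insensitive: bool = False,
) -> SampleRun:
    """Run the expression-based QC workflow on one sample directory.

    The barcode-rank curve is built from per-barcode totals of the raw
    matrix; barcodes at or above the inflection point (the SKP calls) are
    scored against the reference sets, and the EB refinement flags those
    that enrich for no set as noise.
    """
    sample_dir = Path(sample_dir)
    sample_id = sample_id or sample_dir.name
    matrix = read_mtx_triple(sample_dir)
    curve, result = call_cells(
        matrix, collection, max_rank_fraction=max_rank_fraction,
        seed=seed, case_insensitive=case_insensitive)
    logger.info("%s: %d/%d barcodes above the inflection point",
                sample_id, int(curve.skp_calls.sum()), len(curve))

    metrics = None
    metrics_path = sample_dir / "metrics_summary.csv"
    if metrics_path.exists():
        metrics = read_metrics_csv(metrics_path, sample_id=sample_id)
        metrics.sample_id = sample_id

    projections: dict[str, ProjectionTable] = {}
    for fname, method in (("umap_projection.csv", "UMAP"),
                          ("tsne_projection.csv", "tSNE")):
        p = sample_dir / fname
        if p.exists():
            projections[method] = read_projection(p, method=method)

    return SampleRun(sample_id=sample_id, matrix=matrix, curve=curve,
                     enrichment=result, metrics=metrics,
                     projections=projections)
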