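"""Per-sample QC metrics, multi-run aggregation, and adequacy checks.

Conventions: every saturation/fraction metric is kept on the printed percent
scale (45.1 means 45.1%), matching CellRanger summary output.  Read and cell
counts are plain non-negative numbers.  Missing metrics are ``None``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Sequence

logger = logging.getLogger(__name__)

LIBRARY_TYPES = ("GEX", "VDJ", "CITE", "HTO-CMO", "mxATAC", "ATAC")

#: Floors below which cell-type enrichment becomes unreliable (percent).
MIN_SEQUENCING_SATURATION = 11.3
MIN_FRACTION_READS_IN_CELLS = 15.5
#: Recommended depth for 1,200-4,000 genes per cell.
RECOMMENDED_READS_PER_CELL = 50_000

_PERCENT_FIELDS = ("sequencing_saturation", "fraction_reads_in_cells")
_COUNT_FIELDS = (
    "n_reads",
    "mean_reads_per_cell",
    "estimated_cells",
    "total_genes_detected",
    "median_genes_per_cell",
)


@dataclass
class SampleQCMetrics:
    """Canonical QC metrics for one sample (one sequencing run).

    ``extras`` preserves any metric keys not mapped to a canonical field,
    verbatim as parsed.
    """

    sample_id: str = ""
    library_type: str = "GEX"
    n_reads: float | None = None
    mean_reads_per_cell: float | None = None
    estimated_cells: float | None = None
    sequencing_saturation: float | None = None  # percent, 0-100
    fraction_reads_in_cells: float | None = None  # percent, 0-100
    total_genes_detected: float | None = None
    median_genes_per_cell: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_type not in LIBRARY_TYPES:
            raise ValueError(
                f"library_type must be one of {LIBRARY_TYPES}, "
                f"got {self.library_type!r}"
            )
        for name in _PERCENT_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def as_dict(self) -> dict:
        out = {}
        for f in fields(self):
            if f.name == "extras":
                continue
            out[f.name] = getattr(self, f.name)
        out.update(self.extras)
        return out


def sequencing_saturation(n_reads: float, n_unique: float) -> float | None:
    """Percent of reads that are duplicates: ``100 * (1 - n_unique/n_reads)``.

    Returns ``None`` (recorded missing) when ``n_reads`` is zero.
    """
    if n_reads == 0:
        logger.warning("sequencing saturation undefined for zero reads")
        return None
    if not (0 <= n_unique <= n_reads):
        raise ValueError("need 0 <= n_unique <= n_reads")
    return 100.0 * (1.0 - n_unique / n_reads)


def _run_weight(m: SampleQCMetrics) -> float:
    """Read-depth weight for one run."""
    if m.n_reads is not None:
        return float(m.n_reads)
    if m.mean_reads_per_cell is not None and m.estimated_cells is not None:
        return float(m.mean_reads_per_cell) * float(m.estimated_cells)
    raise ValueError(
        f"run {m.sample_id!r}: cannot determine read count for GML weighting "
        "(need n_reads, or mean_reads_per_cell and estimated_cells)"
    )


def aggregate_gml(runs: Sequence[SampleQCMetrics]) -> SampleQCMetrics:
    """Aggregate several sequencing runs of the same library (GML).

    Read counts are summed; percentage metrics are combined as read-count
    weighted means; ``estimated_cells`` and per-cell gene counts are taken
    from the deepest run; ``mean_reads_per_cell`` is recomputed from the
    summed depth.  Provenance of each aggregated field is recorded under
    ``extras["gml_provenance"]``.  Mixing library types is an error; a single
    run is returned unchanged with a warning.
    """
    if not runs:
        raise ValueError("aggregate_gml needs at least one run")
    if len({m.sample_id for m in runs}) != 1:
        raise ValueError("GML aggregation requires a single shared sample_id")
    if len({m.library_type for m in runs}) != 1:
        raise ValueError(
            "GML aggregation cannot mix library types: "
            f"{sorted({m.library_type for m in runs})}"
        )
    if len(runs) == 1:
        logger.warning(
            "aggregate_gml called with a single run (%s); returned unchanged",
            runs[0].sample_id,
        )
        return runs[0]

    weights = [_run_weight(m) for m in runs]
    total = sum(weights)
    deepest = runs[max(range(len(runs)), key=lambda i: weights[i])]

    def wmean(name: str) -> float | None:
        pairs = [
            (w, getattr(m, name)) for w, m in zip(weights, runs)
            if getattr(m, name) is not None
        ]
        if not pairs:
            return None
        wsum = sum(w for w, _ in pairs)
        return sum(w * v for w, v in pairs) / wsum

    provenance = {
        "n_runs": len(runs),
        "n_reads": "sum",
        "sequencing_saturation": "read-weighted mean",
        "fraction_reads_in_cells": "read-weighted mean",
        "estimated_cells": "deepest run",
        "total_genes_detected": "deepest run",
        "median_genes_per_cell": "deepest run",
        "mean_reads_per_cell": "summed reads / deepest-run cells",
        "run_weights": weights,
    }
    cells = deepest.estimated_cells
    return SampleQCMetrics(
        sample_id=runs[0].sample_id,
        library_type=runs[0].library_type,
        n_reads=total,
        mean_reads_per_cell=(total / cells if cells else None),
        estimated_cells=cells,
        sequencing_saturation=wmean("sequencing_saturation"),
        fraction_reads_in_cells=wmean("fraction_reads_in_cells"),
        total_genes_detected=deepest.total_genes_detected,
        median_genes_per_cell=deepest.median_genes_per_cell,
        extras={"gml_provenance": provenance},
    )


@dataclass
class AdequacyVerdict:
    """Outcome of the enrichment-adequacy check for one sample."""

    sample_id: str
    checks: list[tuple[str, str, str]]  # (check name, verdict, message)

    @property
    def overall(self) -> str:
        verdicts = [v for _, v, _ in self.checks]
        if "warn" in verdicts:
            return "warn"
        if "unknown" in verdicts:
            return "unknown"
        return "pass"


def adequacy_check(
    metrics: SampleQCMetrics,
    min_saturation: float = MIN_SEQUENCING_SATURATION,
    min_frac_in_cells: float = MIN_FRACTION_READS_IN_CELLS,
) -> AdequacyVerdict:
    """Check whether a sample is deep enough for cell-type enrichment.

    Comparisons are inclusive at the floors.  Shortfalls warn rather than
    fail: shallow samples still run, with a visible caveat.  A missing metric
    yields verdict ``unknown`` for that check.  When mean reads per cell is
    below :data:`RECOMMENDED_READS_PER_CELL` the depth message cites the
    recommended target.
    """
    checks: list[tuple[str, str, str]] = []

    def bounded(name: str, value: float | None, floor: float) -> None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            checks.append((name, "unknown", f"{name} is missing"))
        elif value >= floor:
            checks.append((name, "pass", f"{name} {value:.1f}% >= {floor}%"))
        else:
            checks.append(
                (name, "warn",
                 f"{name} {value:.1f}% is below the {floor}% floor; "
                 "enrichment-based QC may be unreliable")
            )

    bounded("sequencing_saturation", metrics.sequencing_saturation, min_saturation)
    bounded("fraction_reads_in_cells", metrics.fraction_reads_in_cells,
            min_frac_in_cells)

    mrpc = metrics.mean_reads_per_cell
    if mrpc is None:
        checks.append(("mean_reads_per_cell", "unknown",
                       "mean_reads_per_cell is missing"))
    elif mrpc < RECOMMENDED_READS_PER_CELL:
        checks.append(
            ("mean_reads_per_cell", "warn",
             f"mean reads per cell {mrpc:,.0f} is below the recommended "
             f"{RECOMMENDED_READS_PER_CELL:,} reads per cell "
             "(about 1,200 to 4,000 genes per cell)")
        )
    else:
        checks.append(("mean_reads_per_cell", "pass",
                       f"mean reads per cell {mrpc:,.0f}"))
    return AdequacyVerdict(sample_id=metrics.sample_id, checks=checks)
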