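"""Synthetic droplet scRNA-seq experiments with planted ground truth.

The generator emulates the data regime the QC workflow is built for: a few
hundred real cells of several types, each over-expressing an exclusive
marker-gene signature; a small population of *ambient* barcodes that sit in
the above-knee count range but draw from the pooled soup profile of all
cells (the droplets that depth-based calling keeps and expression-based QC
should reject); and a large tail of near-empty droplets sampling the same
soup at a tiny scale.  Real-cell counts are negative-binomial (scRNA-seq is
overdispersed relative to Poisson); soup droplets are Poisson around the
pooled mean profile.  Everything is reproducible from one seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .qc_metrics import SampleQCMetrics, sequencing_saturation
from .reference_sets import GeneSet, ReferenceGeneSetCollection
from .tenx_io import (
    GeneCellMatrix,
    ProjectionTable,
    write_metrics_csv,
    write_mtx_triple,
    write_projection,
)
from .reference_sets import write_gmt

AMBIENT_LABEL = "ambient"
EMPTY_LABEL = "empty"


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sample.

    Rates are mean molecule counts per gene per droplet.  The defaults give
    a strong-signal three-type mixture: 25 exclusive markers per type at a
    mean of 20 against a background of 0.2, with 5% of above-knee barcodes
    ambient and a deep tail of empty droplets at ~2% of a real cell's depth.
    """

    n_cell_types: int = 3
    markers_per_type: int = 25
    cells_per_type: int = 200
    n_background_genes: int = 500
    marker_expression_rate: float = 20.0
    background_rate: float = 0.2
    dispersion: float = 2.0           # NB size parameter; smaller = noisier
    ambient_fraction: float = 0.05    # fraction of above-knee barcodes
    ambient_scale: float = 1.0        # ambient depth / median real-cell depth
    n_empty_droplets: int = 5000
    empty_scale: float = 0.02         # empty depth / median real-cell depth
    duplication_rate: float = 0.45    # drives synthetic sequencing saturation
    seed: int = 0
    marker_gene_sets: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.markers_per_type,
               self.cells_per_type) < 1:
            raise SimulationConfigError(
                "need at least one cell type, marker, and cell per type")
        for name in ("ambient_fraction", "empty_scale", "duplication_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationConfigError(f"{name} must lie in [0, 1]")
        for name in ("marker_expression_rate", "background_rate",
                     "dispersion", "ambient_scale"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if self.n_empty_droplets < 0 or self.n_background_genes < 0:
            raise SimulationConfigError("counts must be >= 0")
        if self.marker_gene_sets is not None:
            if len(self.marker_gene_sets) != self.n_cell_types:
                raise SimulationConfigError(
                    "marker_gene_sets must supply one set per cell type")
            flat = [g for s in self.marker_gene_sets for g in s]
            if len(set(flat)) != len(flat):
                raise SimulationConfigError(
                    "planted marker sets must be exclusive: a gene appears "
                    "in more than one cell type's set")

    def type_names(self) -> list[str]:
        return [f"Type{chr(ord('A') + t)}" for t in range(self.n_cell_types)]

    def marker_symbols(self) -> list[tuple[str, ...]]:
        if self.marker_gene_sets is not None:
            return [tuple(s) for s in self.marker_gene_sets]
        return [
            tuple(f"MK{t}G{i}" for i in range(self.markers_per_type))
            for t in range(self.n_cell_types)
        ]


@dataclass
class SimulatedExperiment:
    """One simulated sample plus its ground truth."""

    matrix: GeneCellMatrix                 # all droplets, empties included
    truth: pd.Series                       # barcode -> type name | ambient | empty
    collection: ReferenceGeneSetCollection
    projections: dict[str, ProjectionTable]  # method -> table (cells only)
    metrics: SampleQCMetrics
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def cell_barcodes(self) -> list[str]:
        """Above-knee barcodes: real cells and planted ambient droplets."""
        keep = self.truth[self.truth != EMPTY_LABEL]
        return list(keep.index)


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(alphabet, size=16)) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with mean `mean` and size `dispersion`."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a full 10X-style sample with planted truth labels."""
    rng = np.random.default_rng(config.seed)
    type_names = config.type_names()
    marker_sets = config.marker_symbols()

    feature_names: list[str] = [g for s in marker_sets for g in s]
    marker_slices = []
    start = 0
    for s in marker_sets:
        marker_slices.append(np.arange(start, start + len(s)))
        start += len(s)
    feature_names += [f"BG{j}" for j in range(config.n_background_genes)]
    n_features = len(feature_names)
    feature_ids = [f"SYNGENE{i:05d}" for i in range(n_features)]

    n_real = config.n_cell_types * config.cells_per_type
    # ambient_fraction is over above-knee barcodes (real + ambient)
    n_ambient = int(round(
        n_real * config.ambient_fraction / (1.0 - config.ambient_fraction)
    )) if config.ambient_fraction > 0 else 0
    n_empty = config.n_empty_droplets

    # real cells: exclusive marker signature over a flat background
    real = np.empty((n_features, n_real), dtype=np.int64)
    cell_types = np.repeat(np.arange(config.n_cell_types),
                           config.cells_per_type)
    base = np.full(n_features, config.background_rate)
    for j, t in enumerate(cell_types):
        mean = base.copy()
        mean[marker_slices[t]] = config.marker_expression_rate
        real[:, j] = _nb_draw(rng, mean, config.dispersion)

    # soup profile: pooled mean of all real cells, renormalised
    pooled = real.sum(axis=1).astype(float)
    pooled_p = pooled / pooled.sum() if pooled.sum() > 0 else \
        np.full(n_features, 1.0 / n_features)
    median_depth = float(np.median(real.sum(axis=0)))

    ambient = rng.poisson(
        config.ambient_scale * median_depth * pooled_p[:, None],
        size=(n_features, n_ambient),
    ) if n_ambient else np.empty((n_features, 0), dtype=np.int64)
    empty = rng.poisson(
        config.empty_scale * median_depth * pooled_p[:, None],
        size=(n_features, n_empty),
    ) if n_empty else np.empty((n_features, 0), dtype=np.int64)

    dense = np.concatenate([real, ambient, empty], axis=1)
    n_total = dense.shape[1]
    barcodes = _random_barcodes(rng, n_total)
    labels = (
        [type_names[t] for t in cell_types]
        + [AMBIENT_LABEL] * n_ambient
        + [EMPTY_LABEL] * n_empty
    )
    # shuffle droplet order so column position carries no information
    perm = rng.permutation(n_total)
    dense = dense[:, perm]
    barcodes = [barcodes[i] for i in perm]
    labels = [labels[i] for i in perm]

    matrix = GeneCellMatrix(
        counts=sp.csc_matrix(dense),
        feature_names=feature_names,
        feature_ids=feature_ids,
        barcodes=barcodes,
    )
    truth = pd.Series(labels, index=barcodes, name="truth")

    collection = ReferenceGeneSetCollection(
        sets=[
            GeneSet(name=type_names[t], genes=marker_sets[t], species="other")
            for t in range(config.n_cell_types)
        ],
        source=f"synthetic planted markers (seed={config.seed})",
    )

    # deterministic 2-D embedding of the above-knee droplets
    keep = [i for i, lb in enumerate(labels) if lb != EMPTY_LABEL]
    cells_log = np.log1p(dense[:, keep].T)
    n_comp = 2 if min(cells_log.shape) >= 2 else 1
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    coords = pca.fit_transform(cells_log)
    if n_comp == 1:
        coords = np.hstack([coords, np.zeros_like(coords)])
    cell_bcs = [barcodes[i] for i in keep]
    projections = {
        "UMAP": ProjectionTable(barcodes=cell_bcs, coordinates=coords,
                                method="UMAP"),
        "tSNE": ProjectionTable(barcodes=cell_bcs,
                                coordinates=coords[:, ::-1] * 3.0,
                                method="tSNE"),
    }

    # sequencing metrics implied by the planted duplication rate
    n_umis = int(dense.sum())
    n_reads = int(round(n_umis / (1.0 - config.duplication_rate))) \
        if config.duplication_rate < 1 else n_umis
    umis_in_cells = int(dense[:, keep].sum())
    n_called = len(keep)
    genes_per_cell = (dense[:, keep] > 0).sum(axis=0)
    metrics = SampleQCMetrics(
        sample_id="synthetic",
        library_type="GEX",
        n_reads=n_reads,
        mean_reads_per_cell=(n_reads / n_called if n_called else None),
        estimated_cells=n_called,
        sequencing_saturation=sequencing_saturation(n_reads, n_umis),
        fraction_reads_in_cells=100.0 * umis_in_cells / n_umis
        if n_umis else None,
        total_genes_detected=int((dense[:, keep].sum(axis=1) > 0).sum()),
        median_genes_per_cell=float(np.median(genes_per_cell))
        if n_called else None,
    )
    return SimulatedExperiment(
        matrix=matrix, truth=truth, collection=collection,
        projections=projections, metrics=metrics, config=config,
    )


def write_sample_dir(
    experiment: SimulatedExperiment, directory: str | os.PathLike,
    sample_id: str = "synthetic_sample",
) -> Path:
    """Write a complete per-sample 10X-style directory.

    Contents: MTX triple, UMAP/t-SNE projection CSVs, metrics CSV, one-row
    metadata CSV, the planted reference sets as GMT, a truth-labels CSV and
    a JSON manifest recording the full configuration and seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mtx_triple(experiment.matrix, directory)
    write_projection(experiment.projections["UMAP"],
                     directory / "umap_projection.csv")
    write_projection(experiment.projections["tSNE"],
                     directory / "tsne_projection.csv")
    metrics = dataclasses.replace(experiment.metrics, sample_id=sample_id)
    write_metrics_csv(metrics, directory / "metrics_summary.csv")
    pd.DataFrame(
        {"sample_id": [sample_id], "library_type": ["GEX"],
         "batch": ["sim"]}
    ).to_csv(directory / "metadata.csv", index=False)
    write_gmt(experiment.collection, directory / "reference_sets.gmt")
    experiment.truth.rename("truth").to_frame().rename_axis("barcode") \
        .to_csv(directory / "truth_labels.csv")
    manifest = {
        "sample_id": sample_id,
        "seed": experiment.config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(experiment.config).items()
        },
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory
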