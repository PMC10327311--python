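"""Static multi-sample HTML QC report.

One self-contained HTML file with four sections — experimental workflow,
data processing workflow, samples information and QC metrics, data analysis
and quality control — plus a zip archive bundling the HTML with every
tabular export.  All figures are matplotlib SVG embedded inline, so the file
opens in any browser with no server and no external asset fetches.  With a
fixed timestamp the same bundle always renders byte-identical output.

A fixed layering rule applies to every scatter that shows the SKP−EB
complement (depth-called barcodes rejected by expression): complement points
are drawn *after* the called cells so the flagged background is never hidden
underneath.
"""

from __future__ import annotations

import html
import io
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .enrichment import NOISE_LABEL, EnrichmentResult  # noqa: E402
from .pipeline import SampleRun  # noqa: E402
from .qc_metrics import AdequacyVerdict, SampleQCMetrics, adequacy_check  # noqa: E402
from .tenx_io import SampleMetadata  # noqa: E402

logger = logging.getLogger(__name__)

SECTION_TITLES = (
    "Experimental workflow",
    "Data processing workflow",
    "Samples information and QC metrics",
    "Data analysis and quality control",
)

_WORKFLOW_TEXT = {
    "GEX": ("Gene expression (GEX): single-cell 3'/5' transcriptome "
            "libraries; reads are aligned, deduplicated by UMI and "
            "assigned to cell barcodes to form the feature-barcode matrix."),
    "VDJ": ("V(D)J: targeted enrichment of T/B-cell receptor transcripts; "
            "contigs are assembled per barcode and paired with the matched "
            "GEX library where present."),
    "CITE": ("CITE-seq: antibody-derived tags counted alongside the "
             "transcriptome to quantify surface proteins per cell."),
    "HTO-CMO": ("Hashing (HTO/CMO): oligo-tagged samples pooled and "
                "demultiplexed from tag counts."),
    "ATAC": ("ATAC: transposase-accessible chromatin fragments counted "
             "per barcode."),
    "mxATAC": ("Multiome ATAC: joint chromatin accessibility and gene "
               "expression from the same nuclei."),
}

_CELL_COLORS = plt.get_cmap("tab10")
_COMPLEMENT_COLOR = "#d62728"  # red; drawn last so it stays visible
_CALLED_COLOR = "#1f77b4"


@dataclass
class ReportBundle:
    """Everything the report renders, for a set of samples."""

    metadata: SampleMetadata
    runs: dict[str, SampleRun]
    gml_groups: dict[str, list[SampleQCMetrics]] = field(default_factory=dict)
    title: str = "Single-cell QC report"
    seed: int | None = None
    min_saturation: float | None = None
    min_frac_in_cells: float | None = None

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("report bundle contains no samples")
        meta_ids = set(self.metadata.sample_ids)
        missing = sorted(meta_ids - set(self.runs))
        if missing:
            raise ValueError(
                f"metadata names sample(s) with no inputs: {missing}")
        for sid, run in self.runs.items():
            if run.metrics is None:
                raise ValueError(f"sample {sid!r} has no QC metrics record")


def summarize_composition(
    results: dict[str, EnrichmentResult],
) -> pd.DataFrame:
    """Per-sample cell-type proportions over (assigned types + noise).

    Each non-empty row sums to 1.  A sample with an empty assignment vector
    yields an all-zero row and a warning.
    """
    if not results:
        raise ValueError("need at least one sample")
    labels = sorted({
        lb for r in results.values() for lb in r.assignment.unique()
    } | {NOISE_LABEL})
    rows = {}
    for sid, r in results.items():
        n = len(r.assignment)
        if n == 0:
            logger.warning("sample %r has an empty assignment vector", sid)
            rows[sid] = {lb: 0.0 for lb in labels}
            continue
        frac = r.assignment.value_counts(normalize=True)
        rows[sid] = {lb: float(frac.get(lb, 0.0)) for lb in labels}
    df = pd.DataFrame.from_dict(rows, orient="index")[labels]
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# figures


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg"):]


def _label_colors(labels: list[str]) -> dict[str, tuple]:
    ordered = sorted(lb for lb in labels if lb != NOISE_LABEL)
    colors = {lb: _CELL_COLORS(i % 10) for i, lb in enumerate(ordered)}
    colors[NOISE_LABEL] = (0.6, 0.6, 0.6, 1.0)
    return colors


def _scatter_with_complement(ax, xy_called, xy_comp, called_colors,
                             point_size=8.0):
    """Called cells first, SKP−EB complement last (fixed z-order rule)."""
    h = ax.scatter(xy_called[:, 0], xy_called[:, 1], s=point_size,
                   c=called_colors, linewidths=0)
    h.set_gid("called-cells-layer")
    h2 = ax.scatter(xy_comp[:, 0], xy_comp[:, 1], s=point_size * 1.5,
                    c=_COMPLEMENT_COLOR, linewidths=0, zorder=5)
    h2.set_gid("skp-minus-eb-layer")


def projection_figure(run: SampleRun, method: str) -> str | None:
    proj = run.projections.get(method)
    if proj is None:
        return None
    labels = run.enrichment.assignment
    comp_bcs = set(run.curve.barcodes[run.curve.complement].astype(str))
    colors = _label_colors(list(labels.unique()))
    in_res = [bc in labels.index for bc in proj.barcodes]
    xy = proj.coordinates[in_res]
    bcs = [bc for bc, ok in zip(proj.barcodes, in_res) if ok]
    comp_mask = np.array([bc in comp_bcs for bc in bcs], dtype=bool)
    point_colors = [colors[labels[bc]] for bc, c in zip(bcs, comp_mask)
                    if not c]
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    _scatter_with_complement(ax, xy[~comp_mask], xy[comp_mask], point_colors)
    ax.set_xlabel(f"{method} 1")
    ax.set_ylabel(f"{method} 2")
    ax.set_title(f"{run.sample_id}: {method} by assigned type")
    for lb, c in sorted(colors.items()):
        ax.scatter([], [], s=12, c=[c], label=lb)
    ax.scatter([], [], s=12, c=_COMPLEMENT_COLOR, label="SKP−EB")
    ax.legend(fontsize=6, markerscale=1.2, frameon=False, loc="best")
    fig.tight_layout()
    return _fig_to_svg(fig)


def quantification_figure(run: SampleRun) -> str:
    """Total UMI vs detected genes per above-knee barcode, SKP−EB on top."""
    curve = run.curve
    skp_bcs = curve.barcodes[curve.skp_calls].astype(str)
    sub = run.matrix.subset_barcodes(list(skp_bcs))
    umis = np.asarray(sub.counts.sum(axis=0)).ravel()
    genes = np.asarray((sub.counts > 0).sum(axis=0)).ravel()
    comp_bcs = set(curve.barcodes[curve.complement].astype(str))
    comp_mask = np.array([bc in comp_bcs for bc in skp_bcs], dtype=bool)
    xy = np.column_stack([umis, genes]).astype(float)
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    _scatter_with_complement(
        ax, xy[~comp_mask], xy[comp_mask],
        [_CALLED_COLOR] * int((~comp_mask).sum()))
    ax.set_xlabel("Total UMI per barcode")
    ax.set_ylabel("Detected genes per barcode")
    ax.set_title(f"{run.sample_id}: quantification (SKP−EB in red)")
    fig.tight_layout()
    return _fig_to_svg(fig)


def barcode_rank_figure(run: SampleRun, refined: bool) -> str:
    curve = run.curve
    ranks = np.arange(1, len(curve) + 1)
    pos = curve.counts > 0
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    if refined:
        called = pos & curve.eb_calls
        comp = pos & curve.complement
        rest = pos & ~curve.skp_calls
        ax.loglog(ranks[rest], curve.counts[rest], ".", ms=3,
                  color="0.7", label="below inflection")
        h = ax.loglog(ranks[called], curve.counts[called], ".", ms=3,
                      color=_CALLED_COLOR, label="EB cells")[0]
        h.set_gid("called-cells-layer")
        h2 = ax.loglog(ranks[comp], curve.counts[comp], ".", ms=4,
                       color=_COMPLEMENT_COLOR, label="SKP−EB", zorder=5)[0]
        h2.set_gid("skp-minus-eb-layer")
        title = "refined barcode rank (expression-based)"
    else:
        ax.loglog(ranks[pos], curve.counts[pos], "-", color=_CALLED_COLOR)
        title = "barcode rank"
    for idx, name, style in ((curve.knee_index, "knee", "--"),
                             (curve.inflection_index, "inflection", ":")):
        if idx is not None:
            ax.axvline(idx + 1, linestyle=style, color="0.3", lw=0.8)
            ax.annotate(name, (idx + 1, curve.counts.max()), fontsize=6)
    if curve.no_distinct_knee:
        title += " — no distinct knee"
    ax.set_xlabel("Barcode rank")
    ax.set_ylabel("Total count")
    ax.set_title(f"{run.sample_id}: {title}", fontsize=9)
    if refined:
        ax.legend(fontsize=6, frameon=False)
    fig.tight_layout()
    return _fig_to_svg(fig)


def heatmap_figure(run: SampleRun, zscale: bool = True) -> str:
    """Mean expression of each set's genes per assigned cell type.

    Rows are marker genes grouped by set, columns are assigned types; values
    are per-gene z-scaled means by default (raw means optional).
    """
    res = run.enrichment
    labels = res.assignment
    types = sorted(lb for lb in labels.unique() if lb != NOISE_LABEL)
    if not types:
        types = [NOISE_LABEL]
    sub = run.matrix.subset_barcodes(list(labels.index))
    gene_rows, gene_names = [], []
    assert res.match is not None
    for name in res.auc.columns:
        for gi in res.match.matches[name].indices:
            gene_rows.append(gi)
            gene_names.append(run.matrix.feature_names[gi])
    dense = np.asarray(sub.counts[gene_rows, :].todense(), dtype=float)
    means = np.zeros((len(gene_rows), len(types)))
    for k, t in enumerate(types):
        mask = (labels == t).to_numpy()
        if mask.any():
            means[:, k] = dense[:, mask].mean(axis=1)
    if zscale:
        mu = means.mean(axis=1, keepdims=True)
        sd = means.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        means = (means - mu) / sd
    fig, ax = plt.subplots(figsize=(3.4, 0.09 * len(gene_rows) + 1.2))
    im = ax.imshow(means, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(types)), types, fontsize=6, rotation=45)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(gene_rows)} marker genes (grouped by set)",
                  fontsize=6)
    ax.set_title(f"{run.sample_id}: marker expression by assigned type",
                 fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    return _fig_to_svg(fig)


# ---------------------------------------------------------------------------
# HTML assembly


def _table_html(df: pd.DataFrame, float_fmt: str = "{:.3g}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return float_fmt.format(v)
        return html.escape(str(v))
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    body = []
    for _, row in df.iterrows():
        body.append("<tr>" + "".join(f"<td>{fmt(v)}</td>" for v in row)
                    + "</tr>")
    return (f'<table class="qc"><thead><tr>{head}</tr></thead>'
            f"<tbody>{''.join(body)}</tbody></table>")


_STYLE = """
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; }
h1 { border-bottom: 2px solid #444; }
h2 { border-bottom: 1px solid #999; margin-top: 2em; }
table.qc { border-collapse: collapse; font-size: 0.85em; margin: 1em 0; }
table.qc th, table.qc td { border: 1px solid #ccc; padding: 0.3em 0.6em; }
table.qc th { background: #eee; }
.panel { display: inline-block; vertical-align: top; margin: 0.4em; }
.notice { color: #a33; font-style: italic; }
.verdict-warn { color: #a60; font-weight: bold; }
.verdict-pass { color: #282; }
"""


def _metrics_table(runs: dict[str, SampleRun],
                   metadata: SampleMetadata) -> pd.DataFrame:
    lib = {}
    if len(metadata.table):
        lib = dict(zip(metadata.table["sample_id"],
                       metadata.table["library_type"]))
    rows = []
    for sid, run in runs.items():
        d = run.metrics.as_dict()
        d["sample_id"] = sid
        d["library_type"] = lib.get(sid, run.metrics.library_type)
        d["n_skp_cells"] = int(run.curve.skp_calls.sum())
        d["n_eb_cells"] = int(run.curve.eb_calls.sum())
        d["n_noise_skp_minus_eb"] = int(run.curve.complement.sum())
        rows.append(d)
    df = pd.DataFrame(rows)
    front = ["sample_id", "library_type"]
    return df[front + [c for c in df.columns if c not in front]]


def build_report(
    bundle: ReportBundle,
    out_dir: str | Path,
    fixed_timestamp: str | None = None,
) -> tuple[Path, Path]:
    """Render the report and its zip archive.

    Returns ``(html_path, zip_path)``.  With ``fixed_timestamp`` (any
    string, e.g. an ISO date) the HTML and archive are byte-identical across
    reruns of the same bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timestamp = fixed_timestamp or pd.Timestamp.now().isoformat(sep=" ")

    with matplotlib.rc_context({"svg.hashsalt": "dropqc-report"}):
        return _build(bundle, out_dir, timestamp, fixed_timestamp is not None)


def _build(bundle: ReportBundle, out_dir: Path, timestamp: str,
           fixed: bool) -> tuple[Path, Path]:
    lib_types = bundle.metadata.library_types or sorted(
        {r.metrics.library_type for r in bundle.runs.values()})
    csv_paths: list[Path] = []

    # --- section 1 & 2: workflow stubs for the applications present
    s1 = ["<p>Applications in this project: "
          + ", ".join(html.escape(t) for t in lib_types) + ".</p>"]
    s2 = []
    for t in lib_types:
        s2.append(f"<h3>{html.escape(t)}</h3><p>"
                  + html.escape(_WORKFLOW_TEXT.get(t, t)) + "</p>")

    # --- section 3: metadata, metrics, GML, adequacy
    s3 = []
    if len(bundle.metadata.table):
        s3.append("<h3>Sample sheet</h3>")
        s3.append(_table_html(bundle.metadata.table))
    metrics_df = _metrics_table(bundle.runs, bundle.metadata)
    s3.append("<h3>QC metrics per sample</h3>")
    s3.append(_table_html(metrics_df))
    p = out_dir / "qc_metrics.csv"
    metrics_df.to_csv(p, index=False)
    csv_paths.append(p)

    if bundle.gml_groups:
        from .qc_metrics import aggregate_gml
        s3.append("<h3>GML: grouped multiple libraries per sample</h3>")
        gml_rows = []
        for sid, runs in bundle.gml_groups.items():
            agg = aggregate_gml(runs)
            d = agg.as_dict()
            d.pop("gml_provenance", None)
            d["n_runs"] = len(runs)
            gml_rows.append(d)
        gml_df = pd.DataFrame(gml_rows)
        s3.append(_table_html(gml_df))
        p = out_dir / "gml_aggregates.csv"
        gml_df.to_csv(p, index=False)
        csv_paths.append(p)

    s3.append("<h3>Enrichment adequacy</h3>")
    verdict_rows = []
    kwargs = {}
    if bundle.min_saturation is not None:
        kwargs["min_saturation"] = bundle.min_saturation
    if bundle.min_frac_in_cells is not None:
        kwargs["min_frac_in_cells"] = bundle.min_frac_in_cells
    for sid, run in bundle.runs.items():
        verdict: AdequacyVerdict = adequacy_check(run.metrics, **kwargs)
        for check, v, msg in verdict.checks:
            verdict_rows.append({"sample_id": sid, "check": check,
                                 "verdict": v, "message": msg})
    verdict_df = pd.DataFrame(verdict_rows)
    s3.append(_table_html(verdict_df))
    p = out_dir / "adequacy_verdicts.csv"
    verdict_df.to_csv(p, index=False)
    csv_paths.append(p)

    # --- section 4: composition + per-sample panels
    s4 = []
    comp = summarize_composition(
        {sid: r.enrichment for sid, r in bundle.runs.items()})
    s4.append("<h3>Cellular composition per sample</h3>")
    s4.append(_table_html(comp.reset_index()))
    p = out_dir / "composition.csv"
    comp.to_csv(p)
    csv_paths.append(p)

    for sid, run in bundle.runs.items():
        s4.append(f'<h3 id="sample-{html.escape(sid)}">{html.escape(sid)}</h3>')
        panels = []
        for method in ("UMAP", "tSNE"):
            svg = projection_figure(run, method)
            if svg is None:
                panels.append(
                    f'<div class="panel notice">No {method} projection '
                    f"supplied for {html.escape(sid)}; panel omitted.</div>")
            else:
                panels.append(f'<div class="panel">{svg}</div>')
        panels.append(f'<div class="panel">{heatmap_figure(run)}</div>')
        panels.append(
            f'<div class="panel">{quantification_figure(run)}</div>')
        panels.append(
            f'<div class="panel">{barcode_rank_figure(run, refined=False)}'
            "</div>")
        panels.append(
            f'<div class="panel">{barcode_rank_figure(run, refined=True)}'
            "</div>")
        s4.extend(panels)
        run.enrichment.write_csv(out_dir, prefix=f"{sid}_")
        csv_paths += [out_dir / f"{sid}_enrichment.csv",
                      out_dir / f"{sid}_thresholds.csv"]
        p = out_dir / f"{sid}_barcode_rank.csv"
        run.curve.write_csv(p)
        csv_paths.append(p)

    knee_df = pd.DataFrame([
        {"sample_id": sid,
         "knee_rank": run.curve.knee_index + 1,
         "inflection_rank": run.curve.inflection_index + 1,
         "no_distinct_knee": run.curve.no_distinct_knee}
        for sid, run in bundle.runs.items()
    ])
    p = out_dir / "knee_summary.csv"
    knee_df.to_csv(p, index=False)
    csv_paths.append(p)
    s4.append("<h3>Knee and inflection points</h3>")
    s4.append(_table_html(knee_df))

    sections = []
    sample_links = " | ".join(
        f'<a href="#sample-{html.escape(sid)}">{html.escape(sid)}</a>'
        for sid in bundle.runs)
    for i, (title, content) in enumerate(
        zip(SECTION_TITLES, ["".join(s1), "".join(s2), "".join(s3),
                             sample_links + "".join(s4)]), start=1,
    ):
        sections.append(f'<h2 id="section-{i}">{i}. {title}</h2>{content}')

    seed_line = (f"seed {bundle.seed}" if bundle.seed is not None
                 else "seed not set")
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{html.escape(bundle.title)}</title>"
        f"<style>{_STYLE}</style></head><body>"
        f"<h1>{html.escape(bundle.title)}</h1>"
        f"<p>Generated {html.escape(timestamp)} · {seed_line} · "
        f"{len(bundle.runs)} sample(s)</p>"
        + "".join(sections)
        + "</body></html>\n"
    )
    html_path = out_dir / "qc_report.html"
    html_path.write_text(doc, encoding="utf-8")

    zip_path = out_dir / "qc_report.zip"
    zdate = (2020, 1, 1, 0, 0, 0) if fixed else tuple(
        pd.Timestamp.now().timetuple())[:6]
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in [html_path] + sorted(set(csv_paths)):
            info = zipfile.ZipInfo(f.name, date_time=zdate)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, f.read_bytes())
    return html_path, zip_path
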