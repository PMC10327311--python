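# dropqc

Expression-based quality control and automated cell-type annotation for
droplet single-cell RNA-seq, with a multi-sample HTML QC report.

## The problem

Depth-based cell calling on the barcode-rank ("knee") plot keeps every
droplet whose total count clears a threshold. That threshold cannot tell a
real cell from a droplet filled with **ambient RNA** — cell-free transcripts
that produce a pooled-soup expression profile at cell-like depth. Samples
with wetting failures or heavy ambient background show a smooth curve with
no clear cliff, and depth-based calling breaks down entirely.

`dropqc` adds an *expression-based* criterion on top of the knee plot. Each
barcode is scored against a collection of cell-type marker gene sets; a
barcode that enriches for no cell type is flagged as background noise even
when its depth looks cell-like. Per-sample QC metrics, the depth-based and
expression-based calls, and the flagged noise population are assembled into
one self-contained HTML report covering a whole set of samples.

## The score

For one cell, rank all genes by raw count (descending; ties broken by a
seeded shuffle — no normalisation, so only relative expression matters).
For a marker set *G* and an evaluation depth *T* (default: the top 5% of
genes), let *H(r)* be the number of genes of *G* found at rank ≤ *r*. The
recovery-curve AUC is

```
AUC(cell, G) = Σ_{r=1..T} H(r)  /  Σ_{r=1..T} min(r, |G|)
```

which is 1 when *G* occupies the very top of the ranking and 0 when no gene
of *G* appears in the top *T*. Across cells the per-set score distribution
is bimodal (expressing vs non-expressing cells); a two-component Gaussian
mixture locates the cut between the modes, with a conservative
mean + 3·SD fallback when the fit is effectively unimodal. A cell above no
set's threshold is labelled `noise`.

On the barcode-rank curve this yields two nested call vectors: **SKP**
(standard knee-plot calls: rank at or above the inflection point) and
**EB** (expression-based: SKP *and* enriched for ≥ 1 set). The relative
complement SKP−EB is the ambient-noise population, drawn on top of every
scatter in the report so it is never hidden.

## Worked example

```python
from dropqc import SimulationConfig, simulate_experiment
from dropqc.pipeline import call_cells

sim = simulate_experiment(SimulationConfig(seed=7))
curve, result = call_cells(sim.matrix, sim.collection, seed=7)

print(f"barcodes on curve:        {len(curve)}")
print(f"knee / inflection rank:   {curve.knee_index + 1} / {curve.inflection_index + 1}")
print(f"SKP cells (depth-called): {int(curve.skp_calls.sum())}")
print(f"EB cells (enriched):      {int(curve.eb_calls.sum())}")
print(f"flagged noise (SKP-EB):   {int(curve.complement.sum())}")
```

prints

```
barcodes on curve:        5632
knee / inflection rank:   528 / 617
SKP cells (depth-called): 617
EB cells (enriched):      585
flagged noise (SKP-EB):   32
```

The simulated sample plants 600 real cells of three types, 32 ambient
droplets at cell-like depth, and 5,000 near-empty droplets. Depth-based
calling (SKP) keeps 617 barcodes — it cannot avoid the ambient droplets,
which sit at the same depth as real cells. The expression-based refinement
(EB) keeps 585 of them and flags exactly the 32 planted ambient droplets as
noise: every kept barcode enriches strongly for one marker set
(per-set bimodal thresholds ≈ 0.65–0.67), while the soup profile enriches
for none.

The same pipeline runs from the shell:

```sh
dropqc simulate --out sample1 --seed 7
dropqc enrich --input sample1 --gene-sets sample1/reference_sets.gmt --out results
dropqc report --input sample1 --gene-sets sample1/reference_sets.gmt \
              --out report --fixed-timestamp 2024-01-01
```

`report` writes `qc_report.html` — four sections: experimental workflow,
data processing workflow, samples information and QC metrics, data analysis
and quality control (UMAP/t-SNE by assigned type, marker heatmap,
quantification plot, standard and refined barcode-rank plots) — plus a zip
archive bundling the HTML with every CSV export.

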