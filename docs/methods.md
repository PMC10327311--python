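# Methods

This note documents the models and numerical choices behind `dropqc`: how
cells are scored against marker gene sets, how score distributions are
thresholded, how the barcode-rank curve is analysed, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Per-cell recovery-curve AUC

Each cell is treated independently. Its genes are sorted by raw count,
descending; ties — including the tail of undetected genes — are broken by a
pseudo-random shuffle whose stream is derived from `(seed, cell index)`, so
a rerun with the same seed reproduces every permutation bit for bit. Counts
are deliberately not normalised: the score depends only on the within-cell
ranking, so library size cancels and the AUC measures *relative* expression
of the signature.

For a matched gene set *G* and integration depth *T*, with *H(r)* the
number of genes of *G* at rank ≤ *r*:

    AUC = Σ_{r=1..T} H(r) / Σ_{r=1..T} min(r, |G|).

The denominator is the area of a top-packed set, so AUC ∈ [0, 1], reaching
1 iff the best `min(|G|, T)` positions are all set genes and 0 iff none is
in the top *T*. Equivalently each set gene at rank *p* ≤ *T* contributes
*T − p + 1*; the implementation uses this closed form, and the test suite
checks it against a literal step-function integration on random instances.

**Depth `T`.** Default `max_rank_fraction = 0.05` (top 5% of features),
the conventional choice for recovery-curve scoring of scRNA-seq signatures;
exposed in the configuration. Undetected genes participate in the shuffled
tail, but since `T` is far smaller than the gene count they essentially
never affect scores — the rule exists only to make the permutation total
and deterministic.

## Bimodal thresholding

Across cells, a set's AUC distribution is ideally bimodal: a background
mode near zero (cells not of that type) and an enriched mode (cells of the
type). The cut is placed by fitting a two-component univariate Gaussian
mixture and taking the point between the component means where the
posterior membership flips.

Numerical choices, each load-bearing:

- **k-means initialisation** (scikit-learn's default, 3 restarts, seeded).
  With an intermediate cluster present — ambient droplets score mid-range
  in *every* set — a 1-D k-means split groups it with the low mode, because
  that assignment minimises within-cluster variance. Percentile-based mean
  initialisation intermittently converged to a basin that isolated the
  zero spike instead and cut *below* the ambient cluster, assigning soup
  droplets to a cell type.
- **Variance floor** `reg_covar = 3e-3` (component SD ≥ ~0.055 on the unit
  score scale). Many cells score exactly 0 for a set; without the floor one
  component collapses onto that spike and drags the cut to its edge.
- **Bimodality test**: the fit is accepted only if Ashman's
  D = √2·|μ₁−μ₂|/√(σ₁²+σ₂²) ≥ 2, the standard requirement for a mixture to
  be genuinely bimodal. A weaker separation rule (means a fraction of a
  pooled SD apart) does not work: EM fitted to a *unimodal* sample places
  its two component means ~1.6 SD apart, which such a rule never rejects.
- **Fallback**: fewer than 10 cells, a constant vector, a failed fit, or a
  sub-threshold Ashman's D all fall back to `mean + 3·SD`, clipped to
  [0, 1] — a conservative cut that passes roughly the 0.1% normal tail of a
  unimodal distribution and passes nothing on a constant one (assignment
  uses a strict `>`).

**Assignment.** A cell's candidate sets are those with AUC strictly above
their threshold; the label is the candidate with the largest AUC, exact
ties going to the lexicographically smallest set name (a documented
arbitrary-but-deterministic rule). A cell with no candidates is `noise` —
the definition of expression-based background. One passing set suffices;
requiring all sets would conflate "not this type" with "not a cell".

## Barcode-rank analytics

Per-barcode totals are sorted descending (ties by barcode string, for a
stable order). Duplicate count values are collapsed to one point at their
mean rank, and a cubic smoothing spline is fit to log₁₀(count) against
log₁₀(rank) (smoothing factor `0.02` per collapsed point — heavy enough to
suppress plateau jitter, light enough to keep the cliff). On a 2,000-point
grid:

- **inflection** = most negative first derivative (mid-cliff);
- **knee** = minimum signed curvature at or left of the inflection (top of
  the cliff).

Both are mapped back to ranks on the uncollapsed axis, so knee ≤ inflection
always. A curve whose log-log shape is essentially a straight line (linear
fit R² ≥ 0.995 — e.g. a pure power law, the "smooth curve, no cliff"
failure mode) carries no transition signal: both points are placed at the
steepest descent and a `no_distinct_knee` flag is raised rather than
reporting a spurious knee.

**SKP threshold = inflection point**, the permissive depth bound, so the
expression-based refinement does the discriminating work. EB calls are by
construction a subset of SKP; the complement SKP−EB is the flagged noise
population. Across samples, the association between cell yield and noise
count is summarised by a Pearson correlation with its two-sided p-value
(reported as undefined if either variable is constant).

## QC metrics and adequacy

All saturation/fraction metrics live on the printed percent scale (45.1,
never 0.451). Sequencing saturation is `100·(1 − unique/total reads)`.
Aggregation over several sequencing runs of one library (GML) sums read
counts, combines percentages as read-count-weighted means (bounded by the
inputs; idempotent under equal weights), takes cell counts from the deepest
run, and records the provenance of every aggregated field. Mixing library
types is an error.

Enrichment-based QC degrades on very shallow data, so each sample is
checked against two floors — sequencing saturation ≥ 11.3% and fraction of
reads in cells ≥ 15.5%, both inclusive — plus a recommended depth of
50,000 mean reads per cell. Shortfalls produce *warnings*, not failures:
shallow samples still run, with the caveat displayed in the report.

## Synthetic experiments

The generator emulates the data regime the tool targets, with planted truth
for every barcode:

- **Real cells** (default 3 types × 200 cells): negative-binomial counts
  (size 2.0 — scRNA-seq is overdispersed relative to Poisson), mean 20 on
  the cell's own 25 exclusive markers and 0.2 elsewhere. A strong,
  unambiguous signal: the defaults define the reference conditions under
  which the pipeline is expected to be near-perfect.
- **Ambient droplets** (5% of above-knee barcodes): Poisson draws from the
  pooled mean profile of all real cells, scaled to the median real-cell
  depth (`ambient_scale = 1.0`). Placing them at cell depth is the point:
  they are exactly the population a knee threshold keeps and
  expression-based filtering must remove. At depths well below the
  plateau they would fall below the inflection and be discarded as empty,
  which is a different (and easier) scenario.
- **Empty droplets** (5,000): the same soup profile at 2% of the median
  depth, forming the lower plateau.
- **Projection**: a PCA embedding of log1p counts of the above-knee
  barcodes, standing in for UMAP/t-SNE — deterministic and adequate for
  exercising plotting and joins, with no claim of manifold fidelity.
- **Metrics**: derived from a planted read-duplication rate of 0.45, i.e.
  a simulated saturation of 45%.

What the generator does *not* emulate: transcriptome-scale gene counts,
doublets, batch effects, gene-gene correlation, or partial marker overlap
between types (planted sets are exclusive by construction and validated as
such). Passing tests therefore demonstrate correctness of the machinery
and recoverability under a strong clean signal, not performance on noisy
real tissue.

## Report

The report is a single static HTML file: four fixed sections, matplotlib
SVG figures embedded inline, no scripts fetched at view time, plus a zip
archive of the HTML and all CSV exports. Two rendering rules are
contractual and tested: with a fixed timestamp the output is byte-identical
across reruns (SVG hash salt pinned, date metadata suppressed, archive
timestamps frozen), and in every scatter the SKP−EB points are serialized
after the called cells so the flagged background is always drawn on top.
The marker heatmap shows per-gene z-scaled mean expression by assigned type
(raw means available via `zscale=False`); z-scaling was chosen as the
default because raw means are dominated by the handful of most-expressed
markers. Workflow-description sections are template stubs keyed by the
library types present in the metadata sheet.

## Problem sizes

Tests and the acceptance script run the default synthetic experiment
(575 genes × 5,632 droplets), 200-instance AUC oracle sweeps,
1,000-perturbation monotonicity sweeps, a 21,000-barcode two-plateau curve
and a 1,000-cell threshold experiment — sizes at which every property is
measurable with margin while the whole suite stays fast on a single CPU.

## Known limitations

- Cells are annotated individually; no cluster-level label smoothing.
- A cell type absent from the reference collection is labelled `noise`,
  indistinguishable from ambient background.
- The two-component mixture assumes one enriched population per set;
  strongly trimodal score distributions (e.g. two related cell types
  sharing markers) get a single cut between the extreme modes.
- Knee detection needs a few distinct count values; on tiny inputs it
  degrades to the steepest-descent heuristic with the no-knee flag.
- Doublet detection and ambient-profile estimation from the empty-droplet
  pool are out of scope.
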