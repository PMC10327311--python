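"""Barcode-rank curves, knee/inflection detection, and cell calling.

Droplet experiments capture many more barcodes than cells; sorting
per-barcode totals descending produces the characteristic knee plot whose
cliff separates cell-containing droplets from empty ones.  Two call vectors
live on the curve:

* **SKP** (standard knee-plot calls): every barcode at or above the
  inflection point — the permissive depth-based call.
* **EB** (expression-based calls): SKP barcodes that additionally enrich
  for at least one reference gene set.

The relative complement SKP−EB is the set flagged as ambient background
noise: droplets deep enough to pass the knee threshold whose expression
profile matches no cell type.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .enrichment import NOISE_LABEL, EnrichmentResult

logger = logging.getLogger(__name__)

#: Default smoothing factor for the log-log spline fit (per collapsed point).
DEFAULT_SMOOTHING = 0.02

#: Log-log curves this close to a straight line carry no knee signal.
_LINEAR_R2_CUTOFF = 0.995


@dataclass
class BarcodeRankCurve:
    """Barcodes sorted by descending count, with knee analytics and calls."""

    barcodes: np.ndarray          # sorted
    counts: np.ndarray            # non-increasing
    knee_index: int | None = None
    inflection_index: int | None = None
    no_distinct_knee: bool = False
    skp_calls: np.ndarray | None = None   # bool per barcode
    eb_calls: np.ndarray | None = None    # bool per barcode

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def complement(self) -> np.ndarray:
        """SKP−EB mask: called by depth, rejected by expression."""
        if self.skp_calls is None or self.eb_calls is None:
            raise ValueError("call vectors not set; run expression_based_calls")
        return self.skp_calls & ~self.eb_calls

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "barcode": self.barcodes,
            "rank": np.arange(1, len(self) + 1),
            "count": self.counts,
        })
        if self.skp_calls is not None:
            df["skp_call"] = self.skp_calls
        if self.eb_calls is not None:
            df["eb_call"] = self.eb_calls
        return df

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def build_curve(per_barcode_counts: dict[str, int]) -> BarcodeRankCurve:
    """Sort barcodes by descending count (ties broken by barcode string)."""
    if not per_barcode_counts:
        raise ValueError("no barcodes supplied")
    items = sorted(per_barcode_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = np.array([v for _, v in items], dtype=np.int64)
    if counts.min() < 0:
        raise ValueError("per-barcode counts must be non-negative")
    if counts.max() == 0:
        raise ValueError("all barcode counts are zero: no evidence of cells")
    if int((counts > 0).sum()) < 2:
        raise ValueError("need at least 2 barcodes with positive counts")
    return BarcodeRankCurve(
        barcodes=np.array([k for k, _ in items], dtype=object),
        counts=counts,
    )


def _collapsed_loglog(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate count values to (log10 mean rank, log10 count)."""
    pos = counts[counts > 0]
    values, first = np.unique(pos[::-1], return_index=True)  # ascending
    values = values[::-1]                                    # descending
    ranks = []
    start = 0
    for v in values:
        n = int((pos == v).sum())
        ranks.append(start + (n + 1) / 2.0)  # mean 1-based rank of this value
        start += n
    return np.log10(np.asarray(ranks)), np.log10(values.astype(float))


def detect_knee_inflection(
    curve: BarcodeRankCurve, smoothing: float = DEFAULT_SMOOTHING,
) -> tuple[int, int]:
    """Locate the knee and inflection of the barcode-rank curve.

    A cubic smoothing spline is fit to log10(count) vs log10(rank) on the
    duplicate-collapsed points.  The inflection is the point of most
    negative first derivative; the knee is the point of minimum signed
    curvature at or left of the inflection.  Both are mapped back to 0-based
    indices on the uncollapsed sorted axis and stored on the curve.

    A curve that is essentially a straight line in log-log space (e.g. a
    pure power law — "smooth with no cliff or knee") carries no transition
    signal: both points land at the steepest-descent location and
    ``no_distinct_knee`` is flagged.
    """
    x, y = _collapsed_loglog(curve.counts)
    n = len(curve)
    if len(x) < 5:
        logger.warning("too few distinct count values for a spline fit; "
                       "flagging no distinct knee")
        curve.no_distinct_knee = True
        mid = int(np.argmin(np.diff(curve.counts))) if n > 1 else 0
        curve.knee_index = curve.inflection_index = mid
        return mid, mid

    # straight-line log-log curves have no knee by definition
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    spl = UnivariateSpline(x, y, k=3, s=smoothing * len(x))
    grid = np.linspace(x.min(), x.max(), 2000)
    d1 = spl.derivative(1)(grid)
    d2 = spl.derivative(2)(grid)
    infl_g = int(np.argmin(d1))

    curvature = d2 / (1.0 + d1**2) ** 1.5
    left = slice(0, infl_g + 1)
    knee_g = int(np.argmin(curvature[left]))

    def to_index(gx: float) -> int:
        rank = 10.0 ** gx
        return int(min(max(round(rank) - 1, 0), n - 1))

    knee_i, infl_i = to_index(grid[knee_g]), to_index(grid[infl_g])
    if r2 >= _LINEAR_R2_CUTOFF:
        logger.warning("barcode-rank curve is near-linear in log-log space "
                       "(R^2=%.4f): no distinct knee", r2)
        curve.no_distinct_knee = True
        knee_i = infl_i
    if knee_i > infl_i:
        knee_i = infl_i
    curve.knee_index, curve.inflection_index = knee_i, infl_i
    return knee_i, infl_i


def expression_based_calls(
    curve: BarcodeRankCurve, enrichment: EnrichmentResult,
) -> BarcodeRankCurve:
    """Set the SKP and EB call vectors on the curve.

    SKP = rank at or above the inflection point; EB = SKP and assigned to a
    cell type (not noise).  EB is by construction a refinement of SKP.
    Requires knee/inflection to be detected first and at least one curve
    barcode present in the enrichment result.
    """
    if curve.inflection_index is None:
        detect_knee_inflection(curve)
    labels = enrichment.assignment
    present = np.isin(curve.barcodes.astype(str), labels.index.to_numpy())
    if not present.any():
        raise ValueError(
            "enrichment result covers none of the curve's barcodes"
        )
    skp = np.arange(len(curve)) <= curve.inflection_index
    enriched = np.zeros(len(curve), dtype=bool)
    lab = labels.to_dict()
    for i, bc in enumerate(curve.barcodes):
        if skp[i] and lab.get(bc, NOISE_LABEL) != NOISE_LABEL:
            enriched[i] = True
    curve.skp_calls = skp
    curve.eb_calls = enriched
    return curve


@dataclass
class NoiseDepthAssociation:
    """Pearson association between per-sample cell and noise counts."""

    r: float | None
    p_value: float | None
    n: int
    undefined: bool = False
    message: str = ""


def noise_vs_depth_association(
    samples: list[tuple[float, float]],
) -> NoiseDepthAssociation:
    """Correlate the number of cells with the number of noise barcodes.

    Used across samples to check that the ambient-noise call rate is not a
    simple function of cell yield.  Zero variance in either variable makes
    the correlation undefined (flagged, not an error).
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    x = np.array([s[0] for s in samples], dtype=float)
    y = np.array([s[1] for s in samples], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return NoiseDepthAssociation(
            r=None, p_value=None, n=len(samples), undefined=True,
            message="correlation undefined: a variable has zero variance",
        )
    r, p = stats.pearsonr(x, y)
    return NoiseDepthAssociation(r=float(r), p_value=float(p), n=len(samples))
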