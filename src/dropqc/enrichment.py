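"""Per-cell gene-set enrichment scoring and cell-type assignment.

Each cell is scored against every reference gene set with a recovery-curve
AUC: genes are ranked by raw count within the cell (no normalisation — the
score depends only on relative expression, so library size cancels), the
cumulative number of set genes encountered while walking down the ranking is
integrated to a depth ``T``, and the area is divided by the best achievable
area.  A score of 1 means the set's genes occupy the very top of the cell's
expression ranking; 0 means none of them appear in the top ``T``.

The per-set score distribution across cells is typically bimodal: an
enriched mode (cells of that type) and a background mode.  A two-component
Gaussian mixture locates the cut between the modes; when the fit is
degenerate a conservative mean + 3*SD fallback is used.  A cell whose score
exceeds no set's threshold is labelled ``"noise"`` — the population that
expression-based QC flags as ambient background.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .reference_sets import MatchResult, ReferenceGeneSetCollection, match_to_matrix
from .tenx_io import GeneCellMatrix

logger = logging.getLogger(__name__)

NOISE_LABEL = "noise"

#: Default AUC integration depth as a fraction of the feature count.
DEFAULT_MAX_RANK_FRACTION = 0.05

#: Minimum Ashman's D between mixture components to call the fit bimodal.
_MIN_ASHMAN_D = 2.0


@dataclass
class RankedCell:
    """One cell's features ordered by descending raw count.

    ``order`` is a permutation of all feature indices; every detected
    (nonzero) feature precedes every undetected one.  Ties — including the
    all-zero tail — are broken by a seeded shuffle so reruns are identical.
    """

    order: np.ndarray
    n_detected: int

    @property
    def positions(self) -> np.ndarray:
        """1-based rank of each feature (inverse of ``order``)."""
        pos = np.empty(len(self.order), dtype=np.int64)
        pos[self.order] = np.arange(1, len(self.order) + 1)
        return pos


def rank_cell(counts_column: np.ndarray, rng_seed: int | Sequence[int]) -> RankedCell:
    """Rank one cell's features by descending count with seeded tie-breaks.

    An all-zero cell yields a valid (purely random) ranking with
    ``n_detected = 0`` so callers can flag it as low quality.
    """
    counts = np.asarray(counts_column).ravel()
    rng = np.random.default_rng(rng_seed)
    tiebreak = rng.random(counts.size)
    # lexsort: last key is primary -> descending count, then random tiebreak
    order = np.lexsort((tiebreak, -counts))
    return RankedCell(order=order, n_detected=int(np.count_nonzero(counts)))


def _max_recovery_area(set_size: int, max_rank: int) -> int:
    """Area when set genes fill the best possible ranks: sum_r min(r, s)."""
    s, t = set_size, max_rank
    if s >= t:
        return t * (t + 1) // 2
    return s * (s + 1) // 2 + (t - s) * s


def auc_score(
    ranked: RankedCell, set_indices: Sequence[int], max_rank: int
) -> float:
    """Recovery-curve AUC for one cell and one gene set, in [0, 1].

    With ``H(r)`` the number of set genes at rank <= r, the raw area is
    ``sum_{r=1..T} H(r)``; the score is raw / max where max is the area of a
    top-packed set.  Equivalently each set gene at rank ``p <= T``
    contributes ``T - p + 1``.
    """
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    idx = np.asarray(list(set_indices), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("set_indices must be non-empty")
    pos = ranked.positions[idx]
    pos = pos[pos <= max_rank]
    raw = int(np.sum(max_rank - pos + 1))
    return raw / _max_recovery_area(idx.size, max_rank)


def select_threshold(
    auc_values: Sequence[float], random_state: int = 0
) -> tuple[float, str]:
    """Cut the per-set AUC distribution between its two modes.

    Fits a two-component univariate Gaussian mixture and returns the point
    between the component means where posterior membership flips.  Falls back
    to ``mean + 3*SD`` (clipped to [0, 1]) when there are fewer than 10
    cells, the fit fails, or the components are not genuinely separated
    (Ashman's D below 2 — an effectively unimodal fit, where EM splits one
    mode into two overlapping Gaussians).  Returns ``(threshold, method)``
    with method in ``{"bimodal", "fallback_3sigma"}``.
    """
    v = np.asarray(auc_values, dtype=float)
    mean, sd = float(v.mean()), float(v.std())

    def fallback() -> tuple[float, str]:
        return min(max(mean + 3.0 * sd, 0.0), 1.0), "fallback_3sigma"

    if v.size < 10 or sd == 0.0:
        return fallback()

    try:
        # k-means initialisation keeps any intermediate (ambient) cluster
        # with the low mode; reg_covar floors the component SD at ~0.055 on
        # the [0,1] score scale so a spike of identical scores cannot
        # collapse one component and drag the cut down to the spike's edge
        gm = GaussianMixture(
            n_components=2,
            n_init=3,
            reg_covar=3e-3,
            random_state=random_state,
        ).fit(v.reshape(-1, 1))
    except Exception:  # degenerate input; rare
        return fallback()

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo_i, hi_i = int(np.argmin(means)), int(np.argmax(means))
    denom = math.sqrt(float(sds[lo_i] ** 2 + sds[hi_i] ** 2))
    ashman_d = math.sqrt(2.0) * abs(means[hi_i] - means[lo_i]) / denom \
        if denom > 0 else 0.0
    if ashman_d < _MIN_ASHMAN_D:
        return fallback()

    # posterior flip point between the two component means
    grid = np.linspace(means[lo_i], means[hi_i], 2001)
    post = gm.predict_proba(grid.reshape(-1, 1))[:, hi_i]
    above = np.nonzero(post >= 0.5)[0]
    if above.size == 0:
        return fallback()
    return float(grid[above[0]]), "bimodal"


def assign_cells(auc: pd.DataFrame, thresholds: pd.Series) -> pd.Series:
    """Label each cell from its AUC row.

    Candidate sets are those with ``auc > threshold`` (strict); the label is
    the argmax-AUC candidate, ties going to the lexicographically smallest
    set name; a cell with no candidates is ``"noise"``.
    """
    cols = sorted(auc.columns)
    a = auc[cols].to_numpy(dtype=float)
    thr = thresholds[cols].to_numpy(dtype=float)
    passing = a > thr
    masked = np.where(passing, a, -np.inf)
    best = np.argmax(masked, axis=1)  # first max = smallest name (sorted cols)
    labels = np.where(passing.any(axis=1),
                      np.asarray(cols, dtype=object)[best], NOISE_LABEL)
    return pd.Series(labels, index=auc.index, name="assignment")


@dataclass
class EnrichmentResult:
    """Cells x gene-sets AUC matrix with thresholds and per-cell labels."""

    auc: pd.DataFrame            # index = barcodes, columns = set names
    thresholds: pd.Series        # per-set, in [0, 1]
    assignment: pd.Series        # per-cell label in set names + {"noise"}
    max_rank: int
    seed: int
    threshold_methods: dict[str, str]
    match: MatchResult | None = None

    @property
    def barcodes(self) -> list[str]:
        return list(self.auc.index)

    @property
    def n_noise(self) -> int:
        return int((self.assignment == NOISE_LABEL).sum())

    def write_csv(self, directory: str | os.PathLike, prefix: str = "") -> None:
        """Write AUC + assignment and thresholds next to each other."""
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        out = self.auc.copy()
        out.insert(len(out.columns), "assignment", self.assignment)
        out.index.name = "barcode"
        out.to_csv(os.path.join(directory, f"{prefix}enrichment.csv"))
        thr = self.thresholds.rename("threshold").to_frame()
        thr.index.name = "gene_set"
        thr["method"] = [self.threshold_methods.get(n, "") for n in thr.index]
        thr.to_csv(os.path.join(directory, f"{prefix}thresholds.csv"))


def enrich(
    matrix: GeneCellMatrix,
    collection: ReferenceGeneSetCollection,
    max_rank_fraction: float = DEFAULT_MAX_RANK_FRACTION,
    seed: int = 0,
    case_insensitive: bool = False,
) -> EnrichmentResult:
    """Score every cell against every matched reference set and label it.

    ``T = ceil(max_rank_fraction * n_features)`` is the AUC integration
    depth (default: the top 5% of the ranking).  The result is fully
    reproducible from ``seed``: per-cell tie-break streams are derived from
    ``(seed, cell index)``.
    """
    n_features, n_cells = matrix.shape
    if n_features == 0 or n_cells == 0:
        raise ValueError("count matrix is empty")
    match = match_to_matrix(collection, matrix.feature_names,
                            case_insensitive=case_insensitive)
    if not match.matches:
        raise ValueError(
            "no reference gene set matched the matrix features; check that "
            "gene symbols use the same nomenclature (try case_insensitive=True)"
        )
    max_rank = max(1, math.ceil(max_rank_fraction * n_features))
    set_names = list(match.matches)
    set_idx = {n: np.asarray(match.matches[n].indices) for n in set_names}
    max_area = {n: _max_recovery_area(len(set_idx[n]), max_rank)
                for n in set_names}

    counts = matrix.counts.tocsc()
    scores = np.zeros((n_cells, len(set_names)))
    for j in range(n_cells):
        col = np.asarray(counts[:, j].todense()).ravel()
        ranked = rank_cell(col, rng_seed=[seed, j])
        pos = ranked.positions
        for k, name in enumerate(set_names):
            p = pos[set_idx[name]]
            p = p[p <= max_rank]
            scores[j, k] = np.sum(max_rank - p + 1) / max_area[name]

    auc = pd.DataFrame(scores, index=list(matrix.barcodes), columns=set_names)
    thresholds = {}
    methods = {}
    for name in set_names:
        thr, method = select_threshold(auc[name].to_numpy(), random_state=seed)
        thresholds[name] = thr
        methods[name] = method
        logger.info("gene set %r: threshold %.4f (%s)", name, thr, method)
    thresholds = pd.Series(thresholds)
    assignment = assign_cells(auc, thresholds)
    return EnrichmentResult(
        auc=auc, thresholds=thresholds, assignment=assignment,
        max_rank=max_rank, seed=seed, threshold_methods=methods, match=match,
    )
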