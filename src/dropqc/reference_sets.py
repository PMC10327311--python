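"""Cell-type marker gene-set collections.

A reference collection maps cell-type labels to marker gene symbols — genes
with exclusively elevated expression in that cell type.  Collections are
exchanged as GMT files (one set per line: name, description, genes...) or as
a directory of plain-text files with one gene symbol per line.  Before
scoring, sets are matched against the feature names of a count matrix; sets
with poor coverage are dropped so a species or nomenclature mismatch cannot
silently produce all-zero enrichment scores.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

VALID_SPECIES = ("human", "mouse", "other")

#: Sets matching fewer than this fraction of their genes are excluded.
MIN_COVERAGE = 0.2
#: Sets matching fewer than this fraction trigger a warning but are kept.
WARN_COVERAGE = 0.8


class GeneSetError(ValueError):
    """Malformed gene set or collection."""


@dataclass(frozen=True)
class GeneSet:
    """A named marker gene set for one cell type.

    Parameters
    ----------
    name
        Cell-type label; must be non-empty and unique within a collection.
    genes
        Ordered gene symbols; duplicates (case-insensitive) are invalid.
    species
        One of ``human``, ``mouse``, ``other``.
    """

    name: str
    genes: tuple[str, ...]
    species: str = "human"

    def __post_init__(self) -> None:
        if not self.name:
            raise GeneSetError("gene set name must be non-empty")
        if not self.genes:
            raise GeneSetError(f"gene set {self.name!r} has no genes")
        object.__setattr__(self, "genes", tuple(self.genes))
        seen = {g.casefold() for g in self.genes}
        if len(seen) != len(self.genes):
            raise GeneSetError(
                f"gene set {self.name!r} contains duplicate symbols"
            )
        if self.species not in VALID_SPECIES:
            raise GeneSetError(
                f"species must be one of {VALID_SPECIES}, got {self.species!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ReferenceGeneSetCollection:
    """An ordered collection of :class:`GeneSet` with provenance.

    Set names are pairwise distinct; genes may overlap *across* sets (the
    collection does not deduplicate between cell types).
    """

    sets: list[GeneSet]
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GeneSetError(f"duplicate gene set name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def n_genes(self) -> int:
        """Total marker count: the sum of per-set sizes."""
        return sum(len(s) for s in self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def read_gmt(
    path: str | os.PathLike, species: str = "human"
) -> ReferenceGeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...).

    Blank lines are skipped.  Duplicate symbols within one line are collapsed
    to their first occurrence with a warning.  A line with fewer than three
    fields raises :class:`GeneSetError` naming the line number; so does a
    duplicated set name.  If the description field is a recognized species
    tag it overrides ``species`` for that set.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in names:
                raise GeneSetError(
                    f"{path.name}:{lineno}: duplicate gene set name {name!r}"
                )
            genes: list[str] = []
            seen: set[str] = set()
            n_dupes = 0
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                key = g.casefold()
                if key in seen:
                    n_dupes += 1
                    continue
                seen.add(key)
                genes.append(g)
            if n_dupes:
                logger.warning(
                    "%s:%d: set %r: collapsed %d duplicate gene symbol(s)",
                    path.name, lineno, name, n_dupes,
                )
            set_species = description if description in VALID_SPECIES else species
            sets.append(GeneSet(name=name, genes=tuple(genes), species=set_species))
            names.add(name)
    return ReferenceGeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: ReferenceGeneSetCollection, path: str | os.PathLike) -> None:
    """Write a collection to GMT, using the species tag as the description."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.species, *s.genes]) + "\n")


def read_set_directory(
    path: str | os.PathLike, species: str = "human"
) -> ReferenceGeneSetCollection:
    """Read a directory of one-set-per-file plain-text gene lists.

    Each ``*.txt`` file holds one gene symbol per line; the file stem is the
    cell-type label.
    """
    path = Path(path)
    sets = []
    for f in sorted(path.glob("*.txt")):
        genes = [ln.strip() for ln in f.read_text(encoding="utf-8").splitlines()]
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning("%s: collapsed duplicate gene symbols", f.name)
        sets.append(GeneSet(name=f.stem, genes=tuple(deduped), species=species))
    return ReferenceGeneSetCollection(sets=sets, source=str(path))


@dataclass
class GeneSetMatch:
    """One gene set resolved to row indices of a count matrix."""

    name: str
    indices: tuple[int, ...]
    coverage: float


@dataclass
class MatchResult:
    """Outcome of matching a collection to measured features.

    ``matches`` holds only the sets retained for scoring (coverage >=
    :data:`MIN_COVERAGE`); ``coverage`` reports the matched fraction for every
    set, including excluded ones.
    """

    matches: dict[str, GeneSetMatch] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def match_to_matrix(
    collection: ReferenceGeneSetCollection,
    feature_names: Sequence[str],
    case_insensitive: bool = False,
) -> MatchResult:
    """Map each set's symbols to matrix row indices.

    Genes absent from ``feature_names`` are dropped.  Sets with coverage
    below :data:`MIN_COVERAGE` are excluded from scoring with a warning (a
    zero-match set is excluded, not an error); coverage below
    :data:`WARN_COVERAGE` warns but keeps the set.  Matching is exact string
    equality unless ``case_insensitive`` is set (useful across the human
    UPPER-CASE / mouse Title-case symbol conventions).
    """
    if len(feature_names) == 0:
        raise ValueError("feature_names must be non-empty")
    if case_insensitive:
        lookup: dict[str, int] = {}
        for i, f in enumerate(feature_names):
            lookup.setdefault(f.casefold(), i)
    else:
        lookup = {}
        for i, f in enumerate(feature_names):
            lookup.setdefault(f, i)

    result = MatchResult()
    for s in collection:
        idx = []
        for g in s.genes:
            key = g.casefold() if case_insensitive else g
            if key in lookup:
                idx.append(lookup[key])
        cov = len(idx) / len(s.genes)
        result.coverage[s.name] = cov
        if cov < MIN_COVERAGE:
            logger.warning(
                "gene set %r: coverage %.2f < %.2f, excluded from scoring",
                s.name, cov, MIN_COVERAGE,
            )
            result.excluded.append(s.name)
            continue
        if cov < WARN_COVERAGE:
            logger.warning(
                "gene set %r: low coverage %.2f (%d/%d genes matched)",
                s.name, cov, len(idx), len(s.genes),
            )
        result.matches[s.name] = GeneSetMatch(
            name=s.name, indices=tuple(idx), coverage=cov
        )
    return result
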