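"""Annotation collections: datasets of named gene sets with GMT read/write.

The in-memory model mirrors the Datasets -> Gene Sets -> Genes hierarchy
common to curated gene-set databases.  Each :class:`AnnotationDataset` is a
named, cited collection of :class:`GeneSetAnnotation` objects together with
its gene *universe* -- the total pool of genes the collection knows about,
which the INTERSECT background mode intersects against.

Gene identifiers are either MGI-style symbols (matched case-insensitively)
or Ensembl mouse gene IDs (ENSMUSG..., matched after stripping any
``.<digits>`` version suffix).  No translation between the two kinds is
attempted: matching is purely by normalized key.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, NamedTuple, Optional, Sequence

from .errors import GmtFormatError, InvalidIdentifierError

logger = logging.getLogger(__name__)

_ENSEMBL_MOUSE_RE = re.compile(r"^ENSMUSG\d+$")
_VERSION_SUFFIX_RE = re.compile(r"\.\d+$")


class IdKind(enum.Enum):
    """The kind of gene identifier a label was recognized as."""

    SYMBOL = "symbol"
    ENSEMBL = "ensembl"


@dataclass(frozen=True)
class GeneIdentifier:
    """A gene label plus the normalized key used for matching.

    Equality and hashing are by ``normalized_key`` only, so ``Fcgr1`` and
    ``FCGR1`` are the same gene, as are ``ENSMUSG00000015947.12`` and
    ``ENSMUSG00000015947``.
    """

    raw_label: str
    normalized_key: str
    id_kind: IdKind

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneIdentifier):
            return NotImplemented
        return self.normalized_key == other.normalized_key

    def __hash__(self) -> int:
        return hash(self.normalized_key)

    def __repr__(self) -> str:  # keep debugging output compact
        return f"GeneIdentifier({self.normalized_key!r})"


def normalize_gene_id(raw: str) -> GeneIdentifier:
    """Normalize a raw gene label into a :class:`GeneIdentifier`.

    Symbols are upper-cased after trimming; Ensembl mouse IDs additionally
    have any ``.<digits>`` version suffix removed.  The identifier kind is
    decided by the ``ENSMUSG<digits>`` prefix pattern after normalization.

    Raises
    ------
    InvalidIdentifierError
        If the label is empty, whitespace-only, or contains internal
        whitespace (normalized keys must be single tokens).
    """
    trimmed = raw.strip()
    if not trimmed:
        raise InvalidIdentifierError(
            f"invalid gene identifier: {raw!r} is empty or whitespace-only"
        )
    if any(ch.isspace() for ch in trimmed):
        raise InvalidIdentifierError(
            f"invalid gene identifier: {raw!r} contains internal whitespace"
        )
    key = trimmed.upper()
    deversioned = _VERSION_SUFFIX_RE.sub("", key)
    if _ENSEMBL_MOUSE_RE.match(deversioned):
        return GeneIdentifier(trimmed, deversioned, IdKind.ENSEMBL)
    return GeneIdentifier(trimmed, key, IdKind.SYMBOL)


def normalize_gene_ids(labels: Iterable[str]) -> list[GeneIdentifier]:
    """Normalize many labels, preserving order."""
    return [normalize_gene_id(label) for label in labels]


@dataclass
class GeneSetAnnotation:
    """A named gene set within a dataset.

    ``members`` holds the annotated genes behind the K (background overlap)
    and k (query overlap) counts of the enrichment test.
    """

    set_id: str
    display_name: str
    description: str
    members: frozenset[GeneIdentifier]

    def __post_init__(self) -> None:
        if not self.members:
            raise GmtFormatError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AnnotationDataset:
    """A named, cited collection of gene sets plus its gene universe.

    If no explicit universe is given the universe is the union of all
    gene-set members; a larger explicit universe models collections whose
    total gene count exceeds the union of the reported sets.
    """

    dataset_id: str
    title: str = ""
    citation: str = ""
    gene_sets: list[GeneSetAnnotation] = field(default_factory=list)
    universe: frozenset[GeneIdentifier] = frozenset()

    def __post_init__(self) -> None:
        if not self.title:
            self.title = self.dataset_id
        seen: set[str] = set()
        for gs in self.gene_sets:
            if gs.set_id in seen:
                raise GmtFormatError(
                    f"duplicate gene set id {gs.set_id!r} in dataset "
                    f"{self.dataset_id!r}"
                )
            seen.add(gs.set_id)
        union = frozenset().union(*(gs.members for gs in self.gene_sets)) \
            if self.gene_sets else frozenset()
        if not self.universe:
            self.universe = union
        else:
            stray = union - self.universe
            if stray:
                names = sorted(g.normalized_key for g in stray)[:5]
                raise GmtFormatError(
                    f"dataset {self.dataset_id!r}: {len(stray)} gene-set "
                    f"member(s) missing from the supplied universe "
                    f"(e.g. {', '.join(names)})"
                )

    def get_set(self, set_id: str) -> GeneSetAnnotation:
        for gs in self.gene_sets:
            if gs.set_id == set_id:
                return gs
        raise KeyError(set_id)

    @property
    def n_sets(self) -> int:
        return len(self.gene_sets)


def read_gmt(
    source: IO[str],
    dataset_id: str,
    universe_override: Optional[Iterable[GeneIdentifier]] = None,
    title: str = "",
    citation: str = "",
) -> AnnotationDataset:
    """Parse a GMT stream (set-name TAB description TAB gene...) into a dataset.

    Blank lines are skipped with a warning.  Members are normalized and
    de-duplicated per set; line order is preserved.  The universe defaults
    to the union of all members unless ``universe_override`` is given.

    Raises
    ------
    GmtFormatError
        For a line with fewer than 3 fields (reported with its line
        number), duplicate set names, or an empty file.
    """
    gene_sets: list[GeneSetAnnotation] = []
    seen_names: set[str] = set()
    for lineno, line in enumerate(source, start=1):
        stripped = line.rstrip("\n").rstrip("\r")
        if not stripped.strip():
            logger.warning("GMT %s: skipping blank line %d", dataset_id, lineno)
            continue
        fields = stripped.split("\t")
        if len(fields) < 3:
            raise GmtFormatError(
                f"GMT line {lineno}: expected at least 3 tab-separated "
                f"fields (name, description, genes...), got {len(fields)}"
            )
        name, description = fields[0], fields[1]
        if name in seen_names:
            raise GmtFormatError(
                f"GMT line {lineno}: duplicate gene set name {name!r}"
            )
        seen_names.add(name)
        members = frozenset(
            normalize_gene_id(label) for label in fields[2:] if label.strip()
        )
        if not members:
            raise GmtFormatError(
                f"GMT line {lineno}: gene set {name!r} has no gene labels"
            )
        gene_sets.append(
            GeneSetAnnotation(
                set_id=name, display_name=name, description=description,
                members=members,
            )
        )
    if not gene_sets:
        raise GmtFormatError("GMT stream contains no gene sets")
    universe = (
        frozenset(universe_override) if universe_override is not None
        else frozenset()
    )
    return AnnotationDataset(
        dataset_id=dataset_id, title=title, citation=citation,
        gene_sets=gene_sets, universe=universe,
    )


def write_gmt(dataset: AnnotationDataset, sink: IO[str]) -> None:
    """Write a dataset as GMT, one line per gene set in dataset order.

    Members are written as their raw labels, sorted by normalized key so
    serialization is deterministic.
    """
    if not dataset.gene_sets:
        raise GmtFormatError(
            "cannot write a GMT for a dataset with zero gene sets"
        )
    for gs in dataset.gene_sets:
        members = sorted(gs.members, key=lambda g: g.normalized_key)
        fields = [gs.set_id, gs.description] + [g.raw_label for g in members]
        sink.write("\t".join(fields) + "\n")


class GeneMembershipRecord(NamedTuple):
    """One (gene, gene set) membership found by :func:`lookup_genes`."""

    gene: GeneIdentifier
    dataset_id: str
    set_id: str
    set_display_name: str


class LookupResult(NamedTuple):
    records: list[GeneMembershipRecord]
    unmatched: list[GeneIdentifier]


def lookup_genes(
    genes: Sequence[GeneIdentifier],
    datasets: Sequence[AnnotationDataset],
) -> LookupResult:
    """Find every gene set containing each query gene, across all datasets.

    Returns one :class:`GeneMembershipRecord` per (gene, gene set)
    membership, ordered by dataset then set then gene, plus the companion
    list of genes with no membership anywhere.  Absence is not an error.
    """
    if not datasets:
        raise ValueError("lookup_genes requires at least one dataset")
    records: list[GeneMembershipRecord] = []
    matched: set[GeneIdentifier] = set()
    for ds in datasets:
        for gs in ds.gene_sets:
            for gene in genes:
                if gene in gs.members:
                    records.append(
                        GeneMembershipRecord(
                            gene, ds.dataset_id, gs.set_id, gs.display_name
                        )
                    )
                    matched.add(gene)
    unmatched = [g for g in genes if g not in matched]
    return LookupResult(records, unmatched)
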