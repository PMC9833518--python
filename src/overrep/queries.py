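"""Parsing of query gene lists and the background into a QueryCollection.

Two input modes exist.  Single mode takes one gene label per line.
Multiple mode takes a two-column comma-separated file: first column the
gene, second column the name of the list it belongs to, so clustered genes
can be tested as parallel queries.  The background list (one gene per
line) is always required: the hypergeometric model draws the query from
the background, so every query must end up a subset of it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import IO, Mapping

from .annotations import GeneIdentifier, normalize_gene_id
from .errors import EmptyQueryError, QueryFormatError, SubsetViolationError

logger = logging.getLogger(__name__)

QueryMap = dict[str, set[GeneIdentifier]]


@dataclass
class QueryCollection:
    """Named query gene lists plus the user background.

    After assembly every query is a non-empty subset of the background;
    genes dropped to enforce that are recorded per list in
    ``dropped_from_queries``.
    """

    queries: QueryMap
    background: set[GeneIdentifier]
    dropped_from_queries: dict[str, list[GeneIdentifier]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.background:
            raise EmptyQueryError("background gene list is empty")
        for name, genes in self.queries.items():
            if not genes:
                raise EmptyQueryError(f"query list {name!r} is empty")
            if not genes <= self.background:
                raise SubsetViolationError(
                    f"query list {name!r} is not a subset of the background"
                )

    @property
    def query_names(self) -> list[str]:
        return list(self.queries)


def parse_gene_list(source: IO[str]) -> set[GeneIdentifier]:
    """Parse a one-gene-per-line stream into a normalized, de-duplicated set.

    Blank lines are ignored; duplicate count (after normalization) is
    logged as a warning.
    """
    genes: set[GeneIdentifier] = set()
    n_labels = 0
    for line in source:
        label = line.strip()
        if not label:
            continue
        n_labels += 1
        genes.add(normalize_gene_id(label))
    n_dup = n_labels - len(genes)
    if n_dup:
        logger.warning("gene list: removed %d duplicate label(s)", n_dup)
    return genes


def parse_single_query(source: IO[str], list_name: str) -> QueryMap:
    """Parse a single-mode query (one gene per line) under ``list_name``."""
    genes = parse_gene_list(source)
    if not genes:
        raise EmptyQueryError(
            f"query list {list_name!r} contains no genes after parsing"
        )
    return {list_name: genes}


def parse_multi_query(source: IO[str]) -> QueryMap:
    """Parse a multiple-mode two-column CSV (gene, list-name).

    One named set is produced per distinct second-column value, in order of
    first appearance; a gene may belong to several lists.  A first row
    whose first field is "gene" or "genes" (case-insensitive) is treated as
    a header.  Within-list duplicates are removed with a warning.

    Raises
    ------
    QueryFormatError
        For a row without exactly two fields (reported with its row number).
    EmptyQueryError
        If no data rows remain.
    """
    queries: QueryMap = {}
    dup_counts: dict[str, int] = {}
    reader = csv.reader(source)
    for rowno, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 2:
            raise QueryFormatError(
                f"row {rowno}: expected 2 comma-separated fields "
                f"(gene, list), got {len(row)}"
            )
        gene_label, list_name = row[0].strip(), row[1].strip()
        if rowno == 1 and gene_label.lower() in ("gene", "genes"):
            continue  # header row
        gene = normalize_gene_id(gene_label)
        bucket = queries.setdefault(list_name, set())
        if gene in bucket:
            dup_counts[list_name] = dup_counts.get(list_name, 0) + 1
        else:
            bucket.add(gene)
    for name, count in dup_counts.items():
        logger.warning(
            "query list %r: removed %d duplicate gene(s)", name, count
        )
    if not queries:
        raise EmptyQueryError("multi-query file contains no data rows")
    return queries


def assemble_collection(
    queries: Mapping[str, set[GeneIdentifier]],
    background_source: IO[str],
    strict: bool = False,
) -> QueryCollection:
    """Join parsed queries with the background into a QueryCollection.

    Query genes absent from the background are dropped and recorded
    (default) or raise :class:`SubsetViolationError` when ``strict``.

    Raises
    ------
    EmptyQueryError
        If the background is empty, or any query list is empty after
        dropping (the offending list is named).
    """
    if not queries:
        raise EmptyQueryError("no query lists supplied")
    background = parse_gene_list(background_source)
    if not background:
        raise EmptyQueryError("background gene list is empty")
    kept: QueryMap = {}
    dropped: dict[str, list[GeneIdentifier]] = {}
    for name, genes in queries.items():
        missing = sorted(genes - background, key=lambda g: g.normalized_key)
        if missing and strict:
            names = ", ".join(g.raw_label for g in missing)
            raise SubsetViolationError(
                f"query list {name!r} contains {len(missing)} gene(s) "
                f"absent from the background: {names}"
            )
        remaining = genes & background
        if not remaining:
            raise EmptyQueryError(
                f"query list {name!r} is empty after removing genes "
                f"absent from the background"
            )
        kept[name] = remaining
        dropped[name] = missing
        if missing:
            logger.warning(
                "query list %r: dropped %d gene(s) absent from background",
                name, len(missing),
            )
    return QueryCollection(
        queries=kept, background=background, dropped_from_queries=dropped
    )
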