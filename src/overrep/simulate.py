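"""Seeded generators for synthetic universes, annotation datasets and queries.

These generators make every other module testable without any curated
download: a universe of synthetic symbols (GENE000001...), datasets of
randomly drawn (possibly overlapping) gene sets, null queries sampled
uniformly from the background, and queries with a planted fraction of a
target set's members for power / recovery checks.  All draws go through a
single ``numpy.random.default_rng`` stream keyed by an explicit integer
seed, so every artifact is bit-reproducible.

The default shipped fixture mirrors the shape of a small curated
collection of murine macrophage signatures: one dataset of 11 sets over a
3348-gene universe, one of 7 sets, and one of 5 sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotations import (
    AnnotationDataset,
    GeneIdentifier,
    GeneSetAnnotation,
    normalize_gene_id,
    write_gmt,
)
from .errors import ParameterError


def make_universe(size: int, seed: int = 0) -> set[GeneIdentifier]:
    """A universe of ``size`` unique synthetic gene symbols.

    Labels are positional (GENE000001 ... GENE<size>), hence identical
    across seeds; the seed argument exists only for interface symmetry
    with the other generators.
    """
    if size < 1:
        raise ParameterError(f"universe size must be >= 1, got {size}")
    return {normalize_gene_id(f"GENE{i:06d}") for i in range(1, size + 1)}


def _sorted_pool(genes: set[GeneIdentifier]) -> list[GeneIdentifier]:
    return sorted(genes, key=lambda g: g.normalized_key)


def make_annotation_dataset(
    universe: set[GeneIdentifier],
    n_sets: int,
    size_range: tuple[int, int],
    seed: int,
    dataset_id: str = "synthetic",
    full_universe: bool = False,
) -> AnnotationDataset:
    """A dataset of ``n_sets`` gene sets sampled from ``universe``.

    Set sizes are drawn uniformly in ``size_range`` (inclusive) and
    members sampled without replacement per set, so sets may overlap one
    another.  The dataset universe is the union of the sets unless
    ``full_universe`` pins it to the whole input universe (modelling
    collections whose total gene count exceeds the union of reported
    sets).
    """
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ParameterError(
            f"infeasible set size range {size_range} for a universe of "
            f"{len(universe)} genes"
        )
    if n_sets < 1:
        raise ParameterError(f"n_sets must be >= 1, got {n_sets}")
    rng = np.random.default_rng(seed)
    pool = _sorted_pool(universe)
    gene_sets = []
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(pool), size=size, replace=False)
        members = frozenset(pool[j] for j in idx)
        gene_sets.append(
            GeneSetAnnotation(
                set_id=f"{dataset_id}_set{i:02d}",
                display_name=f"{dataset_id} set {i}",
                description=f"synthetic gene set {i} of {dataset_id}",
                members=members,
            )
        )
    return AnnotationDataset(
        dataset_id=dataset_id,
        title=f"Synthetic dataset {dataset_id}",
        citation="synthetic fixture",
        gene_sets=gene_sets,
        universe=frozenset(universe) if full_universe else frozenset(),
    )


def make_null_query(
    background: set[GeneIdentifier], size: int, seed: int
) -> set[GeneIdentifier]:
    """A uniform without-replacement sample of ``size`` background genes."""
    if not 1 <= size <= len(background):
        raise ParameterError(
            f"query size must lie in [1, {len(background)}], got {size}"
        )
    rng = np.random.default_rng(seed)
    pool = _sorted_pool(background)
    idx = rng.choice(len(pool), size=size, replace=False)
    return {pool[j] for j in idx}


def make_enriched_query(
    background: set[GeneIdentifier],
    target: GeneSetAnnotation,
    total: int,
    planted_fraction: float,
    seed: int,
) -> set[GeneIdentifier]:
    """A query with a planted fraction of a target set's members.

    ``round(planted_fraction * total)`` genes are sampled from the target
    set (within the background) and the remainder from the background
    outside the target, so the expected overlap is controlled exactly.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ParameterError(
            f"planted_fraction must lie in [0, 1], got {planted_fraction}"
        )
    n_planted = round(planted_fraction * total)
    inside = _sorted_pool(background & target.members)
    outside = _sorted_pool(background - target.members)
    if n_planted > len(inside):
        raise ParameterError(
            f"cannot plant {n_planted} genes: only {len(inside)} target "
            f"members lie in the background"
        )
    n_rest = total - n_planted
    if n_rest > len(outside):
        raise ParameterError(
            f"cannot draw {n_rest} non-target genes: only {len(outside)} "
            f"available in the background"
        )
    rng = np.random.default_rng(seed)
    query: set[GeneIdentifier] = set()
    if n_planted:
        idx = rng.choice(len(inside), size=n_planted, replace=False)
        query |= {inside[j] for j in idx}
    if n_rest:
        idx = rng.choice(len(outside), size=n_rest, replace=False)
        query |= {outside[j] for j in idx}
    return query


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one simulated study (universe, datasets, queries)."""

    universe_size: int = 3348
    n_sets: int = 11
    set_size_range: tuple[int, int] = (200, 400)
    n_queries: int = 3
    query_size: int = 150
    planted_set: Optional[str] = None
    planted_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if hi > self.universe_size:
            raise ParameterError(
                "set sizes cannot exceed the universe size"
            )
        if self.planted_set is not None and not (
            0.0 <= self.planted_fraction <= 1.0
        ):
            raise ParameterError("planted_fraction must lie in [0, 1]")


# shapes mirroring a small curated macrophage-signature collection
DEFAULT_DATASET_SHAPES: tuple[tuple[str, int], ...] = (
    ("tissue_macrophages", 11),
    ("microglia_development", 7),
    ("lung_injury", 5),
)


def write_fixture(
    outdir: str | Path,
    spec: FixtureSpec = FixtureSpec(),
    dataset_shapes: Sequence[tuple[str, int]] = DEFAULT_DATASET_SHAPES,
) -> dict[str, Path]:
    """Write a complete synthetic study to ``outdir``.

    Produces one GMT per dataset shape, a background list covering the
    whole universe, a single-mode query and a multi-mode two-column CSV
    (with a planted signal in the first list when ``spec.planted_set``
    names a gene set).  Returns the paths written, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe = make_universe(spec.universe_size, spec.seed)
    paths: dict[str, Path] = {}
    datasets = []
    for i, (name, n_sets) in enumerate(dataset_shapes):
        ds = make_annotation_dataset(
            universe, n_sets, spec.set_size_range,
            seed=spec.seed + 101 + i, dataset_id=name,
        )
        datasets.append(ds)
        path = outdir / f"{name}.gmt"
        with open(path, "w") as fh:
            write_gmt(ds, fh)
        paths[f"gmt:{name}"] = path

    bg_path = outdir / "background.txt"
    with open(bg_path, "w") as fh:
        for g in _sorted_pool(universe):
            fh.write(g.raw_label + "\n")
    paths["background"] = bg_path

    queries: dict[str, set[GeneIdentifier]] = {}
    for q in range(1, spec.n_queries + 1):
        name = f"cluster{q}"
        if q == 1 and spec.planted_set is not None:
            target = None
            for ds in datasets:
                try:
                    target = ds.get_set(spec.planted_set)
                    break
                except KeyError:
                    continue
            if target is None:
                raise ParameterError(
                    f"planted_set {spec.planted_set!r} not found in any "
                    f"generated dataset"
                )
            queries[name] = make_enriched_query(
                universe, target, spec.query_size,
                spec.planted_fraction, seed=spec.seed + 500,
            )
        else:
            queries[name] = make_null_query(
                universe, spec.query_size, seed=spec.seed + 500 + q
            )

    single_path = outdir / "query_single.txt"
    with open(single_path, "w") as fh:
        for g in _sorted_pool(queries["cluster1"]):
            fh.write(g.raw_label + "\n")
    paths["query_single"] = single_path

    multi_path = outdir / "query_multi.csv"
    with open(multi_path, "w") as fh:
        fh.write("gene,list\n")
        for name, genes in queries.items():
            for g in _sorted_pool(genes):
                fh.write(f"{g.raw_label},{name}\n")
    paths["query_multi"] = multi_path
    return paths
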