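"""Result tables, heatmap matrices and rendering, and the unmatched report.

The results table lists significantly enriched gene sets with the full
hypergeometric parameters and overlap genes.  The heatmap classifies every
(query x gene set) cell as enriched (p <= 0.05 by default), depleted
(p >= 0.95) or neither, rendered either as a three-color binary image or
as a diverging gradient over a signed -log10 score.  The unmatched report
lists query, background and dataset genes that fall outside each other's
scope so users can spot identifier problems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import ListedColormap  # noqa: E402

from .annotations import AnnotationDataset
from .enrichment import EnrichmentResult
from .errors import ParameterError
from .queries import QueryCollection

logger = logging.getLogger(__name__)

DEFAULT_ENRICH_CUTOFF = 0.05
DEFAULT_DEPLETE_CUTOFF = 0.95

TABLE_COLUMNS = [
    "dataset", "annotation", "query", "p_value", "fdr",
    "N", "n", "K", "k", "overlap_genes",
]

# floor for -log10 of a vanishing depletion complement (p_enrich == 1)
_LOG_FLOOR = 1e-300


def results_table(
    results: Sequence[EnrichmentResult],
    cutoff: float = DEFAULT_ENRICH_CUTOFF,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Tabulate significantly enriched results.

    Rows are filtered to raw p (or FDR when ``use_fdr``) <= ``cutoff``
    (inclusive) and sorted ascending by p, then dataset and annotation.
    Overlap genes are semicolon-joined in normalized-key order.
    """
    if not results:
        raise ParameterError("results_table requires at least one result")
    rows = []
    for r in results:
        criterion = r.fdr if use_fdr else r.p_enrich
        if criterion <= cutoff:
            rows.append(
                {
                    "dataset": r.dataset_id,
                    "annotation": r.set_id,
                    "query": r.query_name,
                    "p_value": r.p_enrich,
                    "fdr": r.fdr,
                    "N": r.params.N,
                    "n": r.params.n,
                    "K": r.params.K,
                    "k": r.params.k,
                    "overlap_genes": ";".join(
                        g.raw_label for g in r.overlap_genes
                    ),
                }
            )
    frame = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if frame.empty:
        logger.warning(
            "no results pass the %s cutoff %g",
            "FDR" if use_fdr else "p-value", cutoff,
        )
        return frame
    return frame.sort_values(
        ["p_value", "dataset", "annotation"], kind="mergesort"
    ).reset_index(drop=True)


def results_table_csv(
    results: Sequence[EnrichmentResult],
    cutoff: float = DEFAULT_ENRICH_CUTOFF,
    use_fdr: bool = False,
) -> str:
    """The results table serialized as RFC-4180 CSV text."""
    return results_table(results, cutoff, use_fdr).to_csv(index=False)


@dataclass
class HeatmapMatrix:
    """Classified (query x gene set) matrix for heatmap rendering.

    ``classes`` holds "enriched" / "depleted" / "neither" / "missing"
    strings and ``scores`` the signed significance: -log10(p_enrich) for
    the enriched side (positive), -(-log10(1 - p_enrich)) for the depleted
    side (negative).  Rows are query names; columns are MultiIndexed
    (dataset_id, set_id) in dataset gene-set order.
    """

    classes: pd.DataFrame
    scores: pd.DataFrame
    enrich_cutoff: float
    deplete_cutoff: float
    use_fdr: bool = False

    @property
    def datasets(self) -> list[str]:
        return list(dict.fromkeys(self.classes.columns.get_level_values(0)))

    def for_dataset(self, dataset_id: str) -> "HeatmapMatrix":
        return HeatmapMatrix(
            classes=self.classes[[dataset_id]],
            scores=self.scores[[dataset_id]],
            enrich_cutoff=self.enrich_cutoff,
            deplete_cutoff=self.deplete_cutoff,
            use_fdr=self.use_fdr,
        )


def _signed_score(p: float) -> float:
    if p < 0.5:
        return -math.log10(p)
    return math.log10(max(1.0 - p, _LOG_FLOOR))


def heatmap_matrix(
    results: Sequence[EnrichmentResult],
    enrich_cutoff: float = DEFAULT_ENRICH_CUTOFF,
    deplete_cutoff: float = DEFAULT_DEPLETE_CUTOFF,
    use_fdr: bool = False,
    datasets: Optional[Sequence[AnnotationDataset]] = None,
) -> HeatmapMatrix:
    """Classify every (query, gene set) cell by the two p-value cutoffs.

    A cell is enriched iff p <= ``enrich_cutoff`` and depleted iff
    p >= ``deplete_cutoff`` (both inclusive; with ``use_fdr`` the FDR
    replaces p on the enrichment side only, as depletion has no adjusted
    value).  Passing ``datasets`` fixes the full column set so skipped
    tests appear as "missing"; otherwise columns come from the results.
    """
    if not enrich_cutoff < deplete_cutoff:
        raise ParameterError(
            f"enrich_cutoff ({enrich_cutoff}) must be below "
            f"deplete_cutoff ({deplete_cutoff})"
        )
    if datasets is not None:
        columns = [
            (ds.dataset_id, gs.set_id)
            for ds in datasets for gs in ds.gene_sets
        ]
    else:
        columns = list(
            dict.fromkeys((r.dataset_id, r.set_id) for r in results)
        )
    queries = list(dict.fromkeys(r.query_name for r in results))
    col_index = pd.MultiIndex.from_tuples(columns, names=["dataset", "set"])
    classes = pd.DataFrame("missing", index=queries, columns=col_index)
    scores = pd.DataFrame(np.nan, index=queries, columns=col_index)
    for r in results:
        key = (r.dataset_id, r.set_id)
        if key not in col_index:
            continue
        p = r.fdr if use_fdr else r.p_enrich
        if p <= enrich_cutoff:
            label = "enriched"
        elif r.p_enrich >= deplete_cutoff:
            label = "depleted"
        else:
            label = "neither"
        classes.loc[r.query_name, key] = label
        scores.loc[r.query_name, key] = _signed_score(r.p_enrich)
    return HeatmapMatrix(
        classes=classes, scores=scores,
        enrich_cutoff=enrich_cutoff, deplete_cutoff=deplete_cutoff,
        use_fdr=use_fdr,
    )


_BINARY_COLORS = {
    "enriched": "#b2182b",   # red
    "depleted": "#2166ac",   # blue
    "neither": "#f7f7f7",
    "missing": "#cccccc",
}


def _render_one(matrix: HeatmapMatrix, style: str, path: Path) -> None:
    classes = matrix.classes
    n_rows, n_cols = classes.shape
    fig_w = max(3.0, 0.35 * n_cols + 2.0)
    fig_h = max(3.0, 0.45 * n_rows + 2.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h), layout="constrained")
    if style == "binary":
        order = ["enriched", "depleted", "neither", "missing"]
        codes = classes.apply(
            lambda col: col.map({name: i for i, name in enumerate(order)})
        ).to_numpy(dtype=float)
        cmap = ListedColormap([_BINARY_COLORS[name] for name in order])
        ax.imshow(codes, cmap=cmap, vmin=-0.5, vmax=3.5, aspect="auto")
    elif style == "gradient":
        values = matrix.scores.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        vmax = max(1.0, float(np.max(np.abs(finite))) if finite.size else 1.0)
        im = ax.imshow(
            values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto"
        )
        fig.colorbar(
            im, ax=ax, shrink=0.8,
            label="signed -log10 p (enrich + / deplete -)",
        )
    else:
        raise ParameterError(
            f"unknown heatmap style {style!r}; use 'binary' or 'gradient'"
        )
    ax.set_xticks(range(n_cols))
    ax.set_xticklabels(
        [f"{d}:{s}" for d, s in classes.columns], rotation=90, fontsize=7
    )
    ax.set_yticks(range(n_rows))
    ax.set_yticklabels(classes.index, fontsize=8)
    ax.set_xlabel("annotated gene sets")
    ax.set_ylabel("query lists")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_heatmap(
    matrix: HeatmapMatrix,
    style: str = "binary",
    sink: str | Path = "heatmap.png",
    split_by_dataset: bool = False,
) -> list[Path]:
    """Render the heatmap matrix to PNG file(s); returns the paths written.

    With ``split_by_dataset`` one image per dataset is written, suffixed
    with the dataset id.
    """
    if matrix.classes.empty:
        raise ParameterError("cannot render an empty heatmap matrix")
    sink = Path(sink)
    written: list[Path] = []
    if split_by_dataset:
        for dataset_id in matrix.datasets:
            path = sink.with_name(
                f"{sink.stem}_{dataset_id}{sink.suffix or '.png'}"
            )
            _render_one(matrix.for_dataset(dataset_id), style, path)
            written.append(path)
    else:
        _render_one(matrix, style, sink)
        written.append(sink)
    return written


def unmatched_report(
    collection: QueryCollection,
    datasets: Sequence[AnnotationDataset],
) -> str:
    """Three-section plain-text report of genes outside each other's scope.

    Sections: query genes absent from every dataset universe (listed with
    their source list), background genes absent from every universe, and
    dataset universe genes absent from the background.  Each section is
    sorted and counted.
    """
    all_universes: set = set()
    for ds in datasets:
        all_universes |= ds.universe
    lines: list[str] = []

    lines.append("## Query genes not found in any dataset universe")
    total = 0
    for name, genes in collection.queries.items():
        missing = sorted(
            (g for g in genes if g not in all_universes),
            key=lambda g: g.normalized_key,
        )
        total += len(missing)
        for g in missing:
            lines.append(f"{g.raw_label}\t(list: {name})")
    lines.insert(1, f"# count: {total}")

    bg_missing = sorted(
        (g for g in collection.background if g not in all_universes),
        key=lambda g: g.normalized_key,
    )
    lines.append("")
    lines.append("## Background genes not found in any dataset universe")
    lines.append(f"# count: {len(bg_missing)}")
    lines.extend(g.raw_label for g in bg_missing)

    ds_missing = sorted(
        (g for g in all_universes if g not in collection.background),
        key=lambda g: g.normalized_key,
    )
    lines.append("")
    lines.append("## Dataset universe genes not found in the background")
    lines.append(f"# count: {len(ds_missing)}")
    lines.extend(g.raw_label for g in ds_missing)
    return "\n".join(lines) + "\n"
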