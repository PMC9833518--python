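# overrep

Over-representation analysis (ORA) of gene lists against curated gene-set
collections — a library and command-line tool for transcriptomics (bulk and
single-cell) workflows on mouse gene identifiers (MGI symbols or Ensembl
`ENSMUSG` IDs).

Given one or more **query** gene lists (e.g. expression clusters), a
**background** gene list, and one or more annotation collections in **GMT**
format, `overrep` asks, for every annotated gene set: does the query contain
more of the set's genes than expected by chance?

## The statistic

For a background of `N` genes, of which `K` belong to an annotated gene set,
and a query of `n` genes drawn from that background with `k` genes in the
set, the enrichment p-value is the hypergeometric upper tail

    P(X ≥ k) = Σ_{i=k}^{min(n,K)}  C(n,i) · C(N−n, K−i) / C(N,K)

The complement `1 − p` scores depletion. Two settings resolve `N` and `n`
before testing:

* **INTERSECT** (default): background and query are intersected with the
  dataset's gene universe — only genes the collection knows about count.
* **USER**: the supplied background and query are used as-is (preferable
  when the background barely overlaps the collection).

All performed tests are corrected jointly by Benjamini–Hochberg FDR; the
comparison count `m` is the number of query lists × annotations across all
selected datasets. Outputs are a sortable results table (CSV), a
per-(query × set) heatmap classified at p ≤ 0.05 (enriched) / p ≥ 0.95
(depleted), an annotation-overlap network (nodes = gene sets, edge weight =
Jaccard index, node color = −log10 p for one query; GraphML or Cytoscape
JSON), and an unmatched-gene report.

## Worked example

Simulate a small study — three GMT collections over a 2000-gene universe,
a background covering the universe, and three query clusters, the first of
which has 60% of its genes planted from `tissue_macrophages_set01`:

```sh
overrep simulate --outdir demo --seed 1 --universe-size 2000 \
    --query-size 120 --planted-set tissue_macrophages_set01 \
    --planted-fraction 0.6
overrep enrich --multi-query demo/query_multi.csv \
    --background demo/background.txt \
    --gmt demo/tissue_macrophages.gmt \
    --gmt demo/microglia_development.gmt \
    --gmt demo/lung_injury.gmt \
    --mode intersect --outdir out
```

which prints

```
69 tests performed over 3 queries and 23 gene sets
outputs written to out (results.csv, 1 heatmap image(s), network.graphml, unmatched.txt, run_log.txt)
```

and the top of `out/results.csv` reads (overlap column truncated here):

```
dataset,annotation,query,p_value,fdr,N,n,K,k,overlap_genes
tissue_macrophages,tissue_macrophages_set01,cluster1,1.0385431347678556e-32,7.165947629898204e-31,1722,110,289,72,GENE000017;...
tissue_macrophages,tissue_macrophages_set07,cluster2,0.041473059294471655,0.7956996721525798,1722,105,222,20,GENE000048;...
```

Reading the first row: under INTERSECT the effective background is the
1722 genes shared by the user background and the collection's universe;
110 of the 120 query genes fall inside it; the annotated set holds 289 of
those background genes, and 72 of them appear in the query — an overlap
whose chance probability is ~1e-32, still ~7e-31 after FDR. The planted
signal is recovered; the second row shows a marginal hit (p = 0.041) for a
null cluster that does not survive correction (FDR = 0.80).

Individual genes can be looked up without running an analysis:

```sh
overrep genes GENE000017 --gmt demo/tissue_macrophages.gmt
```

## Layout

| Module | Role |
| --- | --- |
| `overrep.annotations` | datasets / gene sets / genes model, GMT I/O, identifier normalization, gene lookup |
| `overrep.queries` | single- and multiple-mode query parsing, background assembly |
| `overrep.enrichment` | hypergeometric tail, background resolution, BH-FDR, the full sweep |
| `overrep.network` | gene-set overlap graph, significance overlay, GraphML/Cytoscape export |
| `overrep.reporting` | results table, heatmap classification and rendering, unmatched report |
| `overrep.simulate` | seeded synthetic universes, datasets and queries |
| `overrep.cli` | `overrep` command (`enrich`, `genes`, `graph`, `info`, `simulate`) |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
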