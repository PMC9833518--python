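# Methods

## Model

Each test treats the query list as a size-`n` draw without replacement
from a background universe of `N` genes, `K` of which carry the annotation
under test. The observed overlap `k` is scored by the hypergeometric upper
tail `P(X ≥ k)`, reported as the enrichment p-value. Independence between
tests is not modelled: each (query × gene set) pair is a separate
hypothesis, and the joint multiplicity is handled by Benjamini–Hochberg
FDR over all performed tests, with the comparison count `m` equal to the
number of query lists times the number of annotations across all selected
datasets. Skipped combinations (see below) are excluded from `m`, since an
unperformed comparison contributes no hypothesis.

**Depletion.** Depletion significance is reported as the literal
complement `1 − P(X ≥ k)`, i.e. `P(X ≤ k−1)`. Note this is *not* the
conventional lower tail `P(X ≤ k)`: the two differ by the point mass at
`k`. The complement convention makes enrichment and depletion sum to 1
exactly, so a single slider value (0.05 / 0.95 by default) classifies both
sides; the difference only matters for coarse supports where the point
mass is large. FDR adjustment is applied to enrichment p-values only;
depleted cells are read from the same value via the upper cutoff.

**Background resolution.** Under INTERSECT, both the background and the
query are intersected with the dataset's universe before counting, and
this is done per dataset — so `N` and `n` can differ across collections
within one run. Because gene sets are contained in their universe, `K`
under INTERSECT equals the plain overlap of the user background with the
gene set; this is asserted by a test rather than assumed. If intersection
empties the background or the query, the dataset is skipped and reported,
and the run only fails if *no* dataset was testable (the error advises
USER mode). A gene set with `K = 0` is likewise skipped with a reason: no
test is possible when the background contains none of its members.

## Numerics

The tail is computed in floating point without ever forming the full
distribution: the largest term in the summation range — located at the
distribution's mode — is evaluated exactly from integer binomial
coefficients (arbitrary-precision integers, one correctly rounded
division), and the remaining terms follow from the term ratio

    t(i+1) / t(i) = (n−i)(K−i) / ((i+1)(N−n−K+i+1)),

swept in both directions and accumulated with compensated summation
(`math.fsum`). Anchoring at the mode avoids the underflow that an anchor
at `i = k` suffers when the tail mass lies far above `k`. Against exact
rational arithmetic the absolute error stays at machine precision
(~2e-16) for backgrounds up to at least 2000 genes, and the
implementation agrees with an independent survival-function evaluation to
~1e-15 up to `N` = 20000. When the true tail underflows double precision
the value is floored at 1e-320 so that `p > 0` and `−log10 p` stays
finite. The `k = 0` tail is returned as exactly 1.

BH adjustment is the standard step-up: sorted p-values are multiplied by
`m / rank`, a running minimum is taken from the largest rank downward,
and values are capped at 1. The divisor `m` may exceed the number of
supplied p-values, which the enrichment sweep never needs (it always
tests everything it counts) but the function exposes for completeness.

## Identifier handling

Matching is by normalized key only: symbols are upper-cased
(`Fcgr1` ≡ `FCGR1`), Ensembl mouse IDs are upper-cased with any
`.<digits>` version suffix removed (`ENSMUSG00000015947.12` ≡
`ENSMUSG00000015947`). No cross-mapping between the two kinds is
attempted — a set annotated by symbol will not match a query given as
Ensembl IDs. Mixed membership within one set is permitted. Query genes
absent from the background are dropped and reported (strict mode turns
this into an error); genes absent from every dataset universe are listed
in the unmatched report rather than silently ignored.

A dataset's universe defaults to the union of its gene sets, since a GMT
file carries no separate total-gene count; an explicit universe file can
be supplied for collections whose totals exceed that union (the worked
background-resolution example uses one: a 5000-gene universe holding a
460-gene set).

## Defaults and parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `--mode` | `intersect` | background resolution setting |
| `--alpha` | 0.05 | enrichment cutoff (inclusive, raw p unless `--use-fdr`) |
| `--deplete-cutoff` | 0.95 | depletion cutoff (inclusive) |
| `--min-weight` | 0.05 | minimum network edge weight shown |
| `--edge-metric` | `jaccard` | edge weight; `overlap` gives the overlap coefficient |
| `--heatmap-style` | `binary` | three-color classification; `gradient` maps the signed score |

The heatmap's gradient score is `−log10 p` on the enriched side
(positive) and `log10(1 − p)` on the depleted side (negative); cells for
skipped tests are marked missing. Threshold comparisons are inclusive on
both sides. Ordering everywhere is deterministic: results by dataset,
then gene-set, then query order; overlap genes and GMT members by
normalized key; graph nodes and edges sorted at build time — two runs
with identical inputs produce byte-identical CSV and network files.

## Synthetic data

The generators draw from a single `numpy.random.default_rng` stream per
operation, keyed by an explicit integer seed. `make_universe` produces
positional labels (`GENE000001`…), so universes are identical across
seeds by design; datasets draw set sizes uniformly within a range and
members without replacement per set, so sets overlap each other the way
co-regulated signatures do. The default fixture shapes (11 + 7 + 5 gene
sets, a ~3348-gene universe) mirror the proportions of a small curated
collection of murine macrophage signatures without reproducing any real
membership. Planted queries take `round(f·total)` genes from a target
set and the rest from outside it, giving exact control of the true
overlap for power checks.

What the synthetic data does *not* emulate: correlated annotation
structure across datasets (real collections annotate the same pathways
repeatedly), non-uniform gene-level properties (expression level, length
or GC biases that make real backgrounds non-exchangeable), and
identifier noise (aliases, retired symbols). Passing calibration and
recovery tests here therefore demonstrates correctness of the statistics
under the model's own assumptions, not robustness to those real-data
effects.

## Validation problem sizes

The test suite validates the tail exhaustively for all admissible
parameter combinations with `N ≤ 12` against direct enumeration of all
`C(N,K)` annotation placements, and against exact rational arithmetic for
random cases up to `N = 2000`. Null calibration uses 1000 uniform queries
of 50 genes against a 100-gene set in a 2000-gene universe; recovery uses
200 replicates of a 100-gene query with 80 genes planted from a 120-gene
target among nine decoy sets. These sizes give binomial standard errors
small enough for 3-sigma bounds while keeping the full suite under a
minute of compute.

## Known limitations

* Depletion uses the complement convention described above; users wanting
  the conventional `P(X ≤ k)` tail must shift by one.
* No odds-ratio or effect-size column; p-value magnitude is not
  comparable across tests with different parameters.
* No ortholog mapping or identifier translation; inputs from another
  species must be converted to mouse identifiers upstream.
* The network export is static; interactive layout belongs to the
  consumer (Cytoscape reads both export formats).
* `m` counts performed tests; selecting fewer datasets changes the
  correction, so FDR values are comparable only within one run.
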