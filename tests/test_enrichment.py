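"""The hypergeometric tail, background resolution, BH-FDR, and the
full enrichment sweep, validated against independent oracles
(exhaustive placement enumeration, exact rational arithmetic, scipy,
statsmodels)."""

import itertools
import math
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom as scipy_hypergeom
from statsmodels.stats.multitest import multipletests

import overrep as ov
from overrep.enrichment import BackgroundMode


def exact_tail(N: int, n: int, K: int, k: int) -> Fraction:
    """Exact rational upper tail, summed from integer binomials."""
    num = sum(comb(n, i) * comb(N - n, K - i)
              for i in range(k, min(n, K) + 1))
    return Fraction(num, comb(N, K))


def enumerated_tail(N: int, n: int, K: int, k: int) -> Fraction:
    """Brute-force oracle: enumerate all C(N, K) annotation placements
    and count those overlapping the first n genes in >= k positions."""
    query = set(range(n))
    hits = sum(
        1
        for placement in itertools.combinations(range(N), K)
        if len(query.intersection(placement)) >= k
    )
    return Fraction(hits, comb(N, K))


def tail(N, n, K, k):
    return ov.hypergeom_upper_tail(ov.HypergeomParams(N=N, n=n, K=K, k=k))


class TestHypergeomUpperTail:
    def test_worked_value_11_over_42(self):
        assert tail(10, 5, 4, 3) == pytest.approx(11 / 42, abs=1e-12)
        # and the counting oracle agrees: 55 of 210 placements
        assert enumerated_tail(10, 5, 4, 3) == Fraction(55, 210)

    def test_k_zero_covers_full_support(self):
        assert tail(10, 5, 4, 0) == 1.0

    def test_all_background_annotated_is_deterministic(self):
        assert tail(8, 3, 8, 3) == 1.0
        assert tail(50, 7, 50, 7) == 1.0

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(N=5, n=6, K=2, k=1), "n <= N"),
            (dict(N=5, n=3, K=6, k=1), "K <= N"),
            (dict(N=5, n=2, K=3, k=3), "min"),
            (dict(N=5, n=-1, K=2, k=0), "non-negative"),
        ],
    )
    def test_invariant_violations_name_the_inequality(self, kwargs, match):
        with pytest.raises(ov.ParameterError, match=match):
            ov.HypergeomParams(**kwargs)

    def test_matches_enumeration_oracle_small_N(self):
        for N in range(1, 9):
            for n in range(1, N + 1):
                for K in range(1, N + 1):
                    for k in range(0, min(n, K) + 1):
                        expected = float(enumerated_tail(N, n, K, k))
                        assert tail(N, n, K, k) == pytest.approx(
                            expected, abs=1e-12
                        ), (N, n, K, k)

    @given(st.data())
    def test_matches_exact_rational_arithmetic(self, data):
        N = data.draw(st.integers(2, 2000))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert tail(N, n, K, k) == pytest.approx(
            float(exact_tail(N, n, K, k)), abs=1e-12
        )

    @given(st.data())
    def test_matches_scipy_survival_function(self, data):
        N = data.draw(st.integers(2, 5000))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert tail(N, n, K, k) == pytest.approx(
            scipy_hypergeom.sf(k - 1, N, K, n), rel=1e-9, abs=1e-12
        )

    def test_strictly_decreasing_in_k(self):
        N, n, K = 200, 40, 60
        values = [tail(N, n, K, k) for k in range(min(n, K) + 1)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @given(st.data())
    def test_symmetric_in_n_and_K(self, data):
        N = data.draw(st.integers(2, 500))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert tail(N, n, K, k) == pytest.approx(
            tail(N, K, n, k), rel=1e-12
        )


class TestResolveBackground:
    @pytest.fixture
    def worked_example(self):
        """Background 7000, dataset universe 5000, intersection 4000;
        query 560 with 400 inside the universe and 100 in the set."""
        labels = [f"G{i:05d}" for i in range(1, 8001)]
        g = [None] + [ov.normalize_gene_id(x) for x in labels]
        universe = frozenset(g[1:5001])
        background = set(g[1001:8001])                     # 7000 genes
        query = set(g[1001:1101]) | set(g[1461:1761]) | set(g[5001:5161])
        gene_set = ov.GeneSetAnnotation(
            "target", "target", "", frozenset(g[1001:1461])  # 460 genes
        )
        ds = ov.AnnotationDataset(
            dataset_id="worked", gene_sets=[gene_set], universe=universe
        )
        return query, background, ds, gene_set

    def test_intersect_vs_user_background_sizes(self, worked_example):
        query, background, ds, _ = worked_example
        assert len(query) == 560
        eff_bg, eff_q = ov.resolve_background(
            query, background, ds, BackgroundMode.INTERSECT
        )
        assert len(eff_bg) == 4000
        assert len(eff_q) == 400
        eff_bg_u, eff_q_u = ov.resolve_background(
            query, background, ds, BackgroundMode.USER
        )
        assert len(eff_bg_u) == 7000
        assert len(eff_q_u) == 560

    def test_overlap_is_100_in_both_modes(self, worked_example):
        query, background, ds, gene_set = worked_example
        for mode in BackgroundMode:
            eff_bg, eff_q = ov.resolve_background(
                query, background, ds, mode
            )
            params, overlap, _ = ov.test_one(eff_q, eff_bg, gene_set)
            assert params.k == len(overlap) == 100
            assert params.K == 460

    def test_background_inside_universe_makes_modes_equal(self, gene_set):
        background = gene_set("g1", "g2", "g3", "g4")
        query = gene_set("g1", "g2")
        ds = ov.AnnotationDataset(
            dataset_id="d",
            gene_sets=[ov.GeneSetAnnotation(
                "S", "S", "", frozenset(gene_set("g1", "g3")))],
            universe=frozenset(gene_set("g1", "g2", "g3", "g4", "g5")),
        )
        assert ov.resolve_background(
            query, background, ds, BackgroundMode.INTERSECT
        ) == ov.resolve_background(
            query, background, ds, BackgroundMode.USER
        )

    def test_disjoint_universe_is_degenerate_not_a_crash(self, gene_set):
        ds = ov.AnnotationDataset(
            dataset_id="d",
            gene_sets=[ov.GeneSetAnnotation(
                "S", "S", "", frozenset(gene_set("x1")))],
        )
        with pytest.raises(ov.DegenerateBackgroundError):
            ov.resolve_background(
                gene_set("g1"), gene_set("g1", "g2"), ds,
                BackgroundMode.INTERSECT,
            )

    def test_query_must_be_subset_of_background(self, gene_set):
        ds = ov.AnnotationDataset(
            dataset_id="d",
            gene_sets=[ov.GeneSetAnnotation(
                "S", "S", "", frozenset(gene_set("g1")))],
        )
        with pytest.raises(ov.ParameterError):
            ov.resolve_background(
                gene_set("g9"), gene_set("g1"), ds, BackgroundMode.USER
            )


class TestTestOne:
    def test_counts_by_hand(self, gene_set):
        query = gene_set("g1", "g2", "g3")
        background = gene_set(*(f"g{i}" for i in range(1, 11)))
        gs = ov.GeneSetAnnotation(
            "S", "S", "", frozenset(gene_set("g3", "g4")))
        params, overlap, p = ov.test_one(query, background, gs)
        assert (params.N, params.n, params.K, params.k) == (10, 3, 2, 1)
        assert [g.normalized_key for g in overlap] == ["G3"]
        assert p == pytest.approx(float(exact_tail(10, 3, 2, 1)))

    def test_disjoint_set_gives_p_one(self, gene_set):
        query = gene_set("g1", "g2")
        background = gene_set("g1", "g2", "g3", "g4")
        gs = ov.GeneSetAnnotation(
            "S", "S", "", frozenset(gene_set("g3", "g4")))
        _, overlap, p = ov.test_one(query, background, gs)
        assert overlap == [] and p == 1.0

    def test_full_annotation_gives_p_one(self, gene_set):
        background = gene_set("g1", "g2", "g3")
        gs = ov.GeneSetAnnotation(
            "S", "S", "", frozenset(background))
        params, _, p = ov.test_one(gene_set("g1", "g2"), background, gs)
        assert params.k == params.n and p == 1.0

    def test_K_zero_is_skipped_with_reason(self, gene_set):
        background = gene_set("g1", "g2")
        gs = ov.GeneSetAnnotation(
            "S", "S", "", frozenset(gene_set("x1")))
        with pytest.raises(ov.DegenerateBackgroundError, match="K = 0"):
            ov.test_one(gene_set("g1"), background, gs)


class TestBhAdjust:
    def test_single_test_unchanged(self):
        assert ov.bh_adjust([0.04], 1) == [0.04]

    def test_worked_vector_flat(self):
        assert ov.bh_adjust([0.01, 0.02, 0.03, 0.04], 4) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_worked_vector_step_up(self):
        adjusted = ov.bh_adjust([0.005, 0.011, 0.02, 0.04, 0.045], 5)
        assert adjusted == pytest.approx(
            [0.025, 0.0275, 0.0333333333, 0.045, 0.045], abs=1e-9
        )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ov.ParameterError):
            ov.bh_adjust([0.1, 1.5], 2)
        with pytest.raises(ov.ParameterError):
            ov.bh_adjust([-0.1], 1)

    def test_m_below_length_rejected(self):
        with pytest.raises(ov.ParameterError):
            ov.bh_adjust([0.1, 0.2], 1)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, pvalues):
        ours = ov.bh_adjust(pvalues)
        theirs = multipletests(pvalues, method="fdr_bh")[1]
        assert ours == pytest.approx(list(theirs), abs=1e-12)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=40),
        st.floats(0.01, 0.2),
    )
    def test_rejection_set_equals_classical_step_up(self, pvalues, alpha):
        # skip adversarial boundary floats where the two formulations
        # differ only by the rounding of p*m/rank vs alpha*rank/m
        m = len(pvalues)
        if any(
            abs(p * m / rank - alpha) < 1e-9
            for p in pvalues for rank in range(1, m + 1)
        ):
            return
        adjusted = ov.bh_adjust(pvalues)
        rejected = {i for i, q in enumerate(adjusted) if q <= alpha}
        # classical step-up on the sorted p-values
        order = sorted(range(len(pvalues)), key=lambda i: pvalues[i])
        cut = 0
        for rank, idx in enumerate(order, start=1):
            if pvalues[idx] <= alpha * rank / len(pvalues):
                cut = rank
        classical = set(order[:cut])
        assert rejected == classical

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_bounds(self, pvalues):
        adjusted = ov.bh_adjust(pvalues)
        for p, q in zip(pvalues, adjusted):
            assert p <= q + 1e-15
            assert q <= 1.0


def _study_run(small_study, mode=BackgroundMode.INTERSECT):
    return ov.enrich(
        small_study["collection"], small_study["datasets"], mode
    )


class TestEnrich:
    def test_counts_queries_times_annotations(self, small_study):
        run = _study_run(small_study)
        # 3 query lists x (11 + 4) gene sets
        assert len(run.results) == 45
        assert run.m == 45

    def test_depletion_is_exact_complement(self, small_study):
        run = _study_run(small_study)
        for r in run.results:
            assert r.p_deplete == 1.0 - r.p_enrich

    def test_fdr_bounds(self, small_study):
        run = _study_run(small_study)
        for r in run.results:
            assert r.fdr >= r.p_enrich - 1e-15
            assert r.fdr <= 1.0

    def test_planted_set_ranks_first_for_its_query(self, small_study):
        run = _study_run(small_study)
        planted = [r for r in run.results if r.query_name == "planted"]
        best = min(planted, key=lambda r: r.p_enrich)
        assert (best.dataset_id, best.set_id) == (
            "tissue_a", small_study["target"].set_id
        )

    def test_query_equal_to_gene_set_attains_minimum_p(self, gene_set):
        background = gene_set(*(f"g{i}" for i in range(1, 41)))
        members = frozenset(gene_set(*(f"g{i}" for i in range(1, 6))))
        sets = [
            ov.GeneSetAnnotation("match", "match", "", members),
            ov.GeneSetAnnotation(
                "other", "other", "",
                frozenset(gene_set(*(f"g{i}" for i in range(6, 11)))),
            ),
        ]
        ds = ov.AnnotationDataset(
            dataset_id="d", gene_sets=sets,
            universe=frozenset(background),
        )
        coll = ov.QueryCollection(
            queries={"q": set(members)}, background=background
        )
        run = ov.enrich(coll, [ds], BackgroundMode.USER)
        by_set = {r.set_id: r.p_enrich for r in run.results}
        assert by_set["match"] < by_set["other"]

    def test_intersect_invariant_to_outside_background_genes(
        self, small_study, gene_set
    ):
        run = _study_run(small_study)
        padded_bg = set(small_study["collection"].background) | gene_set(
            *(f"EXTRA{i:03d}" for i in range(50))
        )
        padded = ov.QueryCollection(
            queries=dict(small_study["collection"].queries),
            background=padded_bg,
        )
        run2 = ov.enrich(
            padded, small_study["datasets"], BackgroundMode.INTERSECT
        )
        assert len(run.results) == len(run2.results)
        for a, b in zip(run.results, run2.results):
            assert (a.dataset_id, a.set_id, a.query_name) == \
                (b.dataset_id, b.set_id, b.query_name)
            assert a.p_enrich == b.p_enrich
            assert a.fdr == b.fdr

    def test_intersect_K_equals_user_background_overlap(self, small_study):
        """Gene sets live inside the universe, so intersecting the
        background cannot change K: it must equal |background ∩ set|."""
        run = _study_run(small_study)
        bg = small_study["collection"].background
        sets = {
            (ds.dataset_id, gs.set_id): gs
            for ds in small_study["datasets"] for gs in ds.gene_sets
        }
        for r in run.results:
            gs = sets[(r.dataset_id, r.set_id)]
            assert r.params.K == len(bg & gs.members)

    def test_all_degenerate_advises_user_mode(self, gene_set):
        ds = ov.AnnotationDataset(
            dataset_id="d",
            gene_sets=[ov.GeneSetAnnotation(
                "S", "S", "", frozenset(gene_set("x1", "x2")))],
        )
        coll = ov.QueryCollection(
            queries={"q": gene_set("g1")},
            background=gene_set("g1", "g2"),
        )
        with pytest.raises(ov.NoResultsError, match="USER"):
            ov.enrich(coll, [ds], BackgroundMode.INTERSECT)

    def test_null_queries_are_super_uniform(self):
        """Exact tests on discrete support are conservative: the
        fraction of null p-values at or below 0.05 stays within
        3 binomial SE of 0.05."""
        universe = ov.make_universe(2000)
        gs = ov.GeneSetAnnotation(
            "target", "target", "",
            frozenset(sorted(universe,
                             key=lambda g: g.normalized_key)[:100]),
        )
        n_sim = 300
        hits = 0
        for seed in range(n_sim):
            query = ov.make_null_query(universe, 50, seed=seed)
            _, _, p = ov.test_one(query, universe, gs)
            hits += p <= 0.05
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)
        assert hits / n_sim <= bound
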