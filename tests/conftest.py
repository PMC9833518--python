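"""Shared fixtures: tiny hand-checkable datasets and a seeded study."""

import io

import pytest
from hypothesis import HealthCheck, settings

import overrep as ov

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TWO_SET_GMT = "SetA\tdesc A\tg1\tg2\tg3\nSetB\tdesc B\tg3\tg4\n"


@pytest.fixture
def two_set_dataset() -> ov.AnnotationDataset:
    """Two overlapping sets: SetA={g1,g2,g3}, SetB={g3,g4}; universe of 4."""
    return ov.read_gmt(io.StringIO(TWO_SET_GMT), "demo")


@pytest.fixture
def genes():
    """Normalize a list of labels into identifiers."""
    return lambda *labels: [ov.normalize_gene_id(x) for x in labels]


@pytest.fixture
def gene_set():
    """Build an identifier set from labels."""
    return lambda *labels: {ov.normalize_gene_id(x) for x in labels}


@pytest.fixture(scope="session")
def small_study():
    """A seeded 2000-gene study: 2 datasets, background = universe,
    3 query lists (one with a planted signal in tissue_a_set01)."""
    universe = ov.make_universe(2000)
    ds_a = ov.make_annotation_dataset(
        universe, n_sets=11, size_range=(80, 200), seed=11,
        dataset_id="tissue_a",
    )
    ds_b = ov.make_annotation_dataset(
        universe, n_sets=4, size_range=(80, 200), seed=13,
        dataset_id="tissue_b",
    )
    target = ds_a.gene_sets[0]
    queries = {
        "planted": ov.make_enriched_query(
            universe, target, total=100, planted_fraction=0.6, seed=17
        ),
        "null_1": ov.make_null_query(universe, 100, seed=19),
        "null_2": ov.make_null_query(universe, 100, seed=23),
    }
    bg_text = "\n".join(
        sorted(g.raw_label for g in universe)
    )
    collection = ov.assemble_collection(queries, io.StringIO(bg_text))
    return {
        "universe": universe,
        "datasets": [ds_a, ds_b],
        "target": target,
        "collection": collection,
    }
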