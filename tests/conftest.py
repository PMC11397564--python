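import pytest

from npmpfj import (canonical_npm_pfj_tables, canonical_rating_tables,
                    default_archetypes, generate_foods, planted_labels,
                    score_records, worked_example_foods)


@pytest.fixture(scope="session")
def band_tables():
    return canonical_npm_pfj_tables()


@pytest.fixture(scope="session")
def rating_tables():
    return canonical_rating_tables()


@pytest.fixture(scope="session")
def worked_examples():
    return worked_example_foods()


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes(30)


@pytest.fixture(scope="session")
def synthetic_records(archetypes):
    return generate_foods(archetypes, seed=42)


@pytest.fixture(scope="session")
def synthetic_truth(archetypes):
    return planted_labels(archetypes)


@pytest.fixture(scope="session")
def synthetic_points(synthetic_records):
    return score_records(synthetic_records)


def partition_of(labels):
    """Order-independent representation of a clustering, for comparing
    partitions without caring about label names."""
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)
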