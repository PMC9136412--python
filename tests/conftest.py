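import numpy as np
import pytest

from conglutin.synth import (
    accession_panel,
    generate_candidate_db,
    generate_reference_set,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def reference_set():
    return generate_reference_set(seed=1)


@pytest.fixture(scope="session")
def refs(reference_set):
    return reference_set[0]


@pytest.fixture(scope="session")
def domain_table(reference_set):
    return reference_set[1]


@pytest.fixture(scope="session")
def candidate_db(refs):
    """The default synthetic candidate panel: 2 variants per reference at
    90% planted identity, 8 decoys, 4 duplicates."""
    return generate_candidate_db(
        refs, n_variants=32, n_decoys=8, n_duplicates=4, seed=7, identity=90.0
    )


@pytest.fixture(scope="session")
def screen_hits(refs, candidate_db):
    from conglutin.annotate import screen_candidates

    return screen_candidates(candidate_db.records, refs)


@pytest.fixture(scope="session")
def classification(refs, candidate_db):
    from conglutin.annotate import classify

    return classify(candidate_db.records, refs, 75.0, candidate_db.domains)


@pytest.fixture(scope="session")
def panel():
    return accession_panel()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))
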