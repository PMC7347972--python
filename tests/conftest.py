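import pytest

from plastocomp.synthetic import (
    build_ancestor,
    default_study_config,
    simulate_study,
)


@pytest.fixture(scope="session")
def ancestor_pair():
    """Default synthetic ancestor + construction truth (seed 1)."""
    return build_ancestor(seed=1)


@pytest.fixture(scope="session")
def study():
    """One evolved eight-taxon clade under the default study conditions."""
    ancestor, records, truth = simulate_study(seed=3)
    return ancestor, records, truth


@pytest.fixture(scope="session")
def study_records(study):
    return study[1]


@pytest.fixture(scope="session")
def study_truth(study):
    return study[2]
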