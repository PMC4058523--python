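import pytest

from pomanet import default_truth, generate_cohort, generate_reference_network

# scaled-down cohort for unit tests: same archetypes as the default study
# conditions (2 exclusivity-rich regulators, 1 share-heavy pair), fewer decoys
SMALL = dict(
    n_mirna=30,
    n_gene=80,
    n_rich=2,
    exclusive_per_rich=4,
    n_heavy_pairs=1,
    shared_per_pair=6,
)


@pytest.fixture(scope="session")
def small_truth():
    return default_truth(**SMALL)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return generate_cohort(small_truth, n_control=6, n_case=19, seed=11)


@pytest.fixture(scope="session")
def small_reference(small_truth):
    return generate_reference_network(small_truth, n_extra_edges=60, seed=12)
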