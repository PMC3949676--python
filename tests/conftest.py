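import pytest
from hypothesis import HealthCheck, settings

from metaweight.synthetic import standard_scenario

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small planted two-domain scenario shared by module tests."""
    return standard_scenario(
        seed=11, n_enzymes=24, n_compounds=200, n_clusters=(15, 18),
        genomes_per_cluster=2, seq_len_range=(40, 70))


@pytest.fixture(scope="session")
def tiny_supergraph(tiny_scenario):
    from metaweight.graph import build_supergraph

    sc = tiny_scenario
    return build_supergraph(sc.graph.reactions, sc.graph.cofactors,
                            pathway_membership=sc.graph.pathway_membership)
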