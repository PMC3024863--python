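import pytest

from causaltf import SyntheticScenario, figure2_fixture, generate_network


@pytest.fixture
def fig2():
    return figure2_fixture()


def small_scenario(seed: int, **overrides) -> SyntheticScenario:
    """A <=60-node scenario dense enough that all six models differ."""
    params = dict(
        n_tfs=12,
        n_genes=40,
        n_kinases=5,
        n_modulators=6,
        mean_out_degree=4.0,
        tf_target_fraction=0.3,
        mean_kinase_substrates=1.5,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


def small_network(seed: int, **overrides):
    return generate_network(small_scenario(seed, **overrides))
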