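import pytest

from canyuns.synthetic import generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Noise-free benchmark with unique routes (no reversibles, no decoy use)."""
    return generate_scenario(
        n_conditions=4, pathway_length=3, n_decoys=4,
        reversible_fraction=0.0, noise_fraction=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def misannotation_scenario():
    """Scenario with a high-evidence chain the organism does not use.

    The chain fixes a co-substrate present in every medium, so it gains
    certainty during training and produces false-positive growth calls that
    net-benefit pruning can correct.
    """
    return generate_scenario(
        n_conditions=4, pathway_length=3, n_decoys=4,
        reversible_fraction=0.0, noise_fraction=0.0,
        with_misannotation=True, seed=7,
    )
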