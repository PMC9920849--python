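import numpy as np
import pytest

from gourdstats import TraitSpec, TrialConfig


def make_config(
    n_landraces=6,
    n_blocks=3,
    n_within=2,
    stages=("S1", "S2"),
    mu=10.0,
    sigma2_g=4.0,
    sigma2_e=1.0,
    sigma2_b=0.0,
    stage_effects=None,
    seed=0,
    traits=None,
    **kwargs,
):
    """Small one-trait trial config for fast unit tests."""
    if traits is None:
        traits = {
            "T": TraitSpec(
                mu=mu,
                sigma2_g=sigma2_g,
                sigma2_e=sigma2_e,
                sigma2_b=sigma2_b,
                stage_effects=stage_effects,
            )
        }
    return TrialConfig(
        traits=traits,
        stages=tuple(stages),
        n_landraces=n_landraces,
        n_blocks=n_blocks,
        n_within=n_within,
        rng_seed=seed,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230124)


@pytest.fixture
def tiny_table():
    """A deterministic 2-trait, 2-stage table for aggregation tests."""
    from gourdstats import simulate_trait_table

    config = make_config(
        n_landraces=4,
        n_blocks=2,
        n_within=3,
        traits={
            "A": TraitSpec(mu=5.0, sigma2_g=1.0, sigma2_e=0.5),
            "B": TraitSpec(mu=2.0, sigma2_g=0.2, sigma2_e=0.1),
        },
        seed=7,
    )
    return simulate_trait_table(config)
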