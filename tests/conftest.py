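import logging
from collections import OrderedDict

import pytest

from fflscope.synthetic_data import SimulationConfig, simulate_study

logging.getLogger("fflscope").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """One default-condition simulated study shared across tests."""
    return simulate_study(SimulationConfig(seed=1))


def null_config(seed: int, **overrides) -> SimulationConfig:
    """A zero-effect configuration: no planted probes, DE features or loops."""
    kwargs = dict(
        seed=seed,
        n_hypo_pairs=0,
        n_hyper_pairs=0,
        n_de_genes=0,
        n_de_tfs=0,
        n_de_mirnas=0,
        n_planted_motifs=0,
        n_ffls=OrderedDict(),
        n_probes=2000,
        n_genes=400,
        n_tfs=5,
        n_mirnas=20,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
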