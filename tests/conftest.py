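import numpy as np
import pytest

from mpcin import pipeline
from mpcin.config import RunConfig
from mpcin.simulate import (
    FragmentSimParams,
    KaryotypePlan,
    apply_karyotype,
    make_toy_genome,
    simulate_mate_pairs,
)


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def genome():
    """Six 1 Mb autosomes plus huYAP/muAkt transgene contigs (no sequence)."""
    return make_toy_genome(
        n_autosomes=6,
        autosome_length=1_000_000,
        transgenes=("huYAP", "muAkt"),
        seed=11,
        with_sequence=False,
    )


@pytest.fixture(scope="session")
def diploid(genome):
    derived, truth = apply_karyotype(genome, KaryotypePlan(events=[]))
    return derived


@pytest.fixture(scope="session")
def diploid_fragments(diploid):
    return simulate_mate_pairs(diploid, FragmentSimParams(seed=21))


@pytest.fixture(scope="session")
def panel_tracks(genome, diploid, cfg):
    frames = [
        simulate_mate_pairs(diploid, FragmentSimParams(seed=900 + i)) for i in range(4)
    ]
    return pipeline.build_panel_tracks(frames, genome, cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
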