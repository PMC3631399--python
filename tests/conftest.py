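import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radphy.genome_sim import HaploidGenome
from radphy._seq import encode

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genome(sequence: str, taxon: str = "g") -> HaploidGenome:
    """Haploid genome with identity coordinates, for hand-built examples."""
    L = len(sequence)
    return HaploidGenome(
        taxon=taxon,
        seq=encode(sequence),
        anc_coord=np.arange(L, dtype=np.int64),
        lineage=np.zeros(L, dtype=np.int32),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
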