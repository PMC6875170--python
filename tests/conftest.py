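import numpy as np
import pytest

from tescope.genetics import standard_genetic_code
from tescope.simulate import (
    SYNTHETIC_OPTIMAL_CODONS,
    build_codon_model,
    simulate_genome,
)


@pytest.fixture(scope="session")
def code():
    return standard_genetic_code()


@pytest.fixture(scope="session")
def codon_model():
    return build_codon_model(SYNTHETIC_OPTIMAL_CODONS, target_fop=0.60, target_gc3s=0.70)


@pytest.fixture(scope="session")
def small_sim():
    """One default simulated genome shared across tests (seed pinned)."""
    contigs, families, truth, counts = simulate_genome(seed=11)
    return {"contigs": contigs, "families": families, "truth": truth, "counts": counts}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
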