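import numpy as np
import pytest

from nbsupport import Superalignment

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def tiny_dna():
    return Superalignment.from_sequences(
        ["A", "B", "C", "D"],
        ["ACGTACGT", "ACGAACGA", "ACGCACGC", "AC-TAC?T"],
    )


@pytest.fixture
def quartet_alignment():
    """Strong-signal 4-taxon alignment simulated on ((A,B),(C,D))."""
    from nbsupport import SimulationSpec, ils_like_dataset

    spec = SimulationSpec(
        mixture=[("((A:0.1,B:0.1):0.08,(C:0.1,D:0.1):0.08);", 1.0)],
        n_genes=5,
        gene_length=1000,
        seed=11,
    )
    aln, _ = ils_like_dataset(spec)
    return aln
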