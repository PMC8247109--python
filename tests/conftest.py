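import numpy as np
import pytest

from biganlda import (
    AssociationMatrix,
    DiseaseOntology,
    SequenceSet,
    SimulationConfig,
    simulate,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by unit tests (fast to simulate)."""
    cfg = SimulationConfig(
        nd=12, nl=24, n_blocks=3, seq_length_range=(60, 80), seed=11
    )
    return simulate(cfg)


@pytest.fixture
def tiny_assoc():
    values = np.array([[1, 0, 1, 0], [0, 1, 0, 0], [1, 1, 0, 1]], dtype=np.int8)
    return AssociationMatrix(values, ["d0", "d1", "d2"], ["l0", "l1", "l2", "l3"])


@pytest.fixture
def chain_ontology():
    return DiseaseOntology.from_edges([("p", "d")])


@pytest.fixture
def tiny_seqs():
    return SequenceSet({"l1": "ACGT", "l2": "ACGA"})
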