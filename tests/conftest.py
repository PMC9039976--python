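import numpy as np
import pytest

import toxpimap as tm


@pytest.fixture(scope="session")
def model():
    """The bundled 14-slice, 4-category example model."""
    return tm.pvi_example_model()


@pytest.fixture(scope="session")
def lattice_spec():
    return tm.LatticeSpec()  # 10x10 half-degree cells


@pytest.fixture(scope="session")
def lattice(lattice_spec):
    return tm.make_lattice(lattice_spec)


@pytest.fixture(scope="session")
def scored(model, lattice):
    """A scored 100-record table on the default lattice (no cluster)."""
    boundaries, anchors = lattice
    table = tm.simulate_components(boundaries.keys, model, seed=20,
                                   anchors=anchors)
    return tm.score_table(table, model)


@pytest.fixture()
def small_scored():
    """A tiny hand-made scored table (3 records, 2 slices)."""
    return tm.ScoredTable(
        ids=["a", "b", "c"],
        slice_names=["s1", "s2"],
        slice_scores=np.array([[0.2, 1.0], [0.4, 0.0], [0.6, 0.5]]),
        overall=np.array([1.0, 0.2, 0.9]),
        weights=np.array([1.0, 1.0]),
        lon=np.array([-100.0, -100.5, -101.0]),
        lat=np.array([35.0, 35.5, 36.0]),
    )
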