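import numpy as np
import pytest

from lvestim.mechanics import GeometryParams
from lvestim.surrogate import DisplacementSurrogate, build_training_set


@pytest.fixture(scope="session")
def geometry():
    return GeometryParams()


@pytest.fixture(scope="session")
def unit_training_set(geometry):
    """Small forward-model sample used by the unit-level surrogate."""
    return build_training_set(geometry, n_theta=120, n_interior=60,
                              n_boundary=16, seed=7)


@pytest.fixture(scope="session")
def unit_surrogate(unit_training_set):
    """A quickly trained surrogate, accurate enough for sign and recovery
    checks at loose tolerances (the reference-quality surrogate is trained in
    the acceptance suite)."""
    model = DisplacementSurrogate(random_state=7, max_epochs=1200,
                                  patience=400, lr_decay=0.998)
    ts = unit_training_set
    model.fit(ts.X, ts.U, boundary=ts.boundary)
    return model
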