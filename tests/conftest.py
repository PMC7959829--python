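import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_subject():
    """Three parcels, distinct distributions, enough vertices to bin."""
    from morphnet.morphometry_io import Parcellation, SubjectMorphometry

    gen = np.random.default_rng(7)
    values = {}
    for k, label in enumerate(("A(lh)", "B(lh)", "C(rh)")):
        n = 60 + 10 * k
        values[label] = {
            "volume": gen.lognormal(np.log(25) + 0.2 * k, 0.4, n),
            "area": gen.lognormal(np.log(9), 0.3, n),
            "thickness": np.abs(gen.normal(2.5, 0.5, n)),
        }
    return SubjectMorphometry(
        subject_id="toy",
        parcellation=Parcellation(("A(lh)", "B(lh)", "C(rh)")),
        values=values,
    )


def random_connected_adjacency(rng, n, p=0.5):
    """Rejection-sample a connected 0/1 adjacency matrix."""
    from tests.oracles import floyd_warshall

    while True:
        a = (rng.random((n, n)) < p).astype(np.int8)
        a = np.triu(a, 1)
        a = a + a.T
        if np.isfinite(floyd_warshall(a)).all():
            return a
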