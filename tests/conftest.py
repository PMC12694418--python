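import numpy as np
import pytest

from cytomorph.io import EventCloud
from cytomorph.simulate import CloudSpec, Component, generate_cloud


def make_cloud(values, sample_id="s", replicate_id="r1") -> EventCloud:
    return EventCloud(
        values=np.asarray(values, dtype=float),
        sample_id=sample_id,
        replicate_id=replicate_id,
    )


def blob_cloud(means, masses, n=10_000, var=0.01, seed=3, sample_id="s"):
    """Mixture of isotropic log-space Gaussian blobs, no acquisition cutoff."""
    comps = [
        Component(np.asarray(m, dtype=float), np.diag([var] * 3), w)
        for m, w in zip(means, masses)
    ]
    spec = CloudSpec(comps, n_events=n, seed=seed, fl1_threshold=1e-12)
    cloud, truth = generate_cloud(spec, sample_id=sample_id)
    return cloud, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_cloud(rng):
    """A single full-rank trivariate normal cloud."""
    cov = np.array([[0.05, 0.01, 0.0], [0.01, 0.08, 0.02], [0.0, 0.02, 0.04]])
    vals = rng.multivariate_normal([3.3, 3.7, 3.2], cov, size=5000)
    return make_cloud(vals)
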