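import numpy as np
import pytest

from ffgf.data import LabeledDataset
from ffgf.synthetic import ClusterSpec, PhantomSpec, gen_benchmark_suite, gen_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_random_image(rng):
    return rng.integers(0, 256, size=(8, 8)).astype(np.uint8)


@pytest.fixture
def phantom_pair():
    """One smooth and one textured phantom with the same seed."""
    smooth, _ = gen_phantom(PhantomSpec(texture_density=0.0, speckle_level=0.0, seed=0))
    textured, _ = gen_phantom(
        PhantomSpec(texture_density=25.0, speckle_level=0.0, seed=0)
    )
    return smooth, textured


@pytest.fixture(scope="session")
def separated_clusters():
    """Two 3-D Gaussian classes with 6-sigma mean separation, 100 per class."""
    spec = ClusterSpec(
        mu_pos=np.array([3.0, 0.0, 0.0]),
        mu_neg=np.array([-3.0, 0.0, 0.0]),
        cov=np.eye(3),
        n_per_class=100,
        seed=42,
    )
    from ffgf.synthetic import gen_feature_clusters

    return gen_feature_clusters(spec)


@pytest.fixture(scope="session")
def tiny_benchmark(tmp_path_factory):
    """Small phantom benchmark on disk (6 images per class)."""
    out = tmp_path_factory.mktemp("bench")
    manifest = gen_benchmark_suite(out, n_per_class=6, seed=7)
    return out, manifest


def random_labeled(rng, n=20, d=3):
    X = rng.normal(size=(n, d))
    t = np.where(rng.uniform(size=n) < 0.5, 1, -1)
    t[0], t[1] = 1, -1  # guarantee both classes
    return LabeledDataset(X, t)
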