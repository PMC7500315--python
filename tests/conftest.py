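import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_dataset():
    """Small in-memory synthetic dataset (default 4-class config)."""
    from bilinearcnn.synthetic import SyntheticConfig, generate_arrays

    return generate_arrays(SyntheticConfig(seed=0, images_per_class=12))


@pytest.fixture(scope="session")
def trained_fast(synth_dataset):
    """A fast bilinear classifier trained at the desk-scale profile."""
    from bilinearcnn.estimators import FastBCNNClassifier
    from bilinearcnn.experiments import DESK_SCALE

    X, y = synth_dataset["images"], synth_dataset["labels"]
    clf = FastBCNNClassifier(random_state=0, **DESK_SCALE)
    clf.fit(X, y)
    return clf


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """Synthetic dataset written to disk in the scannable layout."""
    from bilinearcnn.synthetic import SyntheticConfig, generate_synthetic_dataset

    out = tmp_path_factory.mktemp("synthdata")
    cfg = SyntheticConfig(seed=1, n_classes=2, images_per_class=10,
                          image_size=32, scales=(1.0,))
    manifest = generate_synthetic_dataset(cfg, out)
    return out, manifest
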