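import numpy as np
import pytest

from wildface.nn.vit import BackboneConfig
from wildface.recognizer import RecognizerConfig, build_recognizer
from wildface.reid import make_benchmark
from wildface.synthetic import generate_dataset, make_identity_bank


@pytest.fixture(scope="session")
def benchmark_fit():
    """The 12-identity synthetic benchmark, trained once per session."""
    model, ds = make_benchmark(seed=1)
    results = model.fit()
    return model, ds, results


@pytest.fixture(scope="session")
def small_bank():
    return make_identity_bank(4, seed=7)


@pytest.fixture(scope="session")
def small_ds(small_bank):
    return generate_dataset(small_bank, [10] * 4, seed=3, size=64)


@pytest.fixture()
def tiny_recognizer():
    """Untrained desk-scale recognizer (32 px, 17 tokens, 4 layers)."""
    cfg = BackboneConfig(image_size=32, patch_size=8, dim=64, depth=4, n_heads=4, mlp_ratio=2.0)
    return build_recognizer(cfg, RecognizerConfig(n_classes=5), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
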