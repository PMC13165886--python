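import numpy as np
import pytest

from structseg.mini_segmenter import MiniSegmenter, ModelConfig, SegmenterNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SMALL_MODEL = dict(image_size=48, patch_size=8, channels=32, heads=4,
                   encoder_layers=3, token_count=9, rank=4, bottleneck=8,
                   fve_depth=4, warmup_steps=5)


@pytest.fixture
def small_config():
    return ModelConfig(image_size=48, patch_size=8, channels=32, heads=4,
                       encoder_layers=3, token_count=9, rank=4, bottleneck=8,
                       fve_depth=4)


@pytest.fixture
def small_net(small_config):
    return SegmenterNetwork(small_config)


def small_estimator(**overrides):
    params = dict(SMALL_MODEL)
    params.update(overrides)
    return MiniSegmenter(**params)


@pytest.fixture(scope="session")
def tiny_fundus_suite():
    """2-domain, 8-image, 48 px fundus suite for end-to-end tests."""
    from structseg.synthetic_domains import make_domain_suite
    return make_domain_suite("fundus", n_domains=2, n_per_domain=8,
                             size=48, seed=3)
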