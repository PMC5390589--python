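import numpy as np
import pytest

from chdnet import CHDNet, HyperParams, SynthConfig, generate_dataset, sample_training_subset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_hp():
    """Small cascade for fast unit tests: 2+2 filters of 3x3, depth-1 pyramid."""
    return HyperParams(V1=2, V2=2, s1=3, s2=3, L=1)


@pytest.fixture(scope="session")
def tiny_images():
    imgs, labels = generate_dataset(
        SynthConfig(n_normal=4, n_abnormal=6, height=16, width=16, seed=42)
    )
    return imgs, labels


@pytest.fixture(scope="session")
def tiny_net(tiny_hp, tiny_images):
    imgs, _ = tiny_images
    return CHDNet(tiny_hp).fit(imgs)


@pytest.fixture(scope="session")
def synth_benchmark():
    """The default imbalanced benchmark: 48 normal + 267 abnormal 32x32
    images at default contrast, features extracted with default settings
    from banks learned on the seeded 40+44 subset."""
    imgs, labels = generate_dataset(SynthConfig(seed=7))
    subset = sample_training_subset(labels, seed=7)
    net = CHDNet().fit([imgs[i] for i in subset])
    features = net.transform(imgs)
    return features, labels, net
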