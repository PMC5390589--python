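"""High-level fit/transform surface over the cascade.

`CHDNet` bundles the two learned filter banks and the pooling
hyperparameters: `fit` learns the stage-1 eigenfilters from all training
images and the stage-2 eigenfilters from the pooled stage-1 output maps;
`transform` runs the full forward + pooling pipeline and returns one
feature row per image (43008 columns at the defaults).
"""

from __future__ import annotations

import numpy as np

from .cascade import HyperParams, convolve_tanh, nonlinear_transform
from .pca_filters import FilterBank, learn_filters
from .pooling import extract_features, feature_length
from .preprocess import Image, extract_patches, remove_patch_means


def sample_training_subset(
    labels: np.ndarray, n_normal: int = 40, n_abnormal: int = 44, seed: int = 0
) -> np.ndarray:
    """Indices of the seeded filter-learning subset (default 40 normal +
    44 abnormal, ~26.67% of the default 315-image set)."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    out = []
    for cls, want in ((0, n_normal), (1, n_abnormal)):
        pool = np.flatnonzero(labels == cls)
        if len(pool) < want:
            raise ValueError(f"class {cls} has {len(pool)} samples, need {want}")
        out.append(rng.choice(pool, size=want, replace=False))
    return np.sort(np.concatenate(out))


class CHDNet:
    """Two-stage PCA-filter convolutional feature extractor.

    Parameters are carried by a :class:`HyperParams`; after `fit`, the
    learned banks are available as `bank1` / `bank2`.
    """

    def __init__(self, hp: HyperParams | None = None):
        self.hp = hp or HyperParams()
        self.bank1: FilterBank | None = None
        self.bank2: FilterBank | None = None

    def fit(self, imgs: list[Image]) -> "CHDNet":
        """Learn both filter banks from a training image collection.

        Stage 1 pools mean-removed patches over all images; stage 2 pools
        patches of every stage-1 output map (V1 maps per image).
        """
        hp = self.hp
        stage1_patches = [
            remove_patch_means(extract_patches(img, hp.s1, hp.s2)) for img in imgs
        ]
        self.bank1 = learn_filters(stage1_patches, hp.V1, stage=1)

        stage2_patches = []
        for img in imgs:
            for k in range(hp.V1):
                c1 = convolve_tanh(img, self.bank1.filters[k])
                t1 = nonlinear_transform(c1, hp.eps, hp.a) if hp.use_nt else c1
                stage2_patches.append(
                    remove_patch_means(extract_patches(Image(t1), hp.s1, hp.s2))
                )
        self.bank2 = learn_filters(stage2_patches, hp.V2, stage=2)
        return self

    def transform(self, imgs: list[Image]) -> np.ndarray:
        """Feature matrix of shape (n_images, V2 * G * 256)."""
        if self.bank1 is None or self.bank2 is None:
            raise RuntimeError("CHDNet is not fitted; call fit() first")
        return extract_features(imgs, self.bank1, self.bank2, self.hp)

    def fit_transform(self, imgs: list[Image]) -> np.ndarray:
        return self.fit(imgs).transform(imgs)

    @property
    def n_features(self) -> int:
        return feature_length(self.hp)
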