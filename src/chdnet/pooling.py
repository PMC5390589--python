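"""Feature pooling: Heaviside hashing into word images, min-max rescale,
spatial-pyramid word histograms, high dispersal and local response
normalization, ending in one flat feature vector per image.

The V1 binary maps that share a stage-2 filter j are combined into a
single integer "word" image via powers-of-two weights, so each pixel is a
word in [0, 2^V1 - 1] ([0, 255] at V1 = 8).  A spatial pyramid of depth L
partitions the word image into 2^l x 2^l cell grids (G = sum_l 4^l cells,
21 at L = 2) with a 256-bin word histogram per cell; high dispersal then
rescales each G x 256 feature to Euclidean norm sigma, and local response
normalization divides each entry by a power of the windowed sum of squares
across neighboring stage-2 maps.  At the defaults (V2 = 8, L = 2) the
concatenated vector has 8 * 21 * 256 = 43008 entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import HyperParams, StageOutput, forward_one
from .pca_filters import FilterBank
from .preprocess import Image

WORD_BINS = 256

_HEAVISIDE_SOURCES = ("pre_nt", "nt_centered")


@dataclass
class HashedMap:
    """m x n grid of integer words owned by stage-2 filter index j."""

    pixels: np.ndarray  # integer dtype
    filter_index: int


@dataclass
class PyramidFeature:
    """G x 256 per-cell word histograms of one hashed map.

    state is "raw" (non-negative counts), "dispersed" (Frobenius norm
    sigma) or "normalized" (after LRN).
    """

    values: np.ndarray  # (G, 256)
    filter_index: int
    state: str = "raw"


def binarize(map_: np.ndarray, source: str = "pre_nt") -> np.ndarray:
    """Heaviside step: 1 where the source value is strictly positive.

    source "pre_nt" thresholds the tanh convolution map C2 at zero (the
    post-NT map is strictly positive, which would hash every pixel to the
    maximal word); "nt_centered" thresholds T2 minus its own map mean.
    """
    if source not in _HEAVISIDE_SOURCES:
        raise ValueError(f"unknown Heaviside source {source!r}; expected one of {_HEAVISIDE_SOURCES}")
    arr = np.asarray(map_, dtype=np.float64)
    if source == "nt_centered":
        arr = arr - arr.mean()
    return (arr > 0).astype(np.int64)


def hash_group(binary_maps: np.ndarray | list[np.ndarray], filter_index: int = 0) -> HashedMap:
    """Combine V1 binary maps into one word image: H = sum_k 2^((k-1) mod 256) B_k."""
    stack = np.asarray(binary_maps)
    if stack.ndim != 3:
        raise ValueError("expected a stack of V1 binary maps")
    shapes = {tuple(m.shape) for m in stack}
    if len(shapes) != 1:
        raise ValueError(f"binary maps have mismatched shapes: {shapes}")
    v1 = stack.shape[0]
    weights = np.power(2, np.arange(v1) % 256, dtype=np.int64)
    words = np.tensordot(weights, stack.astype(np.int64), axes=(0, 0))
    return HashedMap(words, filter_index=filter_index)


def rescale_hash(hm: HashedMap) -> HashedMap:
    """Per-map min-max rescale to [0, 255] with half-away-from-zero rounding.

    A constant map (max == min) maps to all zeros.
    """
    px = hm.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return HashedMap(np.zeros_like(hm.pixels, dtype=np.int64), hm.filter_index)
    scaled = (px - lo) / (hi - lo) * 255.0
    rounded = np.floor(scaled + 0.5).astype(np.int64)  # values are >= 0
    return HashedMap(rounded, hm.filter_index)


def pyramid_histogram(hm: HashedMap, L: int) -> PyramidFeature:
    """Spatial pyramid of 256-bin word histograms, depth L.

    Level l partitions the map into a 2^l x 2^l cell grid with boundaries
    at floor(m * r / 2^l); cells are ordered level-ascending then
    row-major, giving G = sum_{l=0}^{L} 4^l rows.
    """
    if L < 0:
        raise ValueError(f"L must be >= 0, got {L}")
    words = np.asarray(hm.pixels)
    m, n = words.shape
    if 2**L > min(m, n):
        raise ValueError(f"2^L = {2**L} exceeds map dimension {min(m, n)}")
    if words.min() < 0 or words.max() >= WORD_BINS:
        raise ValueError("word values outside [0, 255]")
    rows = []
    for level in range(L + 1):
        g = 2**level
        rb = [m * r // g for r in range(g + 1)]
        cb = [n * c // g for c in range(g + 1)]
        for r in range(g):
            for c in range(g):
                cell = words[rb[r]:rb[r + 1], cb[c]:cb[c + 1]]
                rows.append(np.bincount(cell.ravel(), minlength=WORD_BINS))
    return PyramidFeature(np.asarray(rows, dtype=np.float64), hm.filter_index, state="raw")


def high_dispersal(pf: PyramidFeature, sigma: float, sqrt_norm: bool = True) -> PyramidFeature:
    """Rescale the feature to fixed energy: f~ = sigma * f / ||f||_2.

    The norm runs over all G x 256 entries; an all-zero feature is
    returned unchanged.  sqrt_norm=False divides by the plain sum of
    squares instead of its square root (no fixed-norm property then).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    ss = float(np.sum(pf.values**2))
    if ss == 0.0:
        return PyramidFeature(pf.values.copy(), pf.filter_index, state="dispersed")
    denom = np.sqrt(ss) if sqrt_norm else ss
    return PyramidFeature(sigma * pf.values / denom, pf.filter_index, state="dispersed")


def local_response_normalize(
    pfs: list[PyramidFeature],
    gamma: float,
    alpha: float,
    beta: float,
    n_lrn: int,
) -> list[PyramidFeature]:
    """Normalize each entry by the windowed sum of squares across maps.

    For map j (1-based) the window covers j' in [max(1, j - n//2),
    min(V2, j + n//2)] in stage-2 filter order:
    f_bar_j = f~_j / (gamma + alpha * sum_{j'} f~_{j'}^2)^beta.
    """
    shapes = {pf.values.shape for pf in pfs}
    if len(shapes) != 1:
        raise ValueError(f"pyramid features have mismatched shapes: {shapes}")
    v2 = len(pfs)
    half = n_lrn // 2
    stack = np.stack([pf.values for pf in pfs])
    sq = stack**2
    out = []
    for j in range(1, v2 + 1):
        lo, hi = max(1, j - half), min(v2, j + half)
        denom = (gamma + alpha * sq[lo - 1:hi].sum(axis=0)) ** beta
        out.append(
            PyramidFeature(stack[j - 1] / denom, pfs[j - 1].filter_index, state="normalized")
        )
    return out


def vectorize(pfs: list[PyramidFeature]) -> np.ndarray:
    """Concatenate the V2 features: (level asc, cell row-major, bin asc) per map."""
    shapes = {pf.values.shape for pf in pfs}
    if len(shapes) > 1:
        raise ValueError(f"pyramid features have mismatched shapes: {shapes}")
    return np.concatenate([pf.values.ravel() for pf in pfs])


def pool_stage2(out2: StageOutput, hp: HyperParams) -> np.ndarray:
    """Pool one image's stage-2 maps into its feature vector."""
    source_maps = out2.C if hp.heaviside_source == "pre_nt" else out2.T
    L = hp.L if hp.use_mfa else 0
    feats = []
    for j in range(hp.V2):
        binmaps = np.stack(
            [binarize(source_maps[k, j], hp.heaviside_source) for k in range(hp.V1)]
        )
        hm = rescale_hash(hash_group(binmaps, filter_index=j))
        pf = pyramid_histogram(hm, L)
        if hp.use_hd:
            pf = high_dispersal(pf, hp.sigma, sqrt_norm=hp.hd_sqrt)
        feats.append(pf)
    if hp.use_lrn:
        feats = local_response_normalize(feats, hp.gamma, hp.alpha, hp.beta, hp.n_lrn)
    return vectorize(feats)


def extract_features(
    imgs: list[Image],
    bank1: FilterBank,
    bank2: FilterBank,
    hp: HyperParams,
) -> np.ndarray:
    """End-to-end features for an image collection: (n_images, V2 * G * 256).

    Composition of the cascade forward pass with binarize -> hash_group ->
    rescale_hash -> pyramid_histogram -> high_dispersal -> LRN ->
    vectorize; the ablation flags on hp skip individual components.
    """
    rows = [pool_stage2(forward_one(img, bank1, bank2, hp), hp) for img in imgs]
    return np.asarray(rows)


def feature_length(hp: HyperParams) -> int:
    """Length contract: V2 * (sum_{l<=L} 4^l) * 256."""
    L = hp.L if hp.use_mfa else 0
    g = sum(4**level for level in range(L + 1))
    return hp.V2 * g * WORD_BINS
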