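"""Two-stage forward pass: zero-padded tanh convolution plus the
nonlinear transformation layer.

Each output pixel is the tanh of the inner product between an eigenfilter
and the mean-removed patch centered at that pixel (correlation convention,
boundary zero-padded), so responses are invariant to constant intensity
offsets and live in (-1, 1).  The nonlinear transformation then maps each
response to a strictly positive value, either a smoothed absolute value
sqrt(eps + C^2) (a = 1) or the softplus log(1 + e^C) (a = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .pca_filters import FilterBank
from .preprocess import Image


@dataclass
class HyperParams:
    """Network hyperparameters and ablation switches.

    eps, a control the nonlinear transformation; gamma, alpha, beta, n_lrn
    the local response normalization; sigma the high-dispersal norm; L the
    pyramid depth.  Defaults are the operating point used throughout:
    eps=1e-8, a=1, gamma=2, alpha=1e-4, beta=0.75, sigma=2.238, n_lrn=5,
    V1=V2=8 filters of size 5x5, L=2.
    """

    eps: float = 1e-8
    a: int = 1
    gamma: float = 2.0
    alpha: float = 1e-4
    beta: float = 0.75
    sigma: float = 2.238
    n_lrn: int = 5
    V1: int = 8
    V2: int = 8
    s1: int = 5
    s2: int = 5
    L: int = 2
    use_nt: bool = True
    use_mfa: bool = True
    use_hd: bool = True
    use_lrn: bool = True
    heaviside_source: str = "pre_nt"
    hd_sqrt: bool = True

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.a not in (0, 1):
            raise ValueError(f"a must be 0 or 1, got {self.a}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.n_lrn < 1:
            raise ValueError(f"n_lrn must be >= 1, got {self.n_lrn}")
        if self.L < 0:
            raise ValueError(f"L must be >= 0, got {self.L}")

    def with_ablation(self, use_nt=None, use_mfa=None, use_hd=None, use_lrn=None):
        kw = {k: v for k, v in dict(
            use_nt=use_nt, use_mfa=use_mfa, use_hd=use_hd, use_lrn=use_lrn
        ).items() if v is not None}
        return replace(self, **kw)


@dataclass
class StageOutput:
    """Per-image maps of one cascade stage, indexed by filter branch.

    Stage 1: C and T have shape (V1, m, n).  Stage 2: shape (V1, V2, m, n)
    where axis 0 is the stage-1 branch k and axis 1 the stage-2 filter j.
    C holds the tanh convolution output; T the post-NT maps (T = C when
    the nonlinear transformation is ablated).
    """

    C: np.ndarray
    T: np.ndarray
    stage: int
    stage1: "StageOutput | None" = field(default=None, repr=False)


def convolve_tanh(img: Image | np.ndarray, filt: np.ndarray) -> np.ndarray:
    """tanh of the filter response on mean-removed, zero-padded patches.

    Output has the input's shape.  The patch mean removal at convolution
    time mirrors the statistics the filters were learned from: the response
    is <filter, patch> - mean(patch) * sum(filter), evaluated over patches
    of the zero-padded image (padding width floor(s/2) per side).
    """
    pixels = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    filt = np.asarray(filt, dtype=np.float64)
    s1, s2 = filt.shape
    if s1 % 2 == 0 or s2 % 2 == 0:
        raise ValueError(f"filter dims must be odd (center undefined), got {s1}x{s2}")
    raw = ndimage.correlate(pixels, filt, mode="constant", cval=0.0)
    patch_mean = ndimage.uniform_filter(pixels, size=(s1, s2), mode="constant", cval=0.0)
    return np.tanh(raw - patch_mean * filt.sum())


def nonlinear_transform(map_: np.ndarray, eps: float, a: int) -> np.ndarray:
    """Elementwise positivity-enforcing transform.

    a = 1: smoothed absolute value sqrt(eps + C^2); a = 0: softplus
    log(1 + e^C), computed stably for large |C|.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    if a not in (0, 1):
        raise ValueError(f"a must be 0 or 1, got {a}")
    c = np.asarray(map_, dtype=np.float64)
    if a == 1:
        return np.sqrt(eps + c * c)
    return np.logaddexp(0.0, c)


def forward_one(img: Image, bank1: FilterBank, bank2: FilterBank, hp: HyperParams) -> StageOutput:
    """Run the two-stage cascade on a single working-size image.

    Stage 1 produces V1 maps; each is pushed through all V2 stage-2
    filters, giving V1*V2 stage-2 maps C2[k, j] and T2[k, j].
    """
    if bank1.filter_shape != (hp.s1, hp.s2) or bank2.filter_shape != (hp.s1, hp.s2):
        raise ValueError(
            f"filter banks {bank1.filter_shape}/{bank2.filter_shape} do not match "
            f"configured size {(hp.s1, hp.s2)}"
        )
    if bank1.n_filters != hp.V1 or bank2.n_filters != hp.V2:
        raise ValueError("filter bank counts do not match V1/V2")
    m, n = img.shape
    if m < hp.s1 or n < hp.s2:
        raise ValueError(f"image {m}x{n} smaller than filter {hp.s1}x{hp.s2}")

    C1 = np.stack([convolve_tanh(img, bank1.filters[k]) for k in range(hp.V1)])
    T1 = (
        np.stack([nonlinear_transform(c, hp.eps, hp.a) for c in C1])
        if hp.use_nt
        else C1.copy()
    )
    s1_out = StageOutput(C1, T1, stage=1)

    C2 = np.empty((hp.V1, hp.V2, m, n))
    for k in range(hp.V1):
        for j in range(hp.V2):
            C2[k, j] = convolve_tanh(T1[k], bank2.filters[j])
    T2 = nonlinear_transform(C2, hp.eps, hp.a) if hp.use_nt else C2.copy()
    return StageOutput(C2, T2, stage=2, stage1=s1_out)


def forward(imgs: list[Image], bank1: FilterBank, bank2: FilterBank, hp: HyperParams) -> list[StageOutput]:
    """Vector of :func:`forward_one` over an image collection."""
    return [forward_one(img, bank1, bank2, hp) for img in imgs]
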