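"""PCA eigenfilter learning from pooled, mean-removed patches.

A stage's filter bank is the set of top eigenvectors of the patch scatter
matrix T T^T pooled over all stage-input maps, each eigenvector reshaped
back to the s1 x s2 patch geometry.  Eigenvectors are scale-invariant, so
the conventional 1/(N*p*V) prefactor on the scatter matrix changes the
eigenvalues reported here but never the filters themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preprocess import PatchMatrix

_TIE_RTOL = 1e-12


@dataclass
class FilterBank:
    """Ordered s1 x s2 eigenfilters for one cascade stage.

    Filters are pairwise orthonormal as vectors and ordered by descending
    eigenvalue of the scatter matrix; ties are broken deterministically.
    """

    filters: np.ndarray  # (V, s1, s2)
    eigenvalues: np.ndarray  # (V,), non-increasing
    stage: int

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def filter_shape(self) -> tuple[int, int]:
        return self.filters.shape[1], self.filters.shape[2]

    def to_csv(self, path: str | Path) -> None:
        """One filter per row, row-major entries, with geometry header."""
        v, s1, s2 = self.filters.shape
        with open(path, "w") as fh:
            fh.write(f"# stage={self.stage} s1={s1} s2={s2} V={v}\n")
            fh.write("eigenvalue," + ",".join(f"w{i}" for i in range(s1 * s2)) + "\n")
            for k in range(v):
                row = ",".join(repr(float(x)) for x in self.filters[k].ravel())
                fh.write(f"{float(self.eigenvalues[k])!r},{row}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FilterBank":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split())
            fh.readline()  # column names
            rows = [line.strip().split(",") for line in fh if line.strip()]
        s1, s2 = int(meta["s1"]), int(meta["s2"])
        eig = np.array([float(r[0]) for r in rows])
        filt = np.array([[float(x) for x in r[1:]] for r in rows]).reshape(-1, s1, s2)
        return cls(filt, eig, stage=int(meta["stage"]))


def fix_sign(kernel: np.ndarray) -> np.ndarray:
    """Resolve the eigenvector sign ambiguity deterministically.

    The entry of largest absolute value is made positive; among tied
    magnitudes the earliest row-major index decides.
    """
    flat = np.asarray(kernel, dtype=np.float64).ravel()
    if not np.any(flat):
        raise ValueError("cannot fix sign of an all-zero kernel")
    idx = int(np.argmax(np.abs(flat)))  # argmax returns the first maximal index
    if flat[idx] < 0:
        return -np.asarray(kernel, dtype=np.float64)
    return np.asarray(kernel, dtype=np.float64)


def learn_filters(
    patch_sets: Iterable[PatchMatrix] | Sequence[PatchMatrix],
    V: int,
    stage: int = 1,
) -> FilterBank:
    """Learn the top-V eigenfilters of a stage from pooled patch matrices.

    The scatter matrix sum_i T_i T_i^T (scaled by 1/(N*p*V), which leaves
    the eigenvectors untouched) is eigendecomposed; the leading V
    eigenvectors are sign-fixed and reshaped row-major to s1 x s2.
    """
    patch_sets = list(patch_sets)
    if not patch_sets:
        raise ValueError("at least one patch matrix is required")
    s1, s2 = patch_sets[0].s1, patch_sets[0].s2
    d = s1 * s2
    if V > d:
        raise ValueError(f"V={V} exceeds patch dimension {d}")
    if V < 1:
        raise ValueError("V must be >= 1")

    scatter = np.zeros((d, d))
    total_cols = 0
    for pm in patch_sets:
        if (pm.s1, pm.s2) != (s1, s2):
            raise ValueError("inconsistent patch geometry across inputs")
        cols = pm.columns
        if not pm.mean_removed:
            cols = cols - cols.mean(axis=0, keepdims=True)
        scatter += cols @ cols.T
        total_cols += cols.shape[1]
    if total_cols == 0:
        raise ValueError("no patch columns present")
    # N * p * V prefactor (irrelevant to the eigenvectors, kept for the
    # eigenvalue scale); total_cols = N * p
    scatter /= total_cols * V

    if not np.any(scatter):
        raise ValueError(
            "degenerate filters: patch scatter matrix is zero "
            "(all inputs constant after mean removal)"
        )

    eigval, eigvec = np.linalg.eigh(scatter)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    vecs = [fix_sign(eigvec[:, k]) for k in range(d)]
    # deterministic tie-break: equal eigenvalues ordered by the sign-fixed
    # lexicographic order of their vectors
    i = 0
    while i < d:
        j = i + 1
        while j < d and np.isclose(eigval[j], eigval[i], rtol=_TIE_RTOL, atol=0.0):
            j += 1
        if j - i > 1:
            tied = sorted(range(i, j), key=lambda k: tuple(vecs[k]))
            vecs[i:j] = [vecs[k] for k in tied]
        i = j

    filters = np.stack([v.reshape(s1, s2) for v in vecs[:V]])
    return FilterBank(filters, eigval[:V].copy(), stage=stage)
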