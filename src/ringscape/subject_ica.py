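"""Per-subject spatial ICA: decompose a 4D series into K spatial maps.

Spatial ICA treats voxels as samples and timepoints as features, so the
recovered sources are spatial maps that are statistically independent over
space; temporal order is irrelevant.  The implementation whitens to K
dimensions by truncated SVD and runs the fixed-point negentropy (logcosh
contrast) iteration with a seeded initial rotation — the standard FastICA
contract.  Each map is z-scored over the brain mask and its sign is fixed
so that skewness is non-negative ("activation" is positive), which makes
one-sided thresholding downstream reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA

from .errors import ConfigurationError, DecompositionError, ValidationError
from .io_formats import BinaryMask

__all__ = ["ComponentMap", "decompose_subject"]


@dataclass(frozen=True)
class ComponentMap:
    """One spatial component of one subject, in z-score units over the mask."""

    subject_id: str
    index: int
    zmap: np.ndarray
    mask: BinaryMask

    def __post_init__(self) -> None:
        zmap = np.asarray(self.zmap, dtype=float)
        if zmap.shape != self.mask.grid.shape:
            raise ValidationError("zmap shape does not match grid")
        if not np.all(np.isfinite(zmap)):
            raise ValidationError("zmap contains non-finite values")
        zmap.setflags(write=False)
        object.__setattr__(self, "zmap", zmap)

    @property
    def in_brain(self) -> np.ndarray:
        return self.zmap[self.mask.values]


def decompose_subject(
    series: np.ndarray,
    brain_mask: BinaryMask,
    K: int,
    seed: int,
    subject_id: str = "sub",
    max_iter: int = 500,
    tol: float = 1e-5,
) -> list[ComponentMap]:
    """Spatial ICA of a (x, y, z, t) series into exactly K component maps."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValidationError("series must be 4D (x, y, z, t)")
    if series.shape[:3] != brain_mask.grid.shape:
        raise ValidationError("series and brain mask shapes differ")
    if not np.all(np.isfinite(series)):
        raise ValidationError("series contains non-finite values")
    n_t = series.shape[3]
    n_vox = brain_mask.size
    if K > min(n_t, n_vox):
        raise ConfigurationError(
            f"K={K} exceeds min(n_timepoints={n_t}, n_voxels={n_vox})"
        )
    if K < 1:
        raise ConfigurationError("K must be >= 1")

    X = series[brain_mask.values, :]  # (voxels, time)
    X = X - X.mean(axis=0, keepdims=True)  # center each time volume over space
    if np.allclose(X, 0):
        raise DecompositionError("degenerate (spatially constant) series")
    # guard: whitening to K dims needs K non-trivial singular values
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[min(K, len(sv)) - 1] <= sv[0] * 1e-10:
        raise DecompositionError(
            f"series rank below K={K}; cannot whiten to K dimensions"
        )

    ica = FastICA(
        n_components=K,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence warnings are tolerable
        sources = ica.fit_transform(X)  # (voxels, K)

    maps: list[ComponentMap] = []
    for k in range(K):
        s = sources[:, k]
        sd = s.std()
        if sd == 0:
            raise DecompositionError(f"component {k + 1} collapsed to a constant")
        z = (s - s.mean()) / sd
        skew = np.mean(z**3)
        if skew < 0:
            z = -z
        full = np.zeros(brain_mask.grid.shape)
        full[brain_mask.values] = z
        maps.append(ComponentMap(subject_id, k + 1, full, brain_mask))
    return maps
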