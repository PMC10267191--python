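"""Raw-signal feature engineering for the adaptive models.

Each voxel's two echo profiles are reduced to a 190-element feature vector:

* the last ``n_tail = 10`` first-echo frames (391..400 of 400, 1-based) are
  averaged into a single normalization factor ``N_fac`` shared by both
  echoes — dividing both by the same factor preserves their ratio, hence the
  T2*-bearing information;
* the first ``l1 = 20`` frames are dropped (pre-steady-state) and the rest
  down-sampled by 4 (~6 s), giving the frame ladder 21, 25, …, 397;
* features 1..95 are the normalized first echo on that ladder, features
  96..190 the normalized second echo on the same ladder.

The grid (l1, step, tail length, frame count) is parameterized so
scaled-down synthetic studies remain testable; the defaults lock to the
400-frame protocol. All frame indices in this module's parameters are
1-based, matching the acquisition convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "FeatureGrid",
    "FeatureVector",
    "normalization_factor",
    "extract_features",
    "feature_frame_ladder",
    "featurize_study",
]


@dataclass(frozen=True)
class FeatureGrid:
    """Down-sampling grid of the feature extractor (1-based frame indices)."""

    n_frames: int = 400
    l1: int = 20       # leading frames eliminated
    step: int = 4      # down-sampling factor
    n_tail: int = 10   # frames averaged into the normalization factor

    def __post_init__(self) -> None:
        if self.l1 < 0 or self.step < 1 or self.n_tail < 1:
            raise ValueError("invalid feature grid")
        if self.l1 + 1 > self.n_frames:
            raise ValueError("feature grid drops every frame")
        if self.n_tail > self.n_frames:
            raise ValueError("tail window longer than the study")

    @property
    def per_echo(self) -> int:
        """Number of sampled frames per echo (95 on the default grid)."""
        return (self.n_frames - self.l1 - 1) // self.step + 1

    @property
    def n_features(self) -> int:
        return 2 * self.per_echo

    @property
    def tail_frames(self) -> Tuple[int, int]:
        """1-based inclusive bounds of the normalization tail (391, 400)."""
        return self.n_frames - self.n_tail + 1, self.n_frames


DEFAULT_GRID = FeatureGrid()
assert DEFAULT_GRID.n_features == 190


def feature_frame_ladder(grid: FeatureGrid = DEFAULT_GRID) -> np.ndarray:
    """1-based frame indices sampled per echo: {l1 + step·j + 1 : j = 0..}."""
    ladder = grid.l1 + grid.step * np.arange(grid.per_echo) + 1
    if ladder[-1] > grid.n_frames:
        raise ValueError("feature ladder exceeds the frame count")
    return ladder


@dataclass(frozen=True)
class FeatureVector:
    """Ordered normalized dual-echo features of one voxel."""

    values: np.ndarray
    voxel: Tuple[int, int, int]
    nfac: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "values", v)


def normalization_factor(fe: np.ndarray, grid: FeatureGrid = DEFAULT_GRID) -> float:
    """Mean first-echo signal over the tail frames (391..400 by default)."""
    fe = np.asarray(fe, float)
    if fe.shape[-1] != grid.n_frames:
        raise ValueError("series length does not match the feature grid")
    lo, hi = grid.tail_frames
    nfac = float(fe[..., lo - 1 : hi].mean(axis=-1)) if fe.ndim == 1 else fe[..., lo - 1 : hi].mean(axis=-1)
    return nfac


def extract_features(
    fe: np.ndarray,
    se: np.ndarray,
    nfac: float,
    grid: FeatureGrid = DEFAULT_GRID,
    voxel: Tuple[int, int, int] = (0, 0, 0),
) -> FeatureVector:
    """Build one voxel's feature vector; ``nfac`` must be positive.

    Both echoes are sampled on the same frame ladder and share the single
    first-echo normalization factor, preserving the echo ratio.
    """
    fe = np.asarray(fe, float)
    se = np.asarray(se, float)
    if fe.shape != se.shape or fe.ndim != 1:
        raise ValueError("fe and se must be 1-D and equally long")
    if fe.size != grid.n_frames:
        raise ValueError("series length does not match the feature grid")
    if not (np.isfinite(nfac) and nfac > 0):
        raise ValueError("normalization factor must be positive")
    idx = feature_frame_ladder(grid) - 1
    mu = np.concatenate([fe[idx], se[idx]]) / nfac
    return FeatureVector(values=mu, voxel=voxel, nfac=float(nfac))


def featurize_study(
    f: np.ndarray,
    s: np.ndarray,
    mask: np.ndarray,
    grid: FeatureGrid = DEFAULT_GRID,
):
    """Vectorized feature extraction over all masked voxels.

    Returns ``(X, coords, nfac, valid)``: the (n_voxels × n_features) matrix,
    the voxel index triples, the per-voxel normalization factors and a
    validity mask (voxels with a non-positive normalization factor or
    non-finite samples are flagged invalid and zero-filled).
    """
    f = np.asarray(f, float)
    s = np.asarray(s, float)
    mask = np.asarray(mask, bool)
    nt = f.shape[-1]
    if nt != grid.n_frames:
        raise ValueError("frame count does not match the feature grid")
    midx = np.flatnonzero(mask.reshape(-1))
    ff = f.reshape(-1, nt)[midx]
    ss = s.reshape(-1, nt)[midx]
    lo, hi = grid.tail_frames
    nfac = ff[:, lo - 1 : hi].mean(axis=1)
    idx = feature_frame_ladder(grid) - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.concatenate([ff[:, idx], ss[:, idx]], axis=1) / nfac[:, None]
    valid = (nfac > 0) & np.all(np.isfinite(x), axis=1)
    x[~valid] = 0.0
    coords = np.column_stack(np.unravel_index(midx, mask.shape))
    return x, coords, nfac, valid
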