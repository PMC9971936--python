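"""Recurrence-plot imaging of 1D ECG segments.

A scalar series X_t is delay-embedded into the 2D phase space
(X_t, X_{t-tau}) (Takens delay-coordinate reconstruction with lag tau,
default 1).  Pairwise distances between trajectory points form the
recurrence matrix, either un-thresholded R_ij = ||S_i - S_j|| (the default,
which preserves distance information and maps to an RGB image through a
colormap) or binarized through the Heaviside step R_ij = theta(eps - ||S_i -
S_j||), where theta(0) = 1 so a pair at exactly the threshold distance
counts as recurrent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import matplotlib
import numpy as np
from scipy.spatial.distance import cdist
from skimage.transform import resize_local_mean

_NORMS = {"euclidean": "euclidean", "max": "chebyshev", "manhattan": "cityblock"}


@dataclass(frozen=True)
class Trajectory:
    """Delay-embedded 2D phase-space point sequence."""

    points: np.ndarray  # (n, 2), row t = (X_t, X_{t-tau})
    tau: int = 1

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Square symmetric pairwise-distance matrix or its binarization."""

    values: np.ndarray
    mode: str  # "unthresholded" | "thresholded"
    epsilon: Optional[float] = None
    norm: str = "euclidean"

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RpImage:
    """Square RGB raster rendered from a recurrence matrix, values in [0,1]."""

    pixels: np.ndarray  # (size, size, 3)
    size: int
    colormap: str

    def to_chw(self) -> np.ndarray:
        """Channel-first copy, the layout the CNN consumes."""
        return np.ascontiguousarray(self.pixels.transpose(2, 0, 1))


@dataclass(frozen=True)
class RpConfig:
    """Parameters of the 1D-segment -> RP-image conversion.

    target_points caps the number of embedded samples: the z-scored segment
    is uniformly decimated to this count so that a tau=1 embedding yields a
    (target_points - 1)-sided matrix (300 -> 299, the native input side of
    the classifier).  full_matrix=True instead embeds every sample and
    relies on area-average resizing.
    """

    tau: int = 1
    target_points: int = 300
    size: int = 299
    colormap: str = "viridis"
    norm: str = "euclidean"
    full_matrix: bool = False
    zscore: bool = True

    def with_size(self, size: int, target_points: Optional[int] = None) -> "RpConfig":
        return replace(
            self,
            size=size,
            target_points=target_points if target_points is not None else size + self.tau,
        )


def takens_embed(samples: np.ndarray, tau: int = 1) -> Trajectory:
    """Delay-embed a scalar series into 2D points (X_t, X_{t-tau}).

    Returns N - tau points for an input of length N.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if len(x) <= tau:
        raise ValueError(f"series of length {len(x)} too short for tau={tau}")
    points = np.column_stack([x[tau:], x[:-tau]])
    return Trajectory(points=points, tau=tau)


def _check_traj(traj: Trajectory) -> np.ndarray:
    pts = np.asarray(traj.points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("trajectory must contain at least 2 points")
    return pts


def unthresholded_rp(traj: Trajectory, norm: str = "euclidean") -> RecurrenceMatrix:
    """Distance matrix R_ij = ||S_i - S_j|| (symmetric, zero diagonal)."""
    pts = _check_traj(traj)
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}; choose from {sorted(_NORMS)}")
    d = cdist(pts, pts, metric=_NORMS[norm])
    d = 0.5 * (d + d.T)  # enforce exact symmetry against fp round-off
    np.fill_diagonal(d, 0.0)
    return RecurrenceMatrix(values=d, mode="unthresholded", epsilon=None, norm=norm)


def thresholded_rp(traj: Trajectory, epsilon: float, norm: str = "euclidean") -> RecurrenceMatrix:
    """Binary recurrence matrix R_ij = theta(eps - ||S_i - S_j||).

    The Heaviside convention theta(0) = 1 makes pairs at distance exactly
    eps recurrent, and puts ones on the diagonal for every eps >= 0.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    base = unthresholded_rp(traj, norm=norm)
    b = (base.values <= epsilon).astype(np.uint8)
    return RecurrenceMatrix(values=b, mode="thresholded", epsilon=float(epsilon), norm=norm)


def render_rp_image(R: RecurrenceMatrix, size: int = 299, colormap: str = "viridis") -> RpImage:
    """Render a recurrence matrix as a size x size RGB image.

    The matrix is min-max normalized to [0,1] (a zero-range matrix maps to
    all zeros), resized by area-average (local-mean) interpolation, and
    passed through the named colormap; the alpha channel is dropped.
    Because of the min-max step the image is invariant to positive scaling
    of the matrix.
    """
    if size < 2:
        raise ValueError("image size must be >= 2")
    v = np.asarray(R.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty recurrence matrix")
    lo, hi = float(v.min()), float(v.max())
    u = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    if u.shape != (size, size):
        u = np.clip(resize_local_mean(u, (size, size)), 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    rgb = np.asarray(cmap(u), dtype=np.float32)[..., :3]
    return RpImage(pixels=rgb, size=size, colormap=colormap)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0))):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _decimate_uniform(x: np.ndarray, target: int) -> np.ndarray:
    if len(x) <= target:
        return x
    idx = np.round(np.linspace(0, len(x) - 1, target)).astype(int)
    return x[idx]


def rp_matrix_from_segment(samples: np.ndarray, cfg: RpConfig = RpConfig()) -> RecurrenceMatrix:
    """Z-score, (optionally) decimate, embed and compute the distance matrix."""
    x = np.asarray(samples, dtype=float).ravel()
    if cfg.zscore:
        x = _zscore(x)
    if not cfg.full_matrix:
        x = _decimate_uniform(x, cfg.target_points)
    traj = takens_embed(x, tau=cfg.tau)
    return unthresholded_rp(traj, norm=cfg.norm)


def ecg_to_rp(samples: np.ndarray, fs: float, cfg: RpConfig = RpConfig()) -> RpImage:
    """Full 1D-segment -> RP-image conversion (deterministic).

    Composition: z-score -> uniform decimation to cfg.target_points (unless
    full_matrix) -> Takens embedding (lag cfg.tau) -> un-thresholded
    distance matrix -> min-max normalization, resize and colormap.  ``fs``
    is accepted for interface symmetry with the rest of the pipeline; the
    conversion itself is sampling-rate agnostic.
    """
    R = rp_matrix_from_segment(samples, cfg)
    return render_rp_image(R, size=cfg.size, colormap=cfg.colormap)
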