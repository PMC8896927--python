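"""Agreement metrics between automatic and manual segmentations.

Contours are compared with the symmetric mean absolute distance (MAD) and
the symmetric Hausdorff distance (max-MAD); regions with the Dice metric.
For contours K (automatic) and L (manual), with f(k, L) = min_l ||k - l||:

    MAD(K, L)     = 1/2 [ (1/|K|) sum_k f(k, L) + (1/|L|) sum_l f(l, K) ]
    max-MAD(K, L) = max( max_k f(k, L), max_l f(l, K) )
    Dice(Z, D)    = 2 |Z ∩ D| / (|Z| + |D|)

Distances are between pixel centers, in px; multiply by the image's
``pixel_size`` for physical units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyRegionError, ShapeError

__all__ = ["Contour", "MetricReport", "extract_contour", "mad", "max_mad", "dice", "evaluate"]


@dataclass(frozen=True)
class Contour:
    """Ordered boundary pixel coordinates (row, col), pixel-center convention."""

    points: np.ndarray  # (N, 2) float
    closed: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise EmptyRegionError("a contour needs at least one (row, col) point")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class MetricReport:
    mad: float
    max_mad: float
    dice: float


def extract_contour(mask: np.ndarray) -> Contour:
    """Boundary of a binary mask: foreground pixels with a 4-adjacent
    background pixel or lying on the image border.

    Equivalent to the mask minus its 4-connected erosion.  Points are
    returned in row-major order.
    """
    mask = np.asarray(mask) != 0
    if mask.ndim != 2:
        raise ShapeError("mask must be 2-D")
    if not mask.any():
        raise EmptyRegionError("cannot extract a contour from an empty mask")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = (
        padded[1:-1, 1:-1]
        & padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    return Contour(points=np.argwhere(boundary).astype(float))


def _directed_min_distances(a: Contour, b: Contour) -> np.ndarray:
    tree = cKDTree(b.points)
    d, _ = tree.query(a.points, k=1)
    return d


def mad(K: Contour, L: Contour) -> float:
    """Symmetric mean absolute contour distance, px."""
    d_kl = _directed_min_distances(K, L)
    d_lk = _directed_min_distances(L, K)
    return 0.5 * (float(d_kl.mean()) + float(d_lk.mean()))


def max_mad(K: Contour, L: Contour) -> float:
    """Symmetric Hausdorff distance (maximum of directed max distances), px."""
    d_kl = _directed_min_distances(K, L)
    d_lk = _directed_min_distances(L, K)
    return max(float(d_kl.max()), float(d_lk.max()))


def dice(Z: np.ndarray, D: np.ndarray) -> float:
    """Dice overlap 2|Z∩D| / (|Z|+|D|) of two binary masks.

    Two empty masks agree perfectly by convention (1.0, with a warning).
    """
    Z = np.asarray(Z) != 0
    D = np.asarray(D) != 0
    if Z.shape != D.shape:
        raise ShapeError(f"mask shapes differ: {Z.shape} vs {D.shape}")
    nz, nd = int(Z.sum()), int(D.sum())
    if nz + nd == 0:
        warnings.warn("both masks empty: Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((Z & D).sum()) / (nz + nd)


def evaluate(auto_mask: np.ndarray, manual_mask: np.ndarray, pixel_size: float = 1.0) -> MetricReport:
    """All three agreement metrics between an automatic and a manual mask."""
    K = extract_contour(auto_mask)
    L = extract_contour(manual_mask)
    return MetricReport(
        mad=mad(K, L) * pixel_size,
        max_mad=max_mad(K, L) * pixel_size,
        dice=dice(manual_mask, auto_mask),
    )
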