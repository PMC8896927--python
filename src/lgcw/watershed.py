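"""Watershed refinement of the clustering mask.

The level-set stage yields one foreground region per connected bright
structure, but adjacent structures (e.g. the heart and an adherent vessel)
merge into a single component, and broken image boundaries leave contours
open.  This stage binarizes the converged state, computes the exact
Euclidean distance transform of the mask, suppresses shallow minima of the
negated distance map (h-minima), and floods the resulting relief from the
surviving minima with a marker-controlled watershed.  Pixels where two
floods meet become watershed lines, splitting adherent structures and
closing their contours.

Flooding uses a strict priority queue ordered by (relief value, insertion
order) — a FIFO tie-break — with 4-connectivity; marker components are
labeled with 8-connectivity.  Both conventions are frozen so results are
bit-reproducible.
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_minima, local_minima

from .core import (
    EnergyParams,
    Image2D,
    LevelSetState,
    initialize_level_set,
    segment_lgscm,
)
from .errors import MarkerError, ShapeError

__all__ = [
    "WatershedParams",
    "binarize",
    "euclidean_distance_transform",
    "find_markers",
    "watershed",
    "segment_lgcw",
]

_STRUCT8 = np.ones((3, 3), dtype=int)


def binarize(state: LevelSetState) -> np.ndarray:
    """Interior membership >= 0.5 as a {0,1} uint8 mask (ties go inside)."""
    return state.interior_mask().astype(np.uint8)


def euclidean_distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each 1-pixel to the nearest 0-pixel.

    Pixel-center metric; zero on 0-pixels.  A mask with no background pixel
    has no finite distances: every pixel gets the sentinel ``max(h, w)``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ShapeError("mask must be 2-D")
    binary = mask != 0
    if binary.all():
        return np.full(mask.shape, float(max(mask.shape)))
    return ndi.distance_transform_edt(binary).astype(float)


def find_markers(dist: np.ndarray, h_depth: float = 2.0) -> np.ndarray:
    """Label the h-minima of the negated distance map inside the foreground.

    Negating the distance map turns region centers into regional minima;
    suppressing minima shallower than ``h_depth`` removes spurious markers
    caused by boundary noise.  Marker components use 8-connectivity.  If the
    suppression depth exceeds the relief's dynamic range, the single deepest
    minimum is kept so flooding always has a seed.
    """
    dist = np.asarray(dist, dtype=float)
    relief = -dist
    foreground = dist > 0
    if not foreground.any():
        return np.zeros(dist.shape, dtype=np.int32)
    if h_depth > 0:
        minima = h_minima(relief, h_depth)
    else:
        minima = local_minima(relief)
    minima = minima.astype(bool) & foreground
    labels, count = ndi.label(minima, structure=_STRUCT8)
    if count == 0:
        # total suppression: seed from the deepest foreground minimum
        deepest = np.zeros_like(foreground)
        vals = np.where(foreground, relief, np.inf)
        deepest_components, _ = ndi.label(vals == vals.min(), structure=_STRUCT8)
        first = np.argwhere(vals == vals.min())[0]
        keep = deepest_components[tuple(first)]
        deepest[deepest_components == keep] = True
        labels, count = ndi.label(deepest, structure=_STRUCT8)
    return labels.astype(np.int32)


_OFFSETS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS8 = _OFFSETS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def watershed(
    relief: np.ndarray,
    markers: np.ndarray,
    connectivity: int = 4,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Marker-controlled watershed by priority flooding.

    Floods ``relief`` from the marker pixels in increasing relief order
    (strict heap ordered by (value, insertion sequence); FIFO among equal
    values).  A pixel whose already-labeled neighbors disagree becomes a
    watershed-line pixel (label 0); marker pixels always keep their label.
    ``mask`` (optional) restricts flooding to its nonzero support.
    """
    relief = np.asarray(relief, dtype=float)
    markers = np.asarray(markers)
    if relief.shape != markers.shape:
        raise ShapeError("relief and markers must have the same shape")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not (markers != 0).any():
        raise MarkerError("watershed needs at least one marker pixel")
    offsets = _OFFSETS4 if connectivity == 4 else _OFFSETS8
    h, w = relief.shape
    allowed = np.ones((h, w), dtype=bool) if mask is None else np.asarray(mask) != 0

    labels = np.where(allowed, markers.astype(np.int64), 0)
    # status: 0 = unvisited, 1 = queued, 2 = resolved
    status = np.zeros((h, w), dtype=np.uint8)
    status[labels != 0] = 2
    status[~allowed] = 2

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for r, c in np.argwhere(labels != 0):
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and status[nr, nc] == 0:
                heapq.heappush(heap, (relief[nr, nc], counter, nr, nc))
                counter += 1
                status[nr, nc] = 1

    while heap:
        _, _, r, c = heapq.heappop(heap)
        if status[r, c] == 2:
            continue
        neighbor_labels = set()
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and allowed[nr, nc]:
                lab = labels[nr, nc]
                if lab > 0 and status[nr, nc] == 2:
                    neighbor_labels.add(int(lab))
        if len(neighbor_labels) == 1:
            labels[r, c] = neighbor_labels.pop()
        else:
            labels[r, c] = 0  # watershed line (or isolated: stays background)
        status[r, c] = 2
        if labels[r, c] != 0:
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and status[nr, nc] == 0:
                    heapq.heappush(heap, (relief[nr, nc], counter, nr, nc))
                    counter += 1
                    status[nr, nc] = 1
    return labels.astype(np.int32)


@dataclass
class WatershedParams:
    h_depth: float = 2.0        # h-minima suppression depth, px
    connectivity: int = 4       # flooding connectivity


@dataclass
class PipelineReport:
    """Per-stage artifacts and timings of a full segmentation run."""

    mask: np.ndarray = None
    state: LevelSetState = None
    iteration_log: list = field(default_factory=list)
    distance: np.ndarray = None
    markers: np.ndarray = None
    timings: dict = field(default_factory=dict)


def segment_lgcw(
    image: Image2D,
    params: EnergyParams | None = None,
    watershed_params: WatershedParams | None = None,
    init: LevelSetState | None = None,
) -> tuple[np.ndarray, PipelineReport]:
    """Full pipeline: clustering level set -> binarize -> EDT -> markers -> watershed.

    Returns the final label mask (0 = background / watershed line, 1..R =
    regions) and a report with per-stage artifacts and timings.  By default
    the level set is initialized by triangle thresholding (region = above
    the dominant dark background peak), so a slice starts from its full
    non-background support regardless of how many tissue classes it shows.
    """
    if params is None:
        params = EnergyParams()
    if watershed_params is None:
        watershed_params = WatershedParams()
    report = PipelineReport()

    t0 = time.perf_counter()
    if init is None:
        init = initialize_level_set(
            image,
            mode="threshold",
            epsilon=params.epsilon,
            threshold_method="triangle",
            clean=True,
        )
    mask, state, log = segment_lgscm(image, params, init)
    report.mask = mask.astype(np.uint8)
    report.state = state
    report.iteration_log = log
    report.timings["lgscm_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    binary = binarize(state)
    dist = euclidean_distance_transform(binary)
    report.distance = dist
    report.timings["edt_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    markers = find_markers(dist, watershed_params.h_depth)
    report.markers = markers
    if not (markers != 0).any():
        # empty foreground: nothing to flood
        labels = np.zeros_like(markers)
    else:
        labels = watershed(
            -dist, markers, connectivity=watershed_params.connectivity, mask=binary
        )
    report.timings["watershed_s"] = time.perf_counter() - t0
    return labels, report
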