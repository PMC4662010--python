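"""Gray-scale ridge skeletonization of elongated DNA fragments.

A pixel belongs to a fragment centerline when it is a local intensity
maximum along the transverse (row) axis and the intensity falls off by more
than a threshold ``delta_f`` over two pixels on both sides:

    I(r, c) >= I(r-1, c)
    I(r, c) >= I(r+1, c)
    I(r, c) -  I(r-2, c) > delta_f
    I(r, c) -  I(r+2, c) > delta_f

Molecules are deposited along the flow (column) axis, so the falloff test is
applied vertically. The resulting skeletal pixels are assembled into
column-ordered connected components; each component is reduced to a
one-pixel-wide path between its end points by a shortest-path search.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Frame, SkeletalSegment

__all__ = [
    "SkeletonizationParams",
    "estimate_noise_sigma",
    "resolve_delta_f",
    "detect_skeletal_pixels",
    "label_components",
    "locate_endpoints",
    "thin_segment",
    "extract_segments",
]

#: border rows where the 5-pixel vertical neighbourhood is undefined
_BORDER = 2


@dataclass
class SkeletonizationParams:
    """Parameters of the ridge detector.

    delta_f
        Expected intensity falloff (ADU) over two pixels transverse to a
        molecule. ``None`` selects an adaptive threshold of three times the
        robust (MAD-based) noise estimate of the frame.
    min_span_cols
        Components spanning fewer columns are discarded as noise.
    connectivity
        4 or 8, for connected-component labelling of skeletal pixels.
    """

    delta_f: float | None = None
    min_span_cols: int = 3
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.delta_f is not None and not self.delta_f > 0:
            raise ValueError("delta_f must be positive")
        if self.min_span_cols < 1:
            raise ValueError("min_span_cols must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def estimate_noise_sigma(frame: Frame) -> float:
    """Robust frame noise estimate: scaled median absolute deviation."""
    vals = frame.pixels.astype(np.float64, copy=False)
    med = np.median(vals)
    return 1.4826 * float(np.median(np.abs(vals - med)))


def resolve_delta_f(frame: Frame, params: SkeletonizationParams) -> float:
    """Effective falloff threshold: configured value or 3x the noise sigma."""
    if params.delta_f is not None:
        return float(params.delta_f)
    return max(3.0 * estimate_noise_sigma(frame), 1.0)


def detect_skeletal_pixels(frame: Frame, params: SkeletonizationParams) -> np.ndarray:
    """Boolean mask of skeletal pixels of ``frame``.

    A pure function of each pixel's 5-pixel vertical neighbourhood; rows
    within two pixels of the top/bottom border are never candidates.

    Raises
    ------
    ValueError
        If the frame has fewer than 5 rows, making the neighbourhood
        undefined everywhere.
    """
    I = frame.pixels.astype(np.float64, copy=False)
    n_rows = I.shape[0]
    if n_rows < 5:
        raise ValueError(
            f"frame has {n_rows} rows; ridge detection needs at least 5"
        )
    delta_f = resolve_delta_f(frame, params)
    mask = np.zeros(I.shape, dtype=bool)
    centre = I[2:-2]
    mask[2:-2] = (
        (centre >= I[1:-3])
        & (centre >= I[3:-1])
        & (centre - I[:-4] > delta_f)
        & (centre - I[4:] > delta_f)
    )
    return mask


def label_components(
    mask: np.ndarray, connectivity: int = 8, min_span_cols: int = 1
) -> list[np.ndarray]:
    """Partition true mask pixels into connected components.

    Returns one ``(n, 2)`` array of (row, col) coordinates per component,
    sorted by (col, row) within the component and by leftmost column across
    components. Components spanning fewer than ``min_span_cols`` columns are
    discarded.
    """
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n_labels = ndimage.label(mask, structure=structure)
    if n_labels == 0:
        return []
    rows, cols = np.nonzero(labels)
    vals = labels[rows, cols]
    order = np.argsort(vals, kind="stable")
    rows, cols, vals = rows[order], cols[order], vals[order]
    bounds = np.searchsorted(vals, np.arange(1, n_labels + 2))
    components: list[np.ndarray] = []
    for k in range(n_labels):
        r = rows[bounds[k] : bounds[k + 1]]
        c = cols[bounds[k] : bounds[k + 1]]
        span = int(c.max()) - int(c.min()) + 1
        if span < min_span_cols:
            continue
        inner = np.lexsort((r, c))
        components.append(np.column_stack([r[inner], c[inner]]))
    components.sort(key=lambda comp: (int(comp[:, 1].min()), int(comp[:, 0].min())))
    return components


def locate_endpoints(
    component: np.ndarray, frame: Frame
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Left and right end points of a component.

    The end point in each extreme column is the pixel of maximum intensity
    there (coil relaxation brightens cut ends); ties go to the smaller row.
    """
    component = np.asarray(component)
    if component.size == 0:
        raise ValueError("cannot locate endpoints of an empty component")
    cols = component[:, 1]

    def _pick(col: int) -> tuple[int, int]:
        rows = component[cols == col][:, 0]
        intens = frame.pixels[rows, col]
        best = rows[np.lexsort((rows, -intens.astype(np.float64)))][0]
        return (int(best), int(col))

    return _pick(int(cols.min())), _pick(int(cols.max()))


def thin_segment(
    component: np.ndarray,
    endpoints: tuple[tuple[int, int], tuple[int, int]],
    frame: Frame,
) -> SkeletalSegment:
    """Reduce a component to a one-pixel-wide path between its end points.

    Dijkstra shortest path restricted to component pixels, with 8-neighbour
    moves whose column strictly increases toward the right end point; edge
    weight is the Euclidean step length (1 or sqrt 2). Ties are resolved
    deterministically by preferring the smaller (row, col) predecessor, so
    the same component always yields the same path.

    Raises
    ------
    ValueError
        If the end points cannot be joined by such a path (malformed
        component).
    """
    left, right = endpoints
    pix = {(int(r), int(c)) for r, c in np.asarray(component)}
    if left not in pix or right not in pix:
        raise ValueError("endpoints must lie inside the component")
    if left == right:
        path = [left]
    else:
        dist: dict[tuple[int, int], float] = {left: 0.0}
        pred: dict[tuple[int, int], tuple[int, int]] = {}
        # heap keys include (row, col) so equal-cost pops are ordered
        heap: list[tuple[float, int, int]] = [(0.0, left[0], left[1])]
        done: set[tuple[int, int]] = set()
        while heap:
            d, r, c = heapq.heappop(heap)
            node = (r, c)
            if node in done:
                continue
            done.add(node)
            if node == right:
                break
            for dr in (-1, 0, 1):
                nxt = (r + dr, c + 1)
                if nxt not in pix:
                    continue
                nd = d + (1.0 if dr == 0 else math.sqrt(2.0))
                old = dist.get(nxt)
                if old is None or nd < old - 1e-12:
                    dist[nxt] = nd
                    pred[nxt] = node
                    heapq.heappush(heap, (nd, nxt[0], nxt[1]))
                elif abs(nd - old) <= 1e-12 and node < pred[nxt]:
                    pred[nxt] = node
        if right not in done:
            raise ValueError(
                "endpoints are disconnected under column-monotone moves; "
                "malformed component"
            )
        path = [right]
        while path[-1] != left:
            path.append(pred[path[-1]])
        path.reverse()
    arr = np.array(path, dtype=np.int64)
    mean_int = float(frame.pixels[arr[:, 0], arr[:, 1]].astype(np.float64).mean())
    return SkeletalSegment(
        pixels=arr,
        left_end=left,
        right_end=right,
        frame_index=frame.frame_index,
        mean_intensity=mean_int,
    )


def extract_segments(
    frame: Frame, params: SkeletonizationParams | None = None
) -> list[SkeletalSegment]:
    """Full per-frame skeletonization: detect, label, thin.

    Components whose end points cannot be joined are dropped with a warning
    rather than aborting the frame. Segments are returned sorted by left end
    column (then row).
    """
    if params is None:
        params = SkeletonizationParams()
    mask = detect_skeletal_pixels(frame, params)
    components = label_components(mask, params.connectivity, params.min_span_cols)
    segments: list[SkeletalSegment] = []
    for comp in components:
        try:
            endpoints = locate_endpoints(comp, frame)
            segments.append(thin_segment(comp, endpoints, frame))
        except ValueError as exc:  # malformed component: warn, keep going
            warnings.warn(
                f"frame {frame.frame_index}: dropping component near "
                f"col {int(comp[:, 1].min())}: {exc}",
                stacklevel=2,
            )
    segments.sort(key=lambda s: (s.left_end[1], s.left_end[0]))
    return segments
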