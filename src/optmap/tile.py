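"""Inter-frame registration along a microchannel (tiling).

The acquisition stage advances by roughly 75 % of the frame width between
exposures, so adjacent frames overlap by ~25 % and the geometric relation
between them is a pure translation. The translation is estimated from
skeletal-segment end points used as landmarks: over a small search window
around the nominal stage advance, the integer translation matching the
largest one-to-one subset of landmarks is selected. Translations are chained
into cumulative per-frame offsets so multi-frame molecules can be assembled
in channel coordinates; no mosaic image is ever constructed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import SkeletalSegment, Translation

__all__ = [
    "TilingParams",
    "estimate_translation",
    "chain_offsets",
    "to_channel_coords",
    "merge_duplicate_segments",
]


@dataclass
class TilingParams:
    """Search-window and matching parameters for tiling.

    nominal_overlap_frac
        Engineered frame overlap as a fraction of frame width (0.25 for the
        standard acquisition), giving a nominal column advance of
        ``(1 - overlap) * width``.
    col_slack_px / row_slack_px
        Half-widths of the search window around the nominal advance.
        ``col_slack_px = None`` uses 10 % of the frame width.
    match_tol_px
        Two landmarks are matched when their distance after translation is
        at most this radius.
    min_matches
        Below this match count the estimate is considered unreliable and
        the nominal advance is used instead (``is_fallback``).
    """

    nominal_overlap_frac: float = 0.25
    col_slack_px: int | None = None
    row_slack_px: int = 5
    match_tol_px: float = 2.0
    min_matches: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.nominal_overlap_frac < 1:
            raise ValueError("nominal_overlap_frac must be in (0, 1)")
        if self.row_slack_px < 0 or self.match_tol_px < 0:
            raise ValueError("slacks and tolerances must be >= 0")
        if self.col_slack_px is not None and self.col_slack_px < 0:
            raise ValueError("col_slack_px must be >= 0")
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")

    def resolved_col_slack(self, frame_width: int) -> int:
        if self.col_slack_px is not None:
            return int(self.col_slack_px)
        return max(1, round(0.10 * frame_width))


def _match_landmarks(
    a: np.ndarray, b: np.ndarray, d_row: int, d_col: int, tol: float
) -> tuple[int, float]:
    """Greedy one-to-one matching of ``b + (d_row, d_col)`` onto ``a``.

    Returns (number of matched pairs, sum of matched residual distances).
    Pairs are claimed in ascending distance order, each landmark at most
    once.
    """
    shifted = b + np.array([d_row, d_col], dtype=np.float64)
    diff = a[:, None, :] - shifted[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    ii, jj = np.nonzero(dist <= tol)
    if ii.size == 0:
        return 0, 0.0
    dd = dist[ii, jj]
    order = np.argsort(dd, kind="stable")
    used_a = np.zeros(a.shape[0], dtype=bool)
    used_b = np.zeros(b.shape[0], dtype=bool)
    n = 0
    resid = 0.0
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        n += 1
        resid += float(dd[k])
    return n, resid


def estimate_translation(
    landmarks_a: list[tuple[int, int]] | np.ndarray,
    landmarks_b: list[tuple[int, int]] | np.ndarray,
    frame_width: int,
    params: TilingParams | None = None,
    window_center: tuple[int, int] | None = None,
) -> Translation:
    """Estimate the translation mapping frame ``b`` coordinates into frame
    ``a``'s system.

    A landmark at ``(r, c)`` in the later frame ``b`` corresponds to
    ``(r + d_row, c + d_col)`` in the earlier frame ``a``; for the standard
    acquisition ``d_col`` is close to ``(1 - overlap) * frame_width``.

    Every integer translation in the window centred on the nominal advance
    (or on ``window_center`` when given) is scored by the number of
    one-to-one landmark matches within ``match_tol_px``; ties are broken by
    smaller residual sum, then lexicographically by ``(d_row, d_col)``. If
    no translation reaches ``min_matches`` the nominal advance is returned
    with ``is_fallback=True``.
    """
    if params is None:
        params = TilingParams()
    nominal_col = round((1.0 - params.nominal_overlap_frac) * frame_width)
    if window_center is None:
        window_center = (0, nominal_col)
    a = np.asarray(landmarks_a, dtype=np.float64).reshape(-1, 2)
    b = np.asarray(landmarks_b, dtype=np.float64).reshape(-1, 2)
    fallback = Translation(window_center[0], window_center[1], 0, is_fallback=True)
    if a.shape[0] == 0 or b.shape[0] == 0:
        warnings.warn("no landmarks available; using nominal translation")
        return fallback
    col_slack = params.resolved_col_slack(frame_width)
    best: tuple[int, float, int, int] | None = None  # (-n, resid, d_row, d_col)
    for d_row in range(window_center[0] - params.row_slack_px,
                       window_center[0] + params.row_slack_px + 1):
        for d_col in range(window_center[1] - col_slack,
                           window_center[1] + col_slack + 1):
            n, resid = _match_landmarks(a, b, d_row, d_col, params.match_tol_px)
            if n == 0:
                continue
            key = (-n, resid, d_row, d_col)
            if best is None or key < best:
                best = key
    if best is None or -best[0] < params.min_matches:
        return fallback
    return Translation(best[2], best[3], n_matched=-best[0], is_fallback=False)


def chain_offsets(pairwise: list[Translation]) -> list[tuple[int, int]]:
    """Cumulative (row, col) offset of each frame in channel coordinates.

    ``offset[0] = (0, 0)``; each later frame's offset is the prefix sum of
    the pairwise translations, so a pixel in frame ``k`` lives at
    ``pixel + offset[k]`` in the channel.
    """
    offsets = [(0, 0)]
    for t in pairwise:
        prev = offsets[-1]
        offsets.append((prev[0] + t.d_row, prev[1] + t.d_col))
    return offsets


def to_channel_coords(
    segment: SkeletalSegment, offsets: list[tuple[int, int]]
) -> SkeletalSegment:
    """Shift a segment from frame coordinates into channel coordinates."""
    if not 0 <= segment.frame_index < len(offsets):
        raise ValueError(
            f"segment frame_index {segment.frame_index} outside the "
            f"{len(offsets)}-frame offset chain"
        )
    d_row, d_col = offsets[segment.frame_index]
    return segment.shifted(d_row, d_col)


def _rows_agree(a: SkeletalSegment, b: SkeletalSegment, tol: float) -> bool:
    """Mean row difference over shared columns is within tol."""
    lo = max(a.left_end[1], b.left_end[1])
    hi = min(a.right_end[1], b.right_end[1])
    if hi < lo:
        return False
    rows_a = {int(c): int(r) for r, c in a.pixels if lo <= c <= hi}
    rows_b = {int(c): int(r) for r, c in b.pixels if lo <= c <= hi}
    shared = sorted(set(rows_a) & set(rows_b))
    if not shared:
        return False
    mean_d = float(np.mean([abs(rows_a[c] - rows_b[c]) for c in shared]))
    return mean_d <= tol


def _stitch(a: SkeletalSegment, b: SkeletalSegment) -> SkeletalSegment:
    """Combine two duplicate observations of one fragment.

    Columns covered by both take the larger-span instance's pixel; columns
    only one instance covers are taken from it, so a fragment truncated at a
    frame border contributes its unique tail. The plain containment case
    reduces to keeping the larger instance.
    """
    major, minor = (a, b) if a.col_span >= b.col_span else (b, a)
    rows = {int(c): int(r) for r, c in minor.pixels}
    rows.update({int(c): int(r) for r, c in major.pixels})
    cols = sorted(rows)
    arr = np.array([(rows[c], c) for c in cols], dtype=np.int64)
    n_a, n_b = len(a.pixels), len(b.pixels)
    mean_int = (a.mean_intensity * n_a + b.mean_intensity * n_b) / (n_a + n_b)
    return SkeletalSegment(
        pixels=arr,
        left_end=(int(arr[0, 0]), int(arr[0, 1])),
        right_end=(int(arr[-1, 0]), int(arr[-1, 1])),
        frame_index=major.frame_index,
        mean_intensity=float(mean_int),
    )


def merge_duplicate_segments(
    segments: list[SkeletalSegment], params: TilingParams | None = None
) -> list[SkeletalSegment]:
    """Collapse duplicate observations of fragments seen in two frames.

    A molecule lying in the ~25 % overlap region is skeletonized in both
    adjacent frames; after the shift into channel coordinates the two
    observations coincide. Segments from adjacent frames whose column
    intervals intersect and whose centerlines agree (mean row difference
    within ``match_tol_px`` over shared columns) are merged, preferring the
    larger-span instance per column. Output is sorted by left end point.
    """
    if params is None:
        params = TilingParams()
    pool = list(segments)
    merged = True
    while merged:
        merged = False
        out: list[SkeletalSegment] = []
        used = [False] * len(pool)
        for i, s in enumerate(pool):
            if used[i]:
                continue
            current = s
            for j in range(i + 1, len(pool)):
                if used[j]:
                    continue
                t = pool[j]
                if abs(current.frame_index - t.frame_index) != 1:
                    continue
                if _rows_agree(current, t, params.match_tol_px):
                    current = _stitch(current, t)
                    used[j] = True
                    merged = True
            used[i] = True
            out.append(current)
        pool = out
    pool.sort(key=lambda s: (s.left_end[1], s.left_end[0]))
    return pool
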