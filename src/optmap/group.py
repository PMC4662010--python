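"""Grouping of skeletal segments into molecules.

After restriction digestion a molecule presents as a left-to-right chain of
fragments separated by small gaps at the cut sites. Segments are grouped
under three constraints: a segment belongs to at most one group, adjacent
segments in a group have strictly non-overlapping column intervals, and a
link (l, r) is formed only when r is l's best right neighbour AND l is r's
best left neighbour (mutual best). "Best" combines spatial proximity of the
facing end points with orientation similarity from straight-line fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import MoleculeGroup, SkeletalSegment

__all__ = [
    "GroupingParams",
    "fit_orientation",
    "pair_score",
    "group_segments",
]


@dataclass
class GroupingParams:
    """Thresholds of the grouping constraints.

    max_gap_px
        Maximum Euclidean distance between facing end points (9 px at
        100 nm/pixel for the standard acquisition).
    max_angle_deg
        Maximum orientation difference between the fitted lines (15 deg).
    angle_weight
        Weight of the normalized angle term relative to the normalized gap
        term in the pairing score.
    """

    max_gap_px: float = 9.0
    max_angle_deg: float = 15.0
    angle_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.max_gap_px > 0:
            raise ValueError("max_gap_px must be positive")
        if not 0 < self.max_angle_deg < 90:
            raise ValueError("max_angle_deg must be in (0, 90)")


def fit_orientation(segment: SkeletalSegment) -> float:
    """Orientation of a segment relative to the column (flow) axis.

    Angle of the least-squares line through the segment pixels, in degrees
    in (-90, 90]. A single-pixel segment has orientation 0 by convention;
    a (degenerate) single-column segment is vertical, 90 degrees.
    """
    pix = segment.pixels
    if len(pix) < 2:
        return 0.0
    cols = pix[:, 1].astype(np.float64)
    rows = pix[:, 0].astype(np.float64)
    cvar = np.sum((cols - cols.mean()) ** 2)
    if cvar == 0.0:
        return 90.0
    slope = float(np.sum((cols - cols.mean()) * (rows - rows.mean())) / cvar)
    return math.degrees(math.atan(slope))


def _angle_diff(a: float, b: float) -> float:
    """Unsigned difference of two line orientations, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def pair_score(
    left: SkeletalSegment,
    right: SkeletalSegment,
    params: GroupingParams | None = None,
) -> float | None:
    """Score of the ordered pairing (left, right); ``None`` if invalid.

    The pairing is valid only if ``right`` starts strictly to the right of
    ``left`` (non-overlapping intervals with at least a one-column gap), the
    facing end points are within ``max_gap_px`` and the fitted orientations
    differ by at most ``max_angle_deg``. The score is the sum of the two
    normalized criteria (lower is better)::

        gap / max_gap_px  +  angle_weight * |d_angle| / max_angle_deg
    """
    if params is None:
        params = GroupingParams()
    if right.left_end[1] <= left.right_end[1]:
        return None  # overlap, or right not to the right
    gap = math.hypot(
        right.left_end[0] - left.right_end[0],
        right.left_end[1] - left.right_end[1],
    )
    if gap > params.max_gap_px:
        return None
    d_angle = _angle_diff(fit_orientation(left), fit_orientation(right))
    if d_angle > params.max_angle_deg:
        return None
    return gap / params.max_gap_px + params.angle_weight * d_angle / params.max_angle_deg


def _gap_and_angle(
    left: SkeletalSegment, right: SkeletalSegment
) -> tuple[float, float]:
    gap = math.hypot(
        right.left_end[0] - left.right_end[0],
        right.left_end[1] - left.right_end[1],
    )
    return gap, _angle_diff(fit_orientation(left), fit_orientation(right))


def _crosses_forbidden(
    left: SkeletalSegment, right: SkeletalSegment, forbidden_cols
) -> bool:
    # an untrusted (fallback) frame boundary between the two segments
    return any(
        left.right_end[1] < x <= right.left_end[1] for x in forbidden_cols
    )


def group_segments(
    segments: list[SkeletalSegment],
    params: GroupingParams | None = None,
    forbidden_cols: tuple[int, ...] = (),
) -> list[MoleculeGroup]:
    """Partition segments into molecule groups by iterated mutual-best
    linking.

    Each round links every pair (l, r) where r is l's lowest-score valid
    right candidate and l is r's lowest-score valid left candidate, then
    removes the linked ports; rounds repeat until no mutual-best pair
    remains. Maximal chains become groups; unlinked segments become
    singleton groups. Ties between equal scores prefer smaller gap, then
    smaller angle difference, then smaller candidate left-end column, so the
    result is deterministic. ``forbidden_cols`` lists channel columns
    (untrusted frame boundaries) that no link may cross.
    """
    if params is None:
        params = GroupingParams()
    n = len(segments)
    # candidate scores with deterministic tie-break keys
    cand: dict[tuple[int, int], tuple[float, float, float, int]] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = pair_score(segments[i], segments[j], params)
            if s is None:
                continue
            if _crosses_forbidden(segments[i], segments[j], forbidden_cols):
                continue
            gap, d_angle = _gap_and_angle(segments[i], segments[j])
            cand[(i, j)] = (s, gap, d_angle, segments[j].left_end[1])

    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    while True:
        best_right: dict[int, int] = {}
        best_left: dict[int, int] = {}
        for (i, j), key in cand.items():
            if i in succ or j in pred:
                continue
            if i not in best_right or key < cand[(i, best_right[i])]:
                best_right[i] = j
            # tie-break for the left-candidate choice keys on the left
            # segment's left-end column
            if j not in best_left:
                best_left[j] = i
            else:
                k_new = (key[0], key[1], key[2], segments[i].left_end[1])
                cur = best_left[j]
                ck = cand[(cur, j)]
                k_cur = (ck[0], ck[1], ck[2], segments[cur].left_end[1])
                if k_new < k_cur:
                    best_left[j] = i
        linked = False
        for i, j in best_right.items():
            if best_left.get(j) == i:
                succ[i] = j
                pred[j] = i
                linked = True
        if not linked:
            break

    groups: list[MoleculeGroup] = []
    starts = [i for i in range(n) if i not in pred]
    starts.sort(key=lambda i: (segments[i].left_end[1], segments[i].left_end[0]))
    for k, start in enumerate(starts):
        chain = [segments[start]]
        cur = start
        while cur in succ:
            cur = succ[cur]
            chain.append(segments[cur])
        groups.append(MoleculeGroup(segments=chain, molecule_id=f"mol_{k:04d}"))
    return groups
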