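"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately naive implementations (per-pixel loops, exhaustive
enumeration) kept separate from the package code paths they validate.
"""

from __future__ import annotations

import math

import numpy as np


def mask_oracle(pixels: np.ndarray, delta_f: float) -> np.ndarray:
    """Per-pixel evaluation of the four skeletal-pixel inequalities."""
    I = pixels.astype(float)
    h, w = I.shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(2, h - 2):
        for c in range(w):
            if (
                I[r, c] >= I[r - 1, c]
                and I[r, c] >= I[r + 1, c]
                and I[r, c] - I[r - 2, c] > delta_f
                and I[r, c] - I[r + 2, c] > delta_f
            ):
                out[r, c] = True
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Brute-force flood fill partition of true pixels."""
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    todo = {tuple(p) for p in np.argwhere(mask)}
    comps = []
    while todo:
        stack = [todo.pop()]
        comp = set(stack)
        while stack:
            r, c = stack.pop()
            for dr, dc in nbrs:
                q = (r + dr, c + dc)
                if q in todo:
                    todo.remove(q)
                    comp.add(q)
                    stack.append(q)
        comps.append(frozenset(comp))
    return set(comps)


def min_monotone_path_cost(pixels: set, left, right) -> float | None:
    """Exhaustive enumeration of column-monotone 8-neighbour paths.

    Returns the minimum Euclidean length from ``left`` to ``right`` using
    moves (dr in {-1,0,1}, dc=+1) inside ``pixels``, or None if no path.
    """
    if left == right:
        return 0.0
    best: list[float | None] = [None]

    def rec(node, cost):
        if node == right:
            if best[0] is None or cost < best[0]:
                best[0] = cost
            return
        r, c = node
        for dr in (-1, 0, 1):
            nxt = (r + dr, c + 1)
            if nxt in pixels and nxt[1] <= right[1]:
                rec(nxt, cost + (1.0 if dr == 0 else math.sqrt(2.0)))

    rec(left, 0.0)
    return best[0]


def translation_grid_oracle(a, b, window_center, row_slack, col_slack, tol,
                            min_matches):
    """Exhaustive window scan for the landmark-matching translation.

    Same semantics as the tiling estimator (translation maps b into a's
    coordinates, greedy one-to-one matching, ties by residual then
    lexicographic) implemented with plain loops.
    """
    a = [tuple(map(float, p)) for p in a]
    b = [tuple(map(float, p)) for p in b]
    best = None
    for d_row in range(window_center[0] - row_slack, window_center[0] + row_slack + 1):
        for d_col in range(window_center[1] - col_slack, window_center[1] + col_slack + 1):
            pairs = []
            for i, (ra, ca) in enumerate(a):
                for j, (rb, cb) in enumerate(b):
                    d = math.hypot(ra - rb - d_row, ca - cb - d_col)
                    if d <= tol:
                        pairs.append((d, i, j))
            pairs.sort(key=lambda t: t[0])
            used_i, used_j = set(), set()
            n, resid = 0, 0.0
            for d, i, j in pairs:
                if i in used_i or j in used_j:
                    continue
                used_i.add(i)
                used_j.add(j)
                n += 1
                resid += d
            if n == 0:
                continue
            key = (-n, resid, d_row, d_col)
            if best is None or key < best:
                best = key
    if best is None or -best[0] < min_matches:
        return None  # fallback
    return (best[2], best[3], -best[0])


def grouping_oracle(segments, params, pair_score_fn, orientation_fn):
    """Mutual-best chaining by one-at-a-time extraction of the globally
    best mutual pair, with the documented tie-breaks.

    ``pair_score_fn`` / ``orientation_fn`` are evaluated per call; the
    chain assembly logic is independent of the package implementation.
    """
    import math as _m

    n = len(segments)

    def key(i, j):
        s = pair_score_fn(segments[i], segments[j], params)
        if s is None:
            return None
        gap = _m.hypot(
            segments[j].left_end[0] - segments[i].right_end[0],
            segments[j].left_end[1] - segments[i].right_end[1],
        )
        da = abs(orientation_fn(segments[i]) - orientation_fn(segments[j]))
        da = min(da % 180.0, 180.0 - da % 180.0)
        return (s, gap, da)

    succ, pred = {}, {}
    while True:
        added = False
        # all currently available mutual-best pairs
        for i in range(n):
            if i in succ:
                continue
            cands = [
                (key(i, j) + (segments[j].left_end[1],), j)
                for j in range(n)
                if j not in pred and j != i and key(i, j) is not None
            ]
            if not cands:
                continue
            cands.sort()
            j = cands[0][1]
            back = [
                (key(l, j) + (segments[l].left_end[1],), l)
                for l in range(n)
                if l not in succ and l != j and key(l, j) is not None
            ]
            back.sort()
            if back and back[0][1] == i:
                succ[i] = j
                pred[j] = i
                added = True
                break  # restart scan after each link
        if not added:
            break
    chains = []
    starts = sorted(
        (i for i in range(n) if i not in pred),
        key=lambda i: (segments[i].left_end[1], segments[i].left_end[0]),
    )
    for s in starts:
        chain = [s]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        chains.append(tuple(chain))
    return chains
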