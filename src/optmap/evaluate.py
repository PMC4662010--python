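"""Comparison of pipeline output against simulator ground truth.

Used by tests and validation scripts to score grouping and sizing accuracy
on synthetic channels where the true molecules are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GroundTruth, TrueMolecule
from .types import MoleculeGroup

__all__ = ["MatchResult", "match_groups_to_truth", "sizing_accuracy"]


@dataclass
class MatchResult:
    """Assignment of recovered groups to true molecules.

    ``assignment[i]`` is the index of the group matched to true molecule
    ``i`` (or None); a molecule is *grouped correctly* when exactly one
    group covers it, that group contains one segment per true fragment, and
    the group contains nothing from any other molecule.
    """

    assignment: list[int | None]
    correct: list[bool]
    n_true: int = 0
    n_groups: int = 0
    group_owners: dict[int, set[int]] = field(default_factory=dict)

    @property
    def fraction_correct(self) -> float:
        return sum(self.correct) / max(self.n_true, 1)


def _segment_owner(seg, molecules: list[TrueMolecule], row_tol: float = 4.0):
    """True molecule index a segment belongs to, by interval + row agreement."""
    mid_col = (seg.left_end[1] + seg.right_end[1]) // 2
    for mi, mol in enumerate(molecules):
        lo_all = mol.fragment_intervals[0][0]
        hi_all = mol.fragment_intervals[-1][1]
        if not lo_all - 5 <= mid_col <= hi_all + 5:
            continue
        local = int(np.clip(mid_col - mol.col_start, 0,
                            mol.centerline_rows.size - 1))
        true_row = mol.centerline_rows[local]
        seg_rows = seg.pixels[np.abs(seg.pixels[:, 1] - mid_col) <= 2][:, 0]
        seg_row = float(seg_rows.mean()) if seg_rows.size else seg.left_end[0]
        if abs(seg_row - true_row) <= row_tol:
            return mi
    return None


def match_groups_to_truth(
    groups: list[MoleculeGroup], truth: GroundTruth
) -> MatchResult:
    """Score how well recovered groups reproduce the true molecules."""
    molecules = truth.molecules
    owners_per_group: dict[int, set[int]] = {}
    groups_per_mol: dict[int, set[int]] = {mi: set() for mi in range(len(molecules))}
    seg_counts: dict[tuple[int, int], int] = {}
    for gi, group in enumerate(groups):
        owners = set()
        for seg in group.segments:
            mi = _segment_owner(seg, molecules)
            if mi is not None:
                owners.add(mi)
                groups_per_mol[mi].add(gi)
                seg_counts[(gi, mi)] = seg_counts.get((gi, mi), 0) + 1
        owners_per_group[gi] = owners

    assignment: list[int | None] = []
    correct: list[bool] = []
    for mi, mol in enumerate(molecules):
        gis = groups_per_mol[mi]
        if len(gis) != 1:
            assignment.append(None)
            correct.append(False)
            continue
        gi = next(iter(gis))
        assignment.append(gi)
        correct.append(
            owners_per_group[gi] == {mi}
            and seg_counts.get((gi, mi), 0) == mol.n_fragments
            and len(groups[gi].segments) == mol.n_fragments
        )
    return MatchResult(
        assignment=assignment,
        correct=correct,
        n_true=len(molecules),
        n_groups=len(groups),
        group_owners=owners_per_group,
    )


def sizing_accuracy(
    rmaps_sizes: list[list[float]],
    matched_truth_sizes: list[list[float]],
    min_kb: float = 10.0,
) -> tuple[int, int, list[float]]:
    """Fraction of true fragments >= ``min_kb`` sized within relative error.

    Takes per-molecule recovered and true size lists (same molecule order;
    recovered order may be reversed relative to truth since deposition
    orientation is unknown) and returns ``(n_within_10pct, n_eligible,
    relative_errors)`` over fragments with true size >= ``min_kb``. A
    molecule whose fragment count disagrees contributes its eligible
    fragments as failures.
    """
    n_ok = 0
    n_el = 0
    errors: list[float] = []
    for rec, true in zip(rmaps_sizes, matched_truth_sizes):
        if rec is not None and len(rec) == len(true):
            fwd = [abs(r - t) / t for r, t in zip(rec, true)]
            rev = [abs(r - t) / t for r, t in zip(rec[::-1], true)]
            errs = fwd if sum(fwd) <= sum(rev) else rev
        else:
            errs = [float("inf")] * len(true)
        for t, e in zip(true, errs):
            if t >= min_kb:
                n_el += 1
                errors.append(e)
                if e <= 0.10:
                    n_ok += 1
    return n_ok, n_el, errors
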