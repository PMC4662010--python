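"""Core data containers shared across the Rmap extraction pipeline.

Coordinate convention: 0-based ``(row, col)`` with row 0 at the top.
Molecules are deposited along the direction of flow, which is the column
(horizontal) axis, so centerlines are column-ordered. Intensities are raw
camera counts (ADU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "SkeletalSegment",
    "MoleculeGroup",
    "Translation",
    "FragmentMeasurement",
    "ConversionFactor",
    "StandardSpec",
    "Rmap",
]


@dataclass
class Frame:
    """One grayscale microscopy frame from a microchannel.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (ADU), indexed ``(row, col)``.
    frame_index
        Position of the frame within its channel, starting at 0.
    channel_id
        Identifier of the microchannel the frame was acquired from.
    pixel_scale_nm
        Physical size of one pixel in nanometres (100 nm for the standard
        optical-mapping acquisition).
    """

    pixels: np.ndarray
    frame_index: int = 0
    channel_id: str = "ch0"
    pixel_scale_nm: float = 100.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.number):
            raise ValueError("frame pixels must be numeric")
        vals = self.pixels.astype(np.float64, copy=False)
        if not np.all(np.isfinite(vals)):
            raise ValueError("frame pixels must be finite")
        if vals.min(initial=0.0) < 0:
            raise ValueError("frame pixels must be non-negative")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(eq=False)  # identity comparison: pixels arrays don't support ==
class SkeletalSegment:
    """One-pixel-wide, column-ordered centerline of one restriction fragment.

    After thinning the segment holds exactly one pixel per spanned column,
    consecutive pixels advance by one column with a row step of at most one,
    and ``left_end`` / ``right_end`` are the first and last path pixels.
    """

    pixels: np.ndarray  # (n, 2) int array of (row, col), column-ordered
    left_end: tuple[int, int]
    right_end: tuple[int, int]
    frame_index: int = 0
    mean_intensity: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("segment pixels must be an (n, 2) array")
        self.left_end = (int(self.left_end[0]), int(self.left_end[1]))
        self.right_end = (int(self.right_end[0]), int(self.right_end[1]))
        if self.left_end[1] > self.right_end[1]:
            raise ValueError("left_end column must be <= right_end column")

    @property
    def col_span(self) -> int:
        """Number of columns spanned (inclusive)."""
        return self.right_end[1] - self.left_end[1] + 1

    def shifted(self, d_row: int, d_col: int) -> "SkeletalSegment":
        """Return a copy translated by ``(d_row, d_col)``."""
        return SkeletalSegment(
            pixels=self.pixels + np.array([d_row, d_col], dtype=np.int64),
            left_end=(self.left_end[0] + d_row, self.left_end[1] + d_col),
            right_end=(self.right_end[0] + d_row, self.right_end[1] + d_col),
            frame_index=self.frame_index,
            mean_intensity=self.mean_intensity,
        )


@dataclass
class MoleculeGroup:
    """Ordered, non-overlapping skeletal segments from one DNA molecule.

    Segments are in channel coordinates; their column intervals are disjoint
    and strictly increase left to right (one interval per restriction
    fragment, in molecular order).
    """

    segments: list[SkeletalSegment]
    molecule_id: str = ""

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.left_end[1] <= a.right_end[1]:
                raise ValueError(
                    "group segments must be disjoint and strictly increasing"
                )

    @property
    def n_fragments(self) -> int:
        return len(self.segments)


@dataclass
class Translation:
    """Integer-pixel translation relating two adjacent frames.

    Maps coordinates of the later frame into the earlier frame's system: a
    landmark at ``(r, c)`` in frame ``k+1`` appears at ``(r + d_row,
    c + d_col)`` in frame ``k``. ``is_fallback`` marks translations that
    fell back to the nominal stage advance because too few landmarks matched.
    """

    d_row: int
    d_col: int
    n_matched: int = 0
    is_fallback: bool = False


@dataclass
class FragmentMeasurement:
    """Integrated fluorescence of one fragment under its fixed-width mask."""

    integrated_fluorescence: float
    n_mask_pixels: int
    span_cols: int
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.integrated_fluorescence < 0:
            raise ValueError("integrated fluorescence must be >= 0")
        if self.n_mask_pixels < self.span_cols:
            raise ValueError("mask cannot be smaller than the column span")


@dataclass
class ConversionFactor:
    """Kilobases per ADU of integrated fluorescence (C_kb)."""

    c_kb: float
    n_standards_used: int = 0

    def __post_init__(self) -> None:
        if not self.c_kb > 0:
            raise ValueError("c_kb must be positive")


@dataclass
class StandardSpec:
    """A co-deposited size standard of known restriction fragment sizes.

    The classic example is Bsu36I-digested lambda DNA (~48.5 kb) with
    fragments 26.718, 7.601 and 14.183 kb.
    """

    name: str
    fragment_sizes_kb: tuple[float, ...]

    def __post_init__(self) -> None:
        self.fragment_sizes_kb = tuple(float(s) for s in self.fragment_sizes_kb)
        if not self.fragment_sizes_kb or any(s <= 0 for s in self.fragment_sizes_kb):
            raise ValueError("standard fragment sizes must be positive")

    @property
    def total_kb(self) -> float:
        return float(sum(self.fragment_sizes_kb))

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_sizes_kb)

    @property
    def fractions(self) -> tuple[float, ...]:
        t = self.total_kb
        return tuple(s / t for s in self.fragment_sizes_kb)


def lambda_bsu36i() -> StandardSpec:
    """The three-fragment Bsu36I lambda DNA standard (~48.5 kb)."""
    return StandardSpec("lambda_bsu36i", (26.718, 7.601, 14.183))


@dataclass
class Rmap:
    """Ordered restriction map of one molecule: fragment sizes in kilobases.

    ``flags`` holds one set of quality tokens per fragment (same order as
    ``fragment_sizes_kb``); flagged fragments are retained, never deleted.
    """

    molecule_id: str
    fragment_sizes_kb: list[float]
    flags: list[set[str]]
    channel_id: str = ""
    frame_span: tuple[int, int] = (0, 0)
    left_col: int = 0
    right_col: int = 0

    def __post_init__(self) -> None:
        if len(self.flags) != len(self.fragment_sizes_kb):
            raise ValueError("one flag set per fragment required")
        if any(s <= 0 for s in self.fragment_sizes_kb):
            raise ValueError("fragment sizes must be positive")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_sizes_kb)

    @property
    def total_kb(self) -> float:
        return float(sum(self.fragment_sizes_kb))
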