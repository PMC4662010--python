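"""Debug overlays: skeletons and groups rendered over the image data."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .types import Frame, MoleculeGroup, SkeletalSegment

__all__ = ["save_skeleton_overlay", "save_group_overlay"]


def save_skeleton_overlay(
    frame: Frame, segments: list[SkeletalSegment], path: str | Path
) -> None:
    """Frame with skeletal pixels in blue and end points in red/green."""
    fig, ax = plt.subplots(figsize=(10, 8))
    ax.imshow(frame.pixels, cmap="gray", interpolation="nearest")
    for seg in segments:
        ax.plot(seg.pixels[:, 1], seg.pixels[:, 0], ".", color="tab:blue", ms=1)
        ax.plot(seg.left_end[1], seg.left_end[0], "r|", ms=8)
        ax.plot(seg.right_end[1], seg.right_end[0], "g|", ms=8)
    ax.set_title(f"{frame.channel_id} frame {frame.frame_index}")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_group_overlay(groups: list[MoleculeGroup], path: str | Path) -> None:
    """Groups over the channel extent, one colour per molecule."""
    fig, ax = plt.subplots(figsize=(12, 4))
    cmap = plt.get_cmap("tab20")
    for k, group in enumerate(groups):
        color = cmap(k % 20)
        for seg in group.segments:
            ax.plot(seg.pixels[:, 1], seg.pixels[:, 0], "-", color=color, lw=1.5)
    ax.invert_yaxis()
    ax.set_xlabel("channel column (px)")
    ax.set_ylabel("row (px)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
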