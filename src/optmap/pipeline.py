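"""End-to-end orchestration: frames -> skeletonize -> tile -> group -> size.

Each microchannel is processed independently (no cross-channel state), so
channels can trivially be distributed across workers. Given identical
frames and configuration the pipeline is fully deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import size as sizing
from .group import GroupingParams, group_segments
from .skeletonize import SkeletonizationParams, extract_segments
from .size import SizingParams
from .tile import (
    TilingParams,
    chain_offsets,
    estimate_translation,
    merge_duplicate_segments,
    to_channel_coords,
)
from .types import ConversionFactor, Frame, Rmap, StandardSpec, lambda_bsu36i

__all__ = [
    "PipelineConfig",
    "RunReport",
    "ChannelResult",
    "read_frames",
    "run_channel",
    "process_channel",
    "write_rmaps",
]

log = logging.getLogger("optmap")


@dataclass
class PipelineConfig:
    """All stage parameters plus the standards spec for one run."""

    skeletonization: SkeletonizationParams = field(
        default_factory=SkeletonizationParams
    )
    tiling: TilingParams = field(default_factory=TilingParams)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    sizing: SizingParams = field(default_factory=SizingParams)
    standard: StandardSpec | None = field(default_factory=lambda_bsu36i)
    c_kb_override: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Build a config from a YAML file; missing sections use defaults.

        Recognized top-level keys: ``skeletonization``, ``tiling``,
        ``grouping``, ``sizing`` (each a mapping of the corresponding
        parameter fields), ``standard`` (inline ``name`` +
        ``fragment_sizes_kb``, or ``standard_file`` pointing at a standards
        YAML), and ``c_kb_override``.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, klass in (
            ("skeletonization", SkeletonizationParams),
            ("tiling", TilingParams),
            ("grouping", GroupingParams),
            ("sizing", SizingParams),
        ):
            if key in data:
                kwargs[key] = klass(**data[key])
        if "standard" in data:
            std = data["standard"]
            kwargs["standard"] = StandardSpec(
                name=std["name"],
                fragment_sizes_kb=tuple(std["fragment_sizes_kb"]),
            )
        elif "standard_file" in data:
            base = Path(path).parent
            kwargs["standard"] = sizing.load_standard_spec(
                base / data["standard_file"]
            )
        if "c_kb_override" in data and data["c_kb_override"] is not None:
            kwargs["c_kb_override"] = float(data["c_kb_override"])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Per-channel processing counts and the tiling audit trail."""

    channel_id: str = ""
    frames_processed: int = 0
    segments_found: int = 0
    groups_formed: int = 0
    standards_identified: int = 0
    rmaps_emitted: int = 0
    fragments_flagged: int = 0
    fallback_boundaries: int = 0
    c_kb: float | None = None
    offsets: list[tuple[int, int]] = field(default_factory=list)
    translations: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "channel_id": self.channel_id,
            "frames_processed": self.frames_processed,
            "segments_found": self.segments_found,
            "groups_formed": self.groups_formed,
            "standards_identified": self.standards_identified,
            "rmaps_emitted": self.rmaps_emitted,
            "fragments_flagged": self.fragments_flagged,
            "fallback_boundaries": self.fallback_boundaries,
            "c_kb": self.c_kb,
            "offsets": [list(o) for o in self.offsets],
            "translations": self.translations,
        }


def read_frames(manifest_path: str | Path) -> dict[str, list[Frame]]:
    """Read a channel manifest into per-channel frame lists.

    The manifest has one line per frame: ``channel_id TAB frame_index TAB
    path`` (paths relative to the manifest). Frames are returned ordered by
    ``frame_index``, which must run 0..n-1 without gaps or duplicates, and
    must be single-plane grayscale images.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    per_channel: dict[str, dict[int, Frame]] = {}
    with open(manifest_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{manifest_path}:{lineno}: expected 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            channel_id, idx_s, rel = parts
            try:
                idx = int(idx_s)
            except ValueError:
                raise ValueError(
                    f"{manifest_path}:{lineno}: frame_index {idx_s!r} is not "
                    "an integer"
                ) from None
            path = (base / rel) if not Path(rel).is_absolute() else Path(rel)
            if not path.exists():
                raise ValueError(f"{manifest_path}:{lineno}: missing file {path}")
            pixels = tifffile.imread(path)
            if pixels.ndim != 2:
                raise ValueError(
                    f"{manifest_path}:{lineno}: {path} is not single-plane "
                    f"grayscale (shape {pixels.shape})"
                )
            chan = per_channel.setdefault(channel_id, {})
            if idx in chan:
                raise ValueError(
                    f"{manifest_path}:{lineno}: duplicate frame_index {idx} "
                    f"in channel {channel_id}"
                )
            chan[idx] = Frame(pixels=pixels, frame_index=idx, channel_id=channel_id)
    out: dict[str, list[Frame]] = {}
    for channel_id, frames in per_channel.items():
        indices = sorted(frames)
        if indices != list(range(len(indices))):
            raise ValueError(
                f"channel {channel_id}: frame indices {indices} are not "
                "contiguous from 0"
            )
        out[channel_id] = [frames[i] for i in indices]
    return out


@dataclass
class ChannelResult:
    """Full output of one channel run, including stage intermediates."""

    rmaps: list[Rmap]
    report: RunReport
    groups: list = field(default_factory=list)
    measurements: list = field(default_factory=list)
    standard_indices: list[int] = field(default_factory=list)
    merged_segments: list = field(default_factory=list)
    offsets: list[tuple[int, int]] = field(default_factory=list)
    conversion: ConversionFactor | None = None


def run_channel(
    frames: list[Frame], config: PipelineConfig | None = None
) -> tuple[list[Rmap], RunReport]:
    """Process one channel's frames into Rmaps.

    Thin wrapper over :func:`process_channel` returning only the Rmaps and
    the run report.
    """
    result = process_channel(frames, config)
    return result.rmaps, result.report


def process_channel(
    frames: list[Frame], config: PipelineConfig | None = None
) -> ChannelResult:
    """Process one channel's frames, keeping stage intermediates.

    Runs skeletonization per frame, estimates the inter-frame translations
    and chains them, merges duplicate segments from overlap regions, groups
    segments into molecules, identifies standards, estimates C_kb (or uses
    the configured override) and emits one Rmap per non-standard group.
    Standards are reported separately in the RunReport, not as Rmaps.
    """
    if config is None:
        config = PipelineConfig()
    if not frames:
        raise ValueError("need at least one frame")
    channel_id = frames[0].channel_id
    report = RunReport(channel_id=channel_id, frames_processed=len(frames))

    per_frame_segments = [
        extract_segments(f, config.skeletonization) for f in frames
    ]
    report.segments_found = sum(len(s) for s in per_frame_segments)
    log.info("%s: %d segments in %d frames", channel_id,
             report.segments_found, len(frames))

    width = frames[0].shape[1]
    translations = []
    for k in range(len(frames) - 1):
        lm_a = [s.left_end for s in per_frame_segments[k]] + [
            s.right_end for s in per_frame_segments[k]
        ]
        lm_b = [s.left_end for s in per_frame_segments[k + 1]] + [
            s.right_end for s in per_frame_segments[k + 1]
        ]
        translations.append(
            estimate_translation(lm_a, lm_b, width, config.tiling)
        )
    offsets = chain_offsets(translations)
    report.offsets = offsets
    report.translations = [
        {
            "d_row": t.d_row,
            "d_col": t.d_col,
            "n_matched": t.n_matched,
            "is_fallback": t.is_fallback,
        }
        for t in translations
    ]
    report.fallback_boundaries = sum(t.is_fallback for t in translations)

    channel_segments = [
        to_channel_coords(s, offsets)
        for segs in per_frame_segments
        for s in segs
    ]
    merged = merge_duplicate_segments(channel_segments, config.tiling)

    # A fallback (too few landmark matches) boundary is distrusted unless a
    # duplicate observation stitched across it confirms the nominal advance.
    from .tile import _rows_agree

    confirmed: set[int] = set()
    by_frame: dict[int, list] = {}
    for s in channel_segments:
        by_frame.setdefault(s.frame_index, []).append(s)
    for k, t in enumerate(translations):
        if not t.is_fallback:
            continue
        for s in by_frame.get(k, []):
            if any(
                _rows_agree(s, u, config.tiling.match_tol_px)
                for u in by_frame.get(k + 1, [])
            ):
                confirmed.add(k)
                break

    boundary_cols = sizing._owner_boundaries(offsets, width)
    forbidden = tuple(
        boundary_cols[k]
        for k, t in enumerate(translations)
        if t.is_fallback and k not in confirmed
    )
    groups = group_segments(merged, config.grouping, forbidden)
    report.groups_formed = len(groups)

    # per-frame background from that frame's own (frame-coordinate) masks
    backgrounds = []
    n_rows = frames[0].shape[0]
    for frame, segs in zip(frames, per_frame_segments):
        masks = [sizing.build_intensity_mask(s, n_rows=n_rows) for s in segs]
        backgrounds.append(
            sizing.estimate_background(frame, masks, config.sizing)
        )

    measurements = [
        sizing.measure_group(g, frames, offsets, backgrounds) for g in groups
    ]
    sizing.flag_distractors(groups, measurements, frames, offsets, config.sizing)
    report.fragments_flagged = sum(
        1 for meas in measurements for m in meas if m.flags
    )

    std_idx: list[int] = []
    if config.standard is not None:
        std_idx = sizing.identify_standards(
            groups, measurements, config.standard,
            config.sizing.standards_rel_tol,
        )
    report.standards_identified = len(std_idx)

    if config.c_kb_override is not None:
        factor = ConversionFactor(config.c_kb_override, n_standards_used=0)
    else:
        try:
            factor = sizing.estimate_conversion_factor(
                std_idx, measurements, config.standard
            )
        except ValueError as exc:
            raise ValueError(f"channel {channel_id}: {exc}") from exc
    report.c_kb = factor.c_kb

    rmaps = []
    std_set = set(std_idx)
    for i, (group, meas) in enumerate(zip(groups, measurements)):
        if i in std_set or not group.segments:
            continue
        rmaps.append(sizing.construct_rmap(group, meas, factor, channel_id))
    report.rmaps_emitted = len(rmaps)
    log.info(
        "%s: %d groups, %d standards, %d Rmaps, c_kb=%.6g",
        channel_id, len(groups), len(std_idx), len(rmaps), factor.c_kb,
    )
    return ChannelResult(
        rmaps=rmaps,
        report=report,
        groups=groups,
        measurements=measurements,
        standard_indices=std_idx,
        merged_segments=merged,
        offsets=offsets,
        conversion=factor,
    )


def write_rmaps(
    rmaps: list[Rmap], report: RunReport, directory: str | Path
) -> None:
    """Write the Rmap TSV, the tiling offsets table and the run report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sizing.write_rmaps_tsv(rmaps, directory / "rmaps.tsv")
    lines = ["#frame_index\td_row_cum\td_col_cum\tn_matched\tfallback_flag"]
    for k, off in enumerate(report.offsets):
        if k == 0:
            n_matched, fb = "-", 0
        else:
            t = report.translations[k - 1]
            n_matched, fb = t["n_matched"], int(t["is_fallback"])
        lines.append(f"{k}\t{off[0]}\t{off[1]}\t{n_matched}\t{fb}")
    (directory / "offsets.tsv").write_text("\n".join(lines) + "\n")
    with open(directory / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
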